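"""Multi-GP Bayesian optimization of the scattering-RMSD objective.

One search round trains every configured kernel family on all evaluations so
far, minimizes the lower-confidence-bound acquisition a(x) = mu(x) - kappa *
sigma(x) for every (kernel, kappa) pair by repeated random sampling with
coordinate-wise averaging of the per-repeat minimizers, deduplicates the
resulting candidates, and evaluates the survivors with the expensive
simulator.  The search region is a ball around a user-chosen center; the
initial design is drawn uniformly by volume from that ball.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize as _scipy_minimize

from .gp import GPModel, KernelSpec, predict, train_gp
from .objective import EvaluationConfig, ObjectiveEvaluation, evaluate_point

__all__ = [
    "SearchConfig",
    "SearchState",
    "sample_hypersphere",
    "lcb",
    "minimize_af",
    "run_optimization",
    "select_reevaluation_points",
    "estimate_confidence_interval",
]

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Search-region, acquisition, and budget settings of one optimization.

    The radius is in log units for stochastic (wait-time offset) searches and
    linear rate units for deterministic ones.  kappa trades exploration
    (large) against exploitation (small); one candidate is proposed per
    (kernel family, kappa) pair per round.
    """

    center: np.ndarray
    radius: float
    kernel_families: tuple[str, ...] = (
        "matern32_ard", "matern52_ard", "rq_ard", "rq_iso",
        "gabor_ard", "neural_network", "se_ard",
    )
    kappa_values: tuple[float, ...] = (0.5, 2.0, 5.0)
    initial_points: int = 100
    replicates_per_point: int = 1
    rounds: int = 10
    af_samples: int = 5000
    af_repeats: int = 10
    reeval_pool: int = 50
    reeval_cap: int = 16
    dedup_tol: float = 1e-6
    n_best_clouds: int = 5
    cloud_scale: float = 0.1
    cloud_shrink: float = 1.0
    log_objective: bool = False
    af_polish: bool = True
    cloud_adapt: bool = False  # scale clouds to the spread of the best points
    diverse_anchors: bool = False  # cluster the top points; anchor clouds on
    # one representative per cluster rather than the (usually coincident)
    # overall best few
    gp_noise: float | None = None  # fixed GP noise variance; None = learned
    train_restarts: int = 2
    train_maxiter: int = 60
    seed: int = 0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not self.kernel_families or not self.kappa_values:
            raise ValueError("need at least one kernel family and one kappa")
        for name in ("initial_points", "replicates_per_point", "af_samples",
                     "af_repeats", "reeval_pool", "reeval_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SearchState:
    """Evaluations, per-kernel models, per-round candidates, and the incumbent."""

    evaluations: list[ObjectiveEvaluation] = field(default_factory=list)
    models: dict[str, GPModel] = field(default_factory=dict)
    round_candidates: list[list[tuple[str, float, np.ndarray]]] = field(default_factory=list)

    @property
    def incumbent(self) -> ObjectiveEvaluation:
        ok = [e for e in self.evaluations if not e.failed]
        if not ok:
            raise ValueError("no successful evaluations")
        return min(ok, key=lambda e: e.rmsd)

    def points(self) -> np.ndarray:
        return np.array([e.point for e in self.evaluations if not e.failed])

    def rmsds(self) -> np.ndarray:
        return np.array([e.rmsd for e in self.evaluations if not e.failed])


def sample_hypersphere(
    center: np.ndarray, radius: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """n points uniform by volume in the ball of the given center and radius."""
    if n < 1:
        raise ValueError("n must be >= 1")
    center = np.asarray(center, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = len(center)
    dirs = rng.standard_normal((n, d))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = radius * rng.uniform(size=(n, 1)) ** (1.0 / d)
    return center + dirs * radii


def lcb(mu: np.ndarray | float, sigma: np.ndarray | float, kappa: float) -> np.ndarray | float:
    """Lower confidence bound mu - kappa * sigma (minimized in acquisition)."""
    if np.any(np.asarray(sigma) < 0):
        raise ValueError("sigma must be non-negative")
    return mu - kappa * sigma


def _clip_to_ball(x: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    delta = x - center
    norm = np.linalg.norm(delta)
    if norm > radius:
        return center + delta * (radius / norm)
    return x


def minimize_af(
    model: GPModel,
    kappa: float,
    config: SearchConfig,
    seed: int | np.random.Generator,
    best_points: np.ndarray | None = None,
    cloud_scale: float | np.ndarray | None = None,
) -> np.ndarray:
    # cloud_scale may be a scalar, a per-dimension sigma vector, or a
    # Cholesky factor of a full cloud covariance (lower-triangular matrix)
    """Sampling-based LCB minimization with coordinate-wise averaging.

    Each repeat draws af_samples points — half uniform in the search ball,
    half from Gaussian clouds around the best evaluated points — and keeps
    the sample LCB minimizer; the returned point is the coordinate-wise mean
    of the repeat minimizers, clipped back into the ball.  Cloud standard
    deviations are stretched per dimension in proportion to the model's ARD
    lengthscales, so flat (long-lengthscale) directions are explored with
    longer steps than steep ones.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = cloud_scale if cloud_scale is not None else config.cloud_scale * config.radius
    d = len(config.center)
    chol = None
    if isinstance(scale, np.ndarray) and scale.ndim == 2:
        chol = scale
        aniso = np.ones(d)
    elif isinstance(scale, np.ndarray):
        aniso = np.ones(d)  # per-dimension sigmas supplied by the caller
    else:
        # stretch clouds along the model's flat (long-lengthscale) directions
        ls = model.kernel.lengthscales
        if len(ls) == d:
            aniso = ls / np.exp(np.mean(np.log(ls)))
            aniso = np.clip(aniso, 1.0 / 3.0, 3.0)
        else:
            aniso = np.ones(d)
    minimizers = []
    for _ in range(config.af_repeats):
        n_uni = config.af_samples
        samples = [sample_hypersphere(config.center, config.radius, n_uni, rng)]
        if best_points is not None and len(best_points) > 0:
            n_cloud = max(1, config.af_samples // 2)
            samples[0] = samples[0][: config.af_samples - n_cloud]
            anchors = best_points[rng.integers(len(best_points), size=n_cloud)]
            if chol is not None:
                cloud = anchors + rng.standard_normal(anchors.shape) @ chol.T
            else:
                cloud = anchors + rng.normal(size=anchors.shape) * (scale * aniso)
            samples.append(cloud)
        xs = np.vstack(samples)
        mu, var = predict(model, xs)
        a = lcb(mu, np.sqrt(var), kappa)
        x_best = xs[int(np.argmin(a))]
        if config.af_polish:
            # refine the sample minimizer to sub-sample-spacing precision
            def af_value(x):
                m, v = predict(model, x)
                return lcb(m, np.sqrt(v), kappa)

            res = _scipy_minimize(
                af_value, x_best, method="Nelder-Mead",
                options={"maxfev": 600, "xatol": 1e-5 * config.radius,
                         "fatol": 0.0},
            )
            cand = _clip_to_ball(res.x, config.center, config.radius)
            if af_value(cand) < af_value(x_best):
                x_best = cand
        minimizers.append(x_best)
    out = np.mean(minimizers, axis=0)
    return _clip_to_ball(out, config.center, config.radius)


def _dedup(candidates, tol):
    kept = []
    for kernel, kappa, x in candidates:
        if any(np.linalg.norm(x - y) < tol for _, _, y in kept):
            continue
        kept.append((kernel, kappa, x))
    return kept


def run_optimization(
    config: SearchConfig,
    eval_config: EvaluationConfig,
    log_path: str | Path | None = None,
) -> SearchState:
    """Run the full multi-GP search: initial design plus acquisition rounds.

    Every source of randomness derives from config.seed.  Failed objective
    evaluations are logged and skipped without aborting the round.
    """
    rng = np.random.default_rng(config.seed)
    state = SearchState()
    log_fh = open(log_path, "w") if log_path is not None else None

    def log_event(**kw):
        if log_fh is not None:
            json.dump({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in kw.items()}, log_fh)
            log_fh.write("\n")

    def run_eval(x, rnd):
        seed = int(rng.integers(2**31 - 1))
        if callable(eval_config):  # plumbing mode: a cheap analytic objective
            ev = ObjectiveEvaluation(
                point=np.asarray(x, dtype=float), rmsd=float(eval_config(x)),
                replicate_rmsds=[], noise_variance=0.0, replicates=1,
            )
        else:
            ev = evaluate_point(x, eval_config, seed=seed)
        state.evaluations.append(ev)
        if ev.failed:
            logger.warning("objective evaluation failed at %s; skipping", x)
        log_event(round=rnd, point=np.asarray(x), rmsd=ev.rmsd,
                  noise=ev.noise_variance, failed=ev.failed)
        return ev

    try:
        design = sample_hypersphere(config.center, config.radius,
                                    config.initial_points, rng)
        for x in design:
            run_eval(x, rnd=0)

        warm: dict[str, KernelSpec] = {}
        for rnd in range(1, config.rounds + 1):
            xs, ys = state.points(), state.rmsds()
            if config.log_objective:
                # regress log RMSD: resolves the orders-of-magnitude drop
                # near the minimum that raw values compress to ~0
                y_fit = np.log(ys + 1e-12 * max(ys.max(), 1e-300))
            else:
                y_fit = ys
            top = np.argsort(ys)[: max(config.n_best_clouds, 10)]
            if config.cloud_adapt and len(top) >= 8:
                # full empirical covariance of the best points, inflated:
                # elongated along the low-objective valley so exploitation
                # probes the valley's continuation, not just its cross-section
                C = np.cov(xs[top].T) * 2.5**2
                C[np.diag_indices_from(C)] += (0.02 * config.radius) ** 2
                cloud = np.linalg.cholesky(C)
            else:
                cloud = (config.cloud_scale * config.radius
                         * config.cloud_shrink ** (rnd - 1))
            for fam in config.kernel_families:
                model = train_gp(
                    warm.get(fam, fam), xs, y_fit,
                    seed=int(rng.integers(2**31 - 1)),
                    restarts=config.train_restarts, maxiter=config.train_maxiter,
                    fixed_noise=config.gp_noise,
                )
                state.models[fam] = model
                warm[fam] = model.kernel
            if config.diverse_anchors and len(xs) >= 10:
                reps = select_reevaluation_points(
                    state, pool=min(50, len(xs)), cap=config.n_best_clouds,
                    lengthscales=np.full(xs.shape[1], 0.1 * config.radius),
                )
                best_points = np.array(reps)
            else:
                order = np.argsort(ys)[: config.n_best_clouds]
                best_points = xs[order]
            candidates = []
            for fam in config.kernel_families:
                for kappa in config.kappa_values:
                    x_new = minimize_af(
                        state.models[fam], kappa, config, rng, best_points,
                        cloud_scale=cloud,
                    )
                    candidates.append((fam, kappa, x_new))
            state.round_candidates.append(candidates)
            log_event(round=rnd, n_candidates=len(candidates))
            survivors = _dedup(candidates, config.dedup_tol * config.radius)
            for fam, kappa, x in survivors:
                ev = run_eval(x, rnd)
                log_event(round=rnd, kernel=fam, kappa=kappa,
                          candidate=np.asarray(x), rmsd=ev.rmsd)
    finally:
        if log_fh is not None:
            log_fh.close()
    return state


def select_reevaluation_points(
    state: SearchState,
    pool: int,
    cap: int,
    lengthscales: np.ndarray,
    threshold: float = 1.0,
) -> list[np.ndarray]:
    """Pick low-RMSD, mutually distant evaluated points for re-evaluation.

    The pool is the ``pool`` best-scoring evaluated points.  Points closer
    than ``threshold`` in lengthscale-scaled Euclidean distance are merged
    agglomeratively (single linkage) and each cluster is represented by its
    best-scoring member; up to ``cap`` representatives are returned, ordered
    by score.  The output is always a subset of the evaluated points.
    """
    ok = [e for e in state.evaluations if not e.failed]
    if not ok:
        raise ValueError("no evaluations to select from")
    ok.sort(key=lambda e: e.rmsd)
    top = ok[: min(pool, len(ok))]
    pts = np.array([e.point for e in top])
    scaled = pts / np.asarray(lengthscales, dtype=float)
    if len(top) == 1:
        return [top[0].point]
    Z = linkage(scaled, method="single")
    labels = fcluster(Z, t=threshold, criterion="distance")
    reps: dict[int, ObjectiveEvaluation] = {}
    for lab, ev in zip(labels, top):  # top is rmsd-sorted: first seen is best
        reps.setdefault(int(lab), ev)
    chosen = sorted(reps.values(), key=lambda e: e.rmsd)[:cap]
    return [e.point for e in chosen]


def estimate_confidence_interval(
    model: GPModel,
    optimum: np.ndarray,
    dim: int,
    seed: int,
    extent: float = 20.0,
    spacing: float = 0.001,
    draws: int = 10_000,
    coverage: float = 0.95,
) -> tuple[float, float]:
    """Per-dimension confidence interval from the GP posterior at an optimum.

    A 1-D grid of extent ``extent * l`` at density ``spacing * l`` (l the
    kernel lengthscale of the scanned dimension) is centered on the optimum;
    ``draws`` independent posterior samples of the objective on the grid are
    drawn and the per-grid-point argmin frequency accumulated; the smallest
    symmetric window around the optimum holding ``coverage`` of the argmin
    mass is returned as (low, high) coordinates of the scanned dimension.
    """
    optimum = np.asarray(optimum, dtype=float)
    ls = model.kernel.lengthscales
    ell = float(ls[dim]) if len(ls) > 1 else float(ls[0])
    half = int(round(extent / (2.0 * spacing)))
    offsets = np.arange(-half, half + 1) * (spacing * ell)
    grid = np.tile(optimum, (len(offsets), 1))
    grid[:, dim] += offsets

    mus, sigmas = [], []
    for i in range(0, len(grid), 5000):
        mu, var = predict(model, grid[i:i + 5000])
        mus.append(mu)
        sigmas.append(np.sqrt(var))
    mu = np.concatenate(mus)
    sigma = np.concatenate(sigmas)

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(grid), dtype=np.int64)
    chunk = 200
    done = 0
    while done < draws:
        m = min(chunk, draws - done)
        samples = mu[None, :] + sigma[None, :] * rng.standard_normal((m, len(grid)))
        idx = np.argmin(samples, axis=1)
        counts += np.bincount(idx, minlength=len(grid))
        done += m

    center = half
    target = coverage * counts.sum()
    width = 0
    acc = counts[center]
    while acc < target and width < half:
        width += 1
        acc += counts[center - width] + counts[center + width]
    return (
        float(optimum[dim] - width * spacing * ell),
        float(optimum[dim] + width * spacing * ell),
    )
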