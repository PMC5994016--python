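"""Gaussian-process regression over the scattering-RMSD objective.

A GP prior F(x) ~ GP(m(x), k(x, x')) with a constant mean is fitted to
evaluated (point, RMSD) pairs; training minimizes the negative log marginal
likelihood over log-hyperparameters with multi-restart L-BFGS.  Seven kernel
families are available, spanning rough (Matern 3/2) to infinitely smooth
(squared exponential) and including a periodic-envelope (Gabor) and a
non-stationary (arcsine neural-network) covariance:

    matern32_ard   sigma^2 (1 + sqrt(3 r)) exp(-sqrt(3 r))
    matern52_ard   sigma^2 (1 + sqrt(5 r) + 5 r / 3) exp(-sqrt(5 r))
    rq_ard         sigma^2 (1 + r / (2 alpha))^(-alpha)
    rq_iso         as rq_ard with a single scalar lengthscale
    gabor_ard      sigma^2 exp(-sum t_i^2 / l_i^2) cos(2 pi sum t_i / p_i)
    neural_network sigma^2 arcsin[x1' P x2 / sqrt((1 + x1' P x1)(1 + x2' P x2))]
    se_ard         sigma^2 exp(-r / 2)

with r = (x1 - x2)' P^-1 (x1 - x2), P = diag(l_i^2), t = x1 - x2, and for the
neural-network family P = diag(1 / l_i^2).  Hyper-priors are not imposed;
box bounds on the log-hyperparameters exist only for numerical safety.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import minimize

__all__ = [
    "KERNEL_FAMILIES",
    "KernelSpec",
    "GPModel",
    "kernel_eval",
    "kernel_matrix",
    "nlml",
    "train_gp",
    "predict",
]

KERNEL_FAMILIES = (
    "matern32_ard",
    "matern52_ard",
    "rq_ard",
    "rq_iso",
    "gabor_ard",
    "neural_network",
    "se_ard",
)

JITTER = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family with its hyperparameters.

    lengthscales is a length-d vector for ARD families and length-1 for
    rq_iso; alpha applies to the rational-quadratic families and periods to
    the Gabor family only.
    """

    family: str
    signal_variance: float
    lengthscales: np.ndarray
    noise_variance: float
    alpha: float = 2.0
    periods: np.ndarray | None = None

    def __post_init__(self):
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        ls = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        object.__setattr__(self, "lengthscales", ls)
        if self.periods is not None:
            object.__setattr__(
                self, "periods", np.atleast_1d(np.asarray(self.periods, dtype=float))
            )
        for name, v in (
            ("signal_variance", self.signal_variance),
            ("noise_variance", self.noise_variance),
            ("alpha", self.alpha),
        ):
            if v < 0 or (name != "noise_variance" and v == 0):
                raise ValueError(f"{name} must be positive")
        if np.any(ls <= 0):
            raise ValueError("lengthscales must be positive")

    # ----------------------------------------------------------- packing
    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "signal_variance": float(self.signal_variance),
            "lengthscales": [float(x) for x in self.lengthscales],
            "noise_variance": float(self.noise_variance),
            "alpha": float(self.alpha),
        }
        if self.periods is not None:
            d["periods"] = [float(x) for x in self.periods]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(
            family=d["family"],
            signal_variance=d["signal_variance"],
            lengthscales=np.asarray(d["lengthscales"]),
            noise_variance=d["noise_variance"],
            alpha=d.get("alpha", 2.0),
            periods=np.asarray(d["periods"]) if "periods" in d else None,
        )


def _scaled_sqdist(x1: np.ndarray, x2: np.ndarray, ls: np.ndarray) -> np.ndarray:
    a = x1 / ls
    b = x2 / ls
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def kernel_matrix(spec: KernelSpec, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Cross-covariance matrix K[i, j] = k(x1[i], x2[j])."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[1] != x2.shape[1]:
        raise ValueError(f"dimension mismatch: {x1.shape[1]} vs {x2.shape[1]}")
    s2 = spec.signal_variance
    fam = spec.family
    if fam in ("matern32_ard", "matern52_ard", "rq_ard", "se_ard"):
        ls = spec.lengthscales
        if len(ls) != x1.shape[1]:
            raise ValueError("ARD lengthscale dimensionality mismatch")
        r = _scaled_sqdist(x1, x2, ls)
        if fam == "se_ard":
            return s2 * np.exp(-r / 2.0)
        if fam == "rq_ard":
            return s2 * (1.0 + r / (2.0 * spec.alpha)) ** (-spec.alpha)
        sr = np.sqrt(np.maximum(r, 0.0))
        if fam == "matern32_ard":
            z = np.sqrt(3.0) * sr
            return s2 * (1.0 + z) * np.exp(-z)
        z = np.sqrt(5.0) * sr
        return s2 * (1.0 + z + 5.0 * r / 3.0) * np.exp(-z)
    if fam == "rq_iso":
        r = _scaled_sqdist(x1, x2, spec.lengthscales[:1])
        return s2 * (1.0 + r / (2.0 * spec.alpha)) ** (-spec.alpha)
    if fam == "gabor_ard":
        ls = spec.lengthscales
        p = spec.periods
        if p is None or len(p) != x1.shape[1] or len(ls) != x1.shape[1]:
            raise ValueError("gabor kernel needs per-dimension lengthscales and periods")
        t = x1[:, None, :] - x2[None, :, :]
        env = np.exp(-np.einsum("ijk,ijk->ij", t / ls, t / ls))
        phase = np.cos(2.0 * np.pi * (t / p).sum(axis=2))
        return s2 * env * phase
    # neural_network (non-stationary arcsine kernel)
    ls = spec.lengthscales
    if len(ls) != x1.shape[1]:
        raise ValueError("ARD lengthscale dimensionality mismatch")
    w = 1.0 / ls**2
    g12 = (x1 * w) @ x2.T
    g11 = np.einsum("ij,ij->i", x1 * w, x1)
    g22 = np.einsum("ij,ij->i", x2 * w, x2)
    denom = np.sqrt(np.outer(1.0 + g11, 1.0 + g22))
    arg = np.clip(g12 / denom, -1.0, 1.0)
    return s2 * np.arcsin(arg)


def kernel_eval(spec: KernelSpec, x1: np.ndarray, x2: np.ndarray) -> float:
    """Kernel value at a single point pair."""
    return float(kernel_matrix(spec, np.atleast_2d(x1), np.atleast_2d(x2))[0, 0])


def kernel_diag(spec: KernelSpec, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if spec.family == "neural_network":
        w = 1.0 / spec.lengthscales**2
        g = np.einsum("ij,ij->i", x * w, x)
        return spec.signal_variance * np.arcsin(np.clip(g / (1.0 + g), -1.0, 1.0))
    return np.full(len(x), spec.signal_variance)


@dataclass
class GPModel:
    """A trained GP: kernel, training data, and cached Cholesky factors."""

    kernel: KernelSpec
    train_inputs: np.ndarray
    train_outputs: np.ndarray
    mean_constant: float
    _chol: tuple | None = field(default=None, repr=False, compare=False)
    _alpha: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.train_inputs = np.atleast_2d(np.asarray(self.train_inputs, dtype=float))
        self.train_outputs = np.asarray(self.train_outputs, dtype=float).ravel()
        if len(self.train_inputs) != len(self.train_outputs):
            raise ValueError("inputs/outputs count mismatch")

    def _factorize(self):
        if self._chol is None:
            K = kernel_matrix(self.kernel, self.train_inputs, self.train_inputs)
            K[np.diag_indices_from(K)] += self.kernel.noise_variance + JITTER
            self._chol = cho_factor(K, lower=True)
            y = self.train_outputs - self.mean_constant
            self._alpha = cho_solve(self._chol, y)
        return self._chol, self._alpha

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel.to_dict(),
            "train_inputs": self.train_inputs.tolist(),
            "train_outputs": self.train_outputs.tolist(),
            "mean_constant": float(self.mean_constant),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPModel":
        return cls(
            kernel=KernelSpec.from_dict(d["kernel"]),
            train_inputs=np.asarray(d["train_inputs"]),
            train_outputs=np.asarray(d["train_outputs"]),
            mean_constant=d["mean_constant"],
        )


def nlml(model: GPModel) -> float:
    """Negative log marginal likelihood of the centered training outputs."""
    n = len(model.train_outputs)
    K = kernel_matrix(model.kernel, model.train_inputs, model.train_inputs)
    K[np.diag_indices_from(K)] += model.kernel.noise_variance + JITTER
    try:
        c, low = cho_factor(K, lower=True)
    except LinAlgError as e:
        raise RuntimeError(
            "Gram matrix not positive definite after jitter; "
            "kernel hyperparameters are ill-conditioned"
        ) from e
    y = model.train_outputs - model.mean_constant
    alpha = cho_solve((c, low), y)
    return float(
        0.5 * y @ alpha + np.sum(np.log(np.diag(c))) + 0.5 * n * np.log(2.0 * np.pi)
    )


def predict(model: GPModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at one or many test points.

    Returns scalars for a single point, arrays for a batch; variances are
    clipped at zero against round-off.
    """
    single = np.asarray(x).ndim == 1
    xs = np.atleast_2d(np.asarray(x, dtype=float))
    chol, alpha = model._factorize()
    ks = kernel_matrix(model.kernel, xs, model.train_inputs)
    mu = model.mean_constant + ks @ alpha
    v = cho_solve(chol, ks.T)
    var = kernel_diag(model.kernel, xs) - np.einsum("ij,ji->i", ks, v)
    var = np.maximum(var, 0.0)
    if single:
        return float(mu[0]), float(var[0])
    return mu, var


# -------------------------------------------------------------- training

def _pack(spec: KernelSpec, fit_noise: bool = True) -> np.ndarray:
    parts = [np.log([spec.signal_variance]), np.log(spec.lengthscales)]
    if spec.family in ("rq_ard", "rq_iso"):
        parts.append(np.log([spec.alpha]))
    if spec.family == "gabor_ard":
        parts.append(np.log(spec.periods))
    if fit_noise:
        parts.append(np.log([spec.noise_variance + 1e-300]))
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, template: KernelSpec, fit_noise: bool = True) -> KernelSpec:
    v = np.exp(theta)
    i = 0
    sig = v[i]; i += 1
    d = len(template.lengthscales)
    ls = v[i:i + d]; i += d
    alpha = template.alpha
    periods = template.periods
    if template.family in ("rq_ard", "rq_iso"):
        alpha = v[i]; i += 1
    if template.family == "gabor_ard":
        periods = v[i:i + d]; i += d
    noise = v[i] if fit_noise else template.noise_variance
    return replace(
        template, signal_variance=sig, lengthscales=ls, alpha=alpha,
        periods=periods, noise_variance=noise,
    )


def default_spec(
    family: str, inputs: np.ndarray, outputs: np.ndarray
) -> KernelSpec:
    """Data-scaled initial hyperparameters for a kernel family."""
    inputs = np.atleast_2d(inputs)
    d = inputs.shape[1]
    span = np.ptp(inputs, axis=0)
    span = np.where(span > 0, span, 1.0)
    var_y = float(np.var(outputs))
    if var_y <= 0:
        var_y = 1.0
    ls = span / 2.0 if family != "rq_iso" else np.array([float(np.mean(span)) / 2.0])
    periods = 2.0 * span if family == "gabor_ard" else None
    return KernelSpec(
        family=family,
        signal_variance=var_y,
        lengthscales=ls,
        noise_variance=0.1 * var_y,
        alpha=2.0,
        periods=periods,
    )


def train_gp(
    family: str | KernelSpec,
    inputs: np.ndarray,
    outputs: np.ndarray,
    seed: int,
    restarts: int = 3,
    maxiter: int = 80,
    fixed_noise: float | None = None,
) -> GPModel:
    """Fit kernel hyperparameters by multi-restart NLML minimization.

    ``family`` may be a family name (data-scaled initialization) or a
    KernelSpec to warm-start from.  ``fixed_noise`` pins the noise variance
    (e.g. to an empirical estimate, or near zero for a noiseless objective)
    instead of learning it.  Deterministic given the seed; the returned
    model's NLML is no worse than at any restart's initialization.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    outputs = np.asarray(outputs, dtype=float).ravel()
    if len(inputs) < 2:
        raise ValueError("need at least 2 training points")
    if isinstance(family, KernelSpec):
        template = family
    else:
        template = default_spec(family, inputs, outputs)
    fit_noise = fixed_noise is None
    if not fit_noise:
        template = replace(template, noise_variance=float(fixed_noise))
    mean_c = float(np.mean(outputs))
    rng = np.random.default_rng(seed)

    def obj(theta):
        spec = _unpack(theta, template, fit_noise)
        try:
            return nlml(GPModel(spec, inputs, outputs, mean_c))
        except (RuntimeError, FloatingPointError):
            return 1e30

    theta0 = _pack(template, fit_noise)
    bounds = [(t - 14.0, t + 14.0) for t in _pack(default_spec(
        template.family, inputs, outputs), fit_noise)]
    best_theta, best_val = theta0, obj(theta0)
    failures = []
    for i in range(restarts):
        start = theta0 if i == 0 else theta0 + rng.normal(0.0, 1.0, size=theta0.shape)
        try:
            res = minimize(
                obj, start, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter},
            )
        except Exception as e:  # pragma: no cover - optimizer internals
            failures.append(str(e))
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best_theta, best_val = res.x, res.fun
    if not np.isfinite(best_val):
        raise RuntimeError(f"all training restarts failed: {failures}")
    return GPModel(_unpack(best_theta, template, fit_noise), inputs, outputs, mean_c)
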