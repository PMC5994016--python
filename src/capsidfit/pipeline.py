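"""Run configuration, ground-truth generation, and pipeline assembly.

A :class:`RunConfig` is a flat, YAML-serializable description of one
inference run: the simulator and its thermodynamic settings, the subunit
form-factor source, the measurement grid, and the search-budget settings.
``make_ground_truth`` produces the synthetic experiment the search fits to;
``build_eval_config`` and ``build_search_config`` assemble the objective and
optimizer from the same description, so the whole pipeline is reproducible
from one file and one seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .geometry import SpeciesTable, build_dodecahedron, enumerate_species
from .kinetics import (
    RateParameters,
    StochasticParams,
    Trajectory,
    expand_parameters,
    integrate_ode,
    project_parameters,
    run_ssa,
)
from .objective import EvaluationConfig, align_candidate
from .optimize import SearchConfig
from .scattering import (
    FormFactorProfile,
    ScatteringExperiment,
    SpeciesGeometry,
    default_q_grid,
    load_form_factor,
    sphere_form_factor,
    trajectory_to_experiment,
)

__all__ = ["RunConfig", "PRESETS", "make_ground_truth", "build_eval_config",
           "build_search_config", "build_world"]


@dataclass
class RunConfig:
    """One documented schema for a full inference run."""

    mode: str = "ode"  # "ode" | "ssa"
    grouping: str = "paired6"  # "paired6" | "full12"
    ground_truth_rates: list[float] = field(default_factory=lambda: [100.0] * 6)
    delta_G: float = 4.0
    RT: float = 1.0
    symmetry: int = 5
    subunit_copies: int = 100_000
    volume: float = 1e-15
    capsid_radius: float = 100.0
    form_factor: str = "sphere"  # "sphere" or a CRYSOL .int path
    sphere_radius: float = 30.0
    q_max: float = 0.5
    q_step: float = 0.01
    time_spacing: str = "log"  # "log" | "linear"
    t_min: float = 1.0
    t_max: float = 10_000.0
    n_times: int = 26
    replicates: int = 1
    # search settings
    radius: float = 10.0
    kernel_families: list[str] = field(default_factory=lambda: [
        "matern32_ard", "matern52_ard", "rq_ard", "rq_iso",
        "gabor_ard", "neural_network", "se_ard",
    ])
    kappa_values: list[float] = field(default_factory=lambda: [0.5, 2.0, 5.0])
    initial_points: int = 50
    rounds: int = 10
    af_samples: int = 1500
    af_repeats: int = 2
    cloud_shrink: float = 0.7
    n_best_clouds: int = 3
    log_objective: bool = True
    reeval_pool: int = 50
    reeval_cap: int = 16
    seed: int = 0
    out_dir: str = "runs"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def sample_times(self) -> np.ndarray:
        if self.time_spacing == "log":
            return np.concatenate(
                [[0.0], np.geomspace(self.t_min, self.t_max, self.n_times - 1)]
            )
        return np.linspace(0.0, self.t_max, self.n_times)

    def q_grid(self) -> np.ndarray:
        n = int(round(self.q_max / self.q_step)) + 1
        return np.round(np.arange(n) * self.q_step, 10)

    def stoch(self) -> StochasticParams:
        return StochasticParams(volume=self.volume, subunit_copies=self.subunit_copies)

    def ground_truth_params(self) -> RateParameters:
        return expand_parameters(
            np.asarray(self.ground_truth_rates, dtype=float), self.grouping,
            self.delta_G, self.RT, self.symmetry,
        )


#: named presets mirroring the published experiment designs plus a desk-scale one
PRESETS: dict[str, dict] = {
    # small stochastic search: radius 3 logs, 100 initial points, 300 replicates
    "ssa-small": dict(mode="ssa", radius=3.0, initial_points=100, replicates=300,
                      rounds=2),
    # large stochastic search: radius 9 logs, 71 initial points, 100 replicates
    "ssa-large": dict(mode="ssa", radius=9.0, initial_points=71, replicates=100,
                      rounds=20),
    # deterministic searches: radius 100, 200 initial points, 100 rounds
    "ode6": dict(mode="ode", grouping="paired6", radius=100.0,
                 initial_points=200, rounds=100),
    "ode12": dict(mode="ode", grouping="full12", radius=100.0,
                  ground_truth_rates=[100.0] * 12, initial_points=200, rounds=100),
    # desk-scale deterministic recovery run
    "ode6-desk": dict(mode="ode", grouping="paired6", radius=10.0,
                      initial_points=50, rounds=10),
}


def preset(name: str, **overrides) -> RunConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return RunConfig(**{**PRESETS[name], **overrides})


@dataclass
class World:
    """The static pieces shared by every objective evaluation of a run."""

    table: SpeciesTable
    geometry: SpeciesGeometry
    form_factor: FormFactorProfile


def build_world(config: RunConfig) -> World:
    table = enumerate_species(build_dodecahedron())
    geometry = SpeciesGeometry.from_table(table, radius=config.capsid_radius)
    q = config.q_grid()
    if config.form_factor == "sphere":
        ff = sphere_form_factor(q, radius=config.sphere_radius)
    else:
        ff = load_form_factor(config.form_factor, q_grid=q)
    return World(table=table, geometry=geometry, form_factor=ff)


def simulate_truth_trajectory(config: RunConfig, world: World) -> Trajectory:
    params = config.ground_truth_params()
    times = config.sample_times()
    if config.mode == "ode":
        init = np.zeros(len(world.table.labels))
        init[world.table.index()[(1, 1)]] = config.stoch().concentration()
        return integrate_ode(world.table, params, init, times)
    return run_ssa(world.table, params, config.stoch(), float(times[-1]),
                   seed=config.seed)


def make_ground_truth(
    config: RunConfig, world: World | None = None, out_dir: str | Path | None = None
) -> tuple[ScatteringExperiment, dict]:
    """Simulate the designated ground-truth point and synthesize its experiment.

    Returns the experiment and a manifest recording parameters, seed, and
    version; when ``out_dir`` is given, writes ``ground_truth.tsv`` and
    ``manifest.json`` there.
    """
    world = world or build_world(config)
    times = config.sample_times()
    traj = simulate_truth_trajectory(config, world)
    states = traj.states if config.mode == "ode" else align_candidate(times, traj)
    experiment = trajectory_to_experiment(
        states, world.table, world.geometry, world.form_factor, times
    )
    manifest = {
        "version": __version__,
        "mode": config.mode,
        "grouping": config.grouping,
        "ground_truth_rates": list(map(float, config.ground_truth_rates)),
        "delta_G": config.delta_G,
        "RT": config.RT,
        "symmetry": config.symmetry,
        "subunit_copies": config.subunit_copies,
        "volume": config.volume,
        "seed": config.seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            experiment.to_tsv(out / "ground_truth.tsv")
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
        except OSError as e:
            raise OSError(f"cannot write ground truth under {out}: {e}") from e
    return experiment, manifest


def build_eval_config(
    config: RunConfig,
    world: World,
    ground_truth: ScatteringExperiment,
    trace_path: str | Path | None = None,
) -> EvaluationConfig:
    wait_gt = None
    if config.mode == "ssa":
        stoch = config.stoch()
        rates_free = np.asarray(config.ground_truth_rates, dtype=float)
        wait_gt = stoch.avogadro * stoch.volume / rates_free
    return EvaluationConfig(
        mode=config.mode,
        table=world.table,
        geometry=world.geometry,
        form_factor=world.form_factor,
        ground_truth=ground_truth,
        grouping=config.grouping,
        delta_G=config.delta_G,
        RT=config.RT,
        symmetry=config.symmetry,
        replicates=config.replicates,
        stoch=config.stoch(),
        wait_times_gt=wait_gt,
        trace_path=trace_path,
    )


def build_search_config(config: RunConfig) -> SearchConfig:
    if config.mode == "ode":
        center = np.asarray(config.ground_truth_rates, dtype=float)
    else:
        center = np.zeros(len(config.ground_truth_rates))
    return SearchConfig(
        center=center,
        radius=config.radius,
        kernel_families=tuple(config.kernel_families),
        kappa_values=tuple(config.kappa_values),
        initial_points=config.initial_points,
        replicates_per_point=config.replicates,
        rounds=config.rounds,
        af_samples=config.af_samples,
        af_repeats=config.af_repeats,
        cloud_shrink=config.cloud_shrink,
        n_best_clouds=config.n_best_clouds,
        log_objective=config.log_objective,
        reeval_pool=config.reeval_pool,
        reeval_cap=config.reeval_cap,
        seed=config.seed,
    )
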