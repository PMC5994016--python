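"""Synthetic time-resolved small-angle scattering from assembly trajectories.

The measured intensity of a dilute solution of assembly intermediates is the
sum of the per-species contributions

    I(q, t) = sum_s  n_s(t) * I_sub(q) * N_s * S_s(q)

where I_sub(q) = drho^2 V^2 |F(q)|^2 is the single-subunit scattering (read
from a CRYSOL ``.int`` profile or generated analytically), N_s the number of
subunits in species s, and S_s(q) the orientationally averaged (Debye)
structure factor of the rigid subunit arrangement.  The product N_s * S_s(q)
is the un-normalized Debye double sum, so a rigid N-mer scatters N^2 times a
single subunit in the coherent q -> 0 limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import SpeciesTable
from .kinetics import Trajectory

__all__ = [
    "FormFactorProfile",
    "SpeciesGeometry",
    "ScatteringExperiment",
    "default_q_grid",
    "load_form_factor",
    "sphere_form_factor",
    "structure_factor",
    "trajectory_to_experiment",
]

logger = logging.getLogger(__name__)


def default_q_grid() -> np.ndarray:
    """q from 0 to 0.5 inverse angstroms in steps of 0.01 (51 points)."""
    return np.round(np.arange(0, 51) * 0.01, 10)


@dataclass(frozen=True)
class FormFactorProfile:
    """Single-subunit scattering intensity drho^2 V^2 |F(q)|^2 on a q grid."""

    q_grid: np.ndarray
    subunit_intensity: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q_grid, dtype=float)
        i = np.asarray(self.subunit_intensity, dtype=float)
        if q.shape != i.shape:
            raise ValueError("q grid and intensity must have equal length")
        if np.any(np.diff(q) <= 0) or q[0] < 0:
            raise ValueError("q grid must be ascending and non-negative")
        if np.any(i < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "q_grid", q)
        object.__setattr__(self, "subunit_intensity", i)


def sphere_form_factor(
    q_grid: np.ndarray, radius: float, contrast_volume: float = 1.0
) -> FormFactorProfile:
    """Analytic uniform-sphere profile: drho^2 V^2 [3 j1(qR)/(qR)]^2.

    A stand-in subunit profile used when no CRYSOL output is supplied;
    contrast_volume is the drho^2 V^2 prefactor (the q -> 0 intensity).
    """
    if radius <= 0:
        raise ValueError("sphere radius must be positive")
    q = np.asarray(q_grid, dtype=float)
    x = q * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    amp = np.where(x == 0.0, 1.0, amp)
    return FormFactorProfile(q, contrast_volume * amp**2)


def load_form_factor(
    source: str | Path, q_grid: np.ndarray | None = None
) -> FormFactorProfile:
    """Read a CRYSOL ``.int`` profile (whitespace columns, one header line).

    Column 1 is q, column 2 the total intensity in solution; remaining
    columns are ignored.  When ``q_grid`` differs from the file grid the
    profile is linearly resampled with a logged warning.
    """
    path = Path(source)
    qs, intens = [], []
    with open(path) as fh:
        lines = fh.readlines()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: line {ln}: expected >= 2 columns")
        try:
            qs.append(float(parts[0]))
            intens.append(float(parts[1]))
        except ValueError as e:
            raise ValueError(f"{path}: line {ln}: non-numeric field") from e
    q = np.array(qs)
    i = np.array(intens)
    if q_grid is not None and (len(q_grid) != len(q) or not np.allclose(q_grid, q)):
        logger.warning(
            "resampling form factor from %d-point file grid to %d-point request",
            len(q), len(q_grid),
        )
        i = np.interp(q_grid, q, i)
        q = np.asarray(q_grid, dtype=float)
    return FormFactorProfile(q, np.clip(i, 0.0, None))


@dataclass(frozen=True)
class SpeciesGeometry:
    """Subunit centroid positions (angstroms) for every species in a table.

    Positions are the dodecahedron face centroids scaled to ``radius``; the
    pairwise distance multiset is rotation-invariant, so any isomorphic
    representative yields the same scattering.
    """

    positions: dict[tuple[int, int], np.ndarray]
    radius: float

    @classmethod
    def from_table(cls, table: SpeciesTable, radius: float = 100.0) -> "SpeciesGeometry":
        if radius <= 0:
            raise ValueError("capsid radius must be positive")
        cents = table.model.centroids
        positions = {
            lab: radius * cents[np.array(sorted(o.faces)) - 1]
            for lab, o in table.species.items()
        }
        return cls(positions=positions, radius=radius)


def structure_factor(positions: np.ndarray, q: float | np.ndarray) -> np.ndarray | float:
    """Debye orientation-averaged structure factor of a rigid point set.

    S(q) = (1/N) sum_{j,k} sinc(q * |R_j - R_k|), with sinc(0) = 1; the
    isotropic average of the pairwise phase sum over all orientations of the
    particle relative to the beam.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    q = np.asarray(q, dtype=float)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    x = q[..., None, None] * d  # broadcast q over the distance matrix
    s = np.sinc(x / np.pi).sum(axis=(-2, -1)) / n
    return float(s) if s.ndim == 0 else s


def debye_sums(geom: SpeciesGeometry, labels, q_grid: np.ndarray) -> np.ndarray:
    """Un-normalized Debye double sums N_s * S_s(q), one row per species."""
    out = np.empty((len(labels), len(q_grid)))
    for i, lab in enumerate(labels):
        pos = geom.positions[lab]
        out[i] = len(pos) * structure_factor(pos, q_grid)
    return out


@dataclass
class ScatteringExperiment:
    """A time x q intensity matrix."""

    times: np.ndarray
    q_grid: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.times), len(self.q_grid)):
            raise ValueError(
                f"intensity shape {self.intensity.shape} inconsistent with "
                f"{len(self.times)} times x {len(self.q_grid)} q values"
            )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time\t" + "\t".join(repr(float(q)) for q in self.q_grid) + "\n")
            for t, row in zip(self.times, self.intensity):
                fh.write(
                    repr(float(t)) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScatteringExperiment":
        with open(path) as fh:
            header = fh.readline().split("\t")
            q = np.array([float(x) for x in header[1:]])
            rows = [[float(x) for x in line.split("\t")] for line in fh if line.strip()]
        arr = np.array(rows)
        return cls(times=arr[:, 0], q_grid=q, intensity=arr[:, 1:])


def trajectory_to_experiment(
    states: np.ndarray | Trajectory,
    table: SpeciesTable,
    geom: SpeciesGeometry,
    ff: FormFactorProfile,
    sample_times: np.ndarray,
) -> ScatteringExperiment:
    """Project species abundances onto a dilute-solution scattering experiment.

    ``states`` is either a (time x species) abundance matrix already aligned
    with ``sample_times`` or a Trajectory whose times coincide with them.
    """
    if isinstance(states, Trajectory):
        if states.states.shape[0] != len(sample_times):
            raise ValueError("trajectory not aligned with sample_times; align first")
        labels = states.labels
        states = states.states
    else:
        labels = table.labels
    if states.shape[1] != len(labels):
        raise ValueError("state matrix does not match the species table")
    missing = [lab for lab in labels if lab not in geom.positions]
    if missing:
        raise ValueError(f"unknown species ids {missing[:3]} in geometry")
    per_species = ff.subunit_intensity[None, :] * debye_sums(geom, labels, ff.q_grid)
    intensity = states @ per_species
    return ScatteringExperiment(
        times=np.asarray(sample_times, dtype=float), q_grid=ff.q_grid, intensity=intensity
    )
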