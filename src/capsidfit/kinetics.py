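"""Deterministic and stochastic kinetics of the dodecamer assembly network.

The reaction network is generated from a :class:`~capsidfit.geometry.SpeciesTable`:
only monomer/monomer and monomer/oligomer reactions exist (m = j + 1).  The
deterministic model evolves molar concentrations [j,k](t) with, for each
monomer-addition edge (j,k) -> (m,n),

    forward flux  = k_on[j] * a * O * [j,k][1,1]
    backward flux = k_on[j] * b * s * [m,n],    s = exp(-dG * (c_mn - c_jk) / RT)

where a/b are the forward/backward degeneracies, O the monomer symmetry number
(5 for a pentagonal subunit), c the internal bond counts, and k_on[j] the
per-size association rate (the j -> j+1 step owns rate index j; index 12 is
inert padding kept for dimensional parity of the 12-parameter search space).
The stability factor s sets the equilibrium of each step; with this sign
convention a positive dG is the free-energy penalty for breaking one bond, so
favorable binding means dG > 0.

The stochastic counterpart is an exact direct-method Gillespie simulation of
the same network with molar rates converted to per-count propensities via the
system volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .geometry import SpeciesTable

__all__ = [
    "AVOGADRO",
    "RateParameters",
    "StochasticParams",
    "Trajectory",
    "ReactionNetwork",
    "stability",
    "ode_rhs",
    "integrate_ode",
    "run_ssa",
    "convert_rates",
    "expand_parameters",
]

AVOGADRO = 6.02214076e23

GROUPINGS = ("full12", "paired6")


@dataclass(frozen=True)
class RateParameters:
    """Kinetic parameters of the assembly network.

    on_rates[i-1] is the molar association rate constant (1/M/s) for monomer
    addition to an i-mer; entry 12 has no forward reaction and is inert.
    delta_G and RT share units (e.g. kJ/mol); delta_G > 0 means stable bonds
    under the stability convention of this module.
    """

    on_rates: np.ndarray
    delta_G: float = 5.0
    RT: float = 1.0
    symmetry: int = 5
    grouping: str = "full12"

    def __post_init__(self):
        rates = np.asarray(self.on_rates, dtype=float)
        object.__setattr__(self, "on_rates", rates)
        if rates.shape != (12,):
            raise ValueError(f"on_rates must have length 12, got {rates.shape}")
        if np.any(rates <= 0):
            raise ValueError("all on_rates must be positive")
        if self.RT <= 0:
            raise ValueError("RT must be positive")
        if self.symmetry < 1:
            raise ValueError("symmetry must be >= 1")
        if self.grouping not in GROUPINGS:
            raise ValueError(f"grouping must be one of {GROUPINGS}")
        if self.grouping == "paired6":
            pairs = rates.reshape(6, 2)
            if not np.allclose(pairs[:, 0], pairs[:, 1]):
                raise ValueError("paired6 grouping requires equal rates within size pairs")


@dataclass(frozen=True)
class StochasticParams:
    """Discrete-simulation settings: volume, copy number, log-coordinates.

    Wait times T and log coordinates x relate to ground-truth wait times by
    T = 10 ** (log10(T_GT) + x); x = 0 is the ground-truth point.
    """

    volume: float = 1e-15
    avogadro: float = AVOGADRO
    subunit_copies: int = 1000

    def concentration(self) -> float:
        """Initial monomer concentration (M) implied by copies and volume."""
        return self.subunit_copies / (self.avogadro * self.volume)


@dataclass
class Trajectory:
    """Time-stamped species abundances, aligned with a SpeciesTable.

    states[t] holds integer counts (kind="ssa") or molar concentrations
    (kind="ode") in the order of ``labels``.
    """

    kind: str
    times: np.ndarray
    states: np.ndarray
    labels: list[tuple[int, int]]

    def mass(self) -> np.ndarray:
        """Total subunit mass (size-weighted abundance) at each time."""
        sizes = np.array([j for j, _ in self.labels], dtype=float)
        return self.states @ sizes

    def to_tsv(self, path: str | Path) -> None:
        cols = ["time"] + [f"({j},{k})" for j, k in self.labels]
        df = pd.DataFrame(
            np.column_stack([self.times, self.states]), columns=cols
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        labels = [tuple(int(x) for x in c.strip("()").split(",")) for c in df.columns[1:]]
        return cls(
            kind=kind,
            times=df["time"].to_numpy(),
            states=df.iloc[:, 1:].to_numpy(),
            labels=labels,  # type: ignore[arg-type]
        )


def stability(c_jk: int, c_mn: int, params: RateParameters) -> float:
    """Boltzmann stability factor exp(-dG * (c_mn - c_jk) / RT).

    Multiplies the dissociation flux of the (m,n) -> (j,k) step; small values
    (favorable bonds, dG > 0) make dissociation slow.
    """
    if params.RT <= 0:
        raise ValueError("RT must be positive")
    if c_jk < 0 or c_mn < 0:
        raise ValueError("bond counts must be non-negative")
    return float(np.exp(-params.delta_G * (c_mn - c_jk) / params.RT))


@dataclass
class ReactionNetwork:
    """Vectorized reaction arrays compiled from a SpeciesTable."""

    labels: list[tuple[int, int]]
    monomer_index: int
    reactant: np.ndarray  # species index of (j,k)
    product: np.ndarray  # species index of (m,n)
    size: np.ndarray  # j (rate index of the step)
    a: np.ndarray
    b: np.ndarray
    delta_bonds: np.ndarray  # c_mn - c_jk
    sizes: np.ndarray  # per-species size vector

    @classmethod
    def from_table(cls, table: SpeciesTable) -> "ReactionNetwork":
        labels = table.labels
        index = table.index()
        reactions = table.reactions()
        return cls(
            labels=labels,
            monomer_index=index[(1, 1)],
            reactant=np.array([index[s] for s, _, _, _ in reactions]),
            product=np.array([index[d] for _, d, _, _ in reactions]),
            size=np.array([s[0] for s, _, _, _ in reactions]),
            a=np.array([a for _, _, a, _ in reactions], dtype=float),
            b=np.array([b for _, _, _, b in reactions], dtype=float),
            delta_bonds=np.array(
                [table.bond_counts[d] - table.bond_counts[s] for s, d, _, _ in reactions],
                dtype=float,
            ),
            sizes=np.array([j for j, _ in labels], dtype=float),
        )

    def rate_vectors(self, params: RateParameters) -> tuple[np.ndarray, np.ndarray]:
        """(forward prefactor k*a*O, backward prefactor k*b*s) per reaction."""
        k = params.on_rates[self.size - 1]
        s = np.exp(-params.delta_G * self.delta_bonds / params.RT)
        return k * self.a * params.symmetry, k * self.b * s


def ode_rhs(state: np.ndarray, table_or_net: SpeciesTable | ReactionNetwork,
            params: RateParameters) -> np.ndarray:
    """Concentration time-derivative of the full assembly network.

    Gain/loss terms are assembled per monomer-addition edge; every reaction
    conserves subunit mass, so the size-weighted derivative sum is zero.
    """
    net = (
        table_or_net
        if isinstance(table_or_net, ReactionNetwork)
        else ReactionNetwork.from_table(table_or_net)
    )
    state = np.asarray(state, dtype=float)
    if state.shape != (len(net.labels),):
        raise ValueError(
            f"state length {state.shape} does not match species count {len(net.labels)}"
        )
    fwd_pref, bwd_pref = net.rate_vectors(params)
    m0 = state[net.monomer_index]
    flux = fwd_pref * state[net.reactant] * m0 - bwd_pref * state[net.product]
    dy = np.zeros_like(state)
    np.add.at(dy, net.product, flux)
    np.subtract.at(dy, net.reactant, flux)
    dy[net.monomer_index] -= flux.sum()
    return dy


def _ode_jacobian(net: ReactionNetwork, params: RateParameters):
    fwd_pref, bwd_pref = net.rate_vectors(params)
    n = len(net.labels)
    m0i = net.monomer_index

    def jac(t, y):
        J = np.zeros((n, n))
        m0 = y[m0i]
        for r in range(len(fwd_pref)):
            u, v = net.reactant[r], net.product[r]
            # d flux / d y[u], d y[m0], d y[v]
            du = fwd_pref[r] * m0
            dm = fwd_pref[r] * y[u]
            dv = -bwd_pref[r]
            for col, g in ((u, du), (m0i, dm), (v, dv)):
                J[v, col] += g
                J[u, col] -= g
                J[m0i, col] -= g
        return J

    return jac


def integrate_ode(
    table: SpeciesTable,
    params: RateParameters,
    init: np.ndarray,
    sample_times: np.ndarray,
    rtol: float = 1e-8,
    atol: float | None = None,
) -> Trajectory:
    """Adaptive stiff integration evaluated exactly at ``sample_times``."""
    sample_times = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(sample_times) <= 0) or sample_times[0] < 0:
        raise ValueError("sample_times must be ascending and non-negative")
    net = ReactionNetwork.from_table(table)
    init = np.asarray(init, dtype=float)
    if atol is None:
        atol = rtol * max(init.max(), 1e-30) * 1e-3
    t0 = 0.0
    t1 = float(sample_times[-1]) if sample_times[-1] > 0 else 1.0
    sol = solve_ivp(
        lambda t, y: ode_rhs(y, net, params),
        (t0, t1),
        init,
        method="BDF",
        jac=_ode_jacobian(net, params),
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed at t={sol.t[-1]}: {sol.message}")
    states = sol.sol(sample_times).T
    return Trajectory(kind="ode", times=sample_times, states=states, labels=net.labels)


def run_ssa(
    table: SpeciesTable,
    params: RateParameters,
    stoch: StochasticParams,
    t_max: float,
    seed: int,
) -> Trajectory:
    """Exact direct-method Gillespie simulation of the assembly network.

    Propensities use per-count rate constants c = k_molar / (N_A * volume);
    dimerization (identical reactants) uses the n*(n-1)/2 pair count with
    c = 2 * k_molar / (N_A * volume) so the large-number mean matches the
    deterministic model.  Every reaction event is recorded (the Markov state
    is constant between events).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    net = ReactionNetwork.from_table(table)
    rng = np.random.default_rng(seed)
    scale = 1.0 / (stoch.avogadro * stoch.volume)
    fwd_pref, bwd_pref = net.rate_vectors(params)
    # per-count forward constants; bimolecular scaling, doubled for A+A
    c_fwd = fwd_pref * scale
    dimer = net.reactant == net.monomer_index
    c_fwd[dimer] *= 2.0
    m0i = net.monomer_index

    n_species = len(net.labels)
    state = np.zeros(n_species, dtype=np.int64)
    state[m0i] = stoch.subunit_copies

    times = [0.0]
    states = [state.copy()]
    t = 0.0
    while True:
        n_u = state[net.reactant].astype(float)
        n_mono = float(state[m0i])
        pair = np.where(dimer, n_u * (n_u - 1) / 2.0, n_u * n_mono)
        prop_f = c_fwd * pair
        prop_b = bwd_pref * state[net.product]
        props = np.concatenate([prop_f, prop_b])
        total = props.sum()
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        r = int(rng.choice(len(props), p=props / total))
        nr = len(prop_f)
        if r < nr:  # association
            u, v = net.reactant[r], net.product[r]
            state[u] -= 1
            state[m0i] -= 1
            state[v] += 1
        else:  # dissociation
            r -= nr
            u, v = net.reactant[r], net.product[r]
            state[v] -= 1
            state[u] += 1
            state[m0i] += 1
        times.append(t)
        states.append(state.copy())
    return Trajectory(
        kind="ssa", times=np.array(times), states=np.array(states), labels=net.labels
    )


def convert_rates(
    value: float | np.ndarray,
    mode: str,
    stoch: StochasticParams | None = None,
    inverse: bool = False,
) -> float | np.ndarray:
    """Convert between expected wait times T and rate constants k.

    mode="uni": T = 1/k (and k = 1/T — the map is an involution).
    mode="bi": k_molar = N_A * volume / T_bi; ``inverse`` maps back.
    """
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0):
        raise ValueError("rates and wait times must be positive")
    if mode == "uni":
        out = 1.0 / value
    elif mode == "bi":
        if stoch is None:
            raise ValueError("bimolecular conversion requires StochasticParams")
        out = stoch.avogadro * stoch.volume / value  # involution as well
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def log_coords_to_wait_times(x: np.ndarray, wait_times_gt: np.ndarray) -> np.ndarray:
    """T = 10 ** (log10(T_GT) + x); x = 0 recovers the ground truth."""
    x = np.asarray(x, dtype=float)
    wait_times_gt = np.asarray(wait_times_gt, dtype=float)
    return 10.0 ** (np.log10(wait_times_gt) + x)


def expand_parameters(
    free_vector: np.ndarray,
    grouping: str = "full12",
    delta_G: float = 5.0,
    RT: float = 1.0,
    symmetry: int = 5,
) -> RateParameters:
    """Build RateParameters from a 6- or 12-dimensional search vector.

    paired6 duplicates each entry into its size pair {1,2},{3,4},...,{11,12};
    full12 is the identity embedding.
    """
    v = np.asarray(free_vector, dtype=float)
    if grouping == "paired6":
        if v.shape != (6,):
            raise ValueError(f"paired6 expects 6 entries, got {v.shape}")
        rates = np.repeat(v, 2)
    elif grouping == "full12":
        if v.shape != (12,):
            raise ValueError(f"full12 expects 12 entries, got {v.shape}")
        rates = v.copy()
    else:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    if np.any(rates <= 0):
        raise ValueError("rate entries must be positive")
    return RateParameters(
        on_rates=rates, delta_G=delta_G, RT=RT, symmetry=symmetry, grouping=grouping
    )


def project_parameters(params: RateParameters) -> np.ndarray:
    """Inverse of expand_parameters: the free vector of a RateParameters."""
    if params.grouping == "paired6":
        return params.on_rates[::2].copy()
    return params.on_rates.copy()
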