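"""Dodecahedron geometry, rotational isomorphism, and intermediate enumeration.

The model capsid is a dodecamer: 12 pentagonal subunits occupying the faces
of a regular dodecahedron.  A partial assembly (oligomer) is a non-empty,
edge-connected subset of faces.  Two oligomers are the same chemical species
when a proper rotation of the dodecahedron maps one face set onto the other,
so the state space of the assembly network is the set of rotation orbits of
connected face subsets.  This module builds the polyhedron, its 60-element
rotation group, the pairwise isomorphism test, and the breadth-first
enumeration of all unique intermediates together with the forward/backward
reaction degeneracies of every monomer-addition edge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PolyhedronModel",
    "Oligomer",
    "SpeciesTable",
    "build_dodecahedron",
    "are_isomorphic",
    "enumerate_species",
]

#: absolute tolerance for comparing rotated centroids on the unit sphere
CENTROID_TOL = 1e-6

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class PolyhedronModel:
    """A regular dodecahedron at unit circumradius (of its face-centroid set).

    Face centroids of the dodecahedron are the vertices of an icosahedron;
    the 12 unit vectors in ``centroids`` are exactly that vertex set.

    Attributes
    ----------
    centroids : (12, 3) array of unit face-centroid coordinates.
    adjacency : dict mapping face index (1..12) to a tuple of its 5 neighbors.
    rotations : (60, 3, 3) array, the icosahedral rotation group I ⊂ SO(3).
    face_permutations : (60, 12) int array; row g maps face i (0-based) to
        ``face_permutations[g, i]`` under rotation g.
    """

    face_count: int
    edges_per_face: int
    centroids: np.ndarray
    adjacency: dict[int, tuple[int, ...]]
    rotations: np.ndarray
    face_permutations: np.ndarray

    def neighbors(self, face: int) -> tuple[int, ...]:
        return self.adjacency[face]


@dataclass(frozen=True)
class Oligomer:
    """A connected subset of dodecahedron faces (1-based indices)."""

    faces: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.faces)

    def bond_count(self, model: PolyhedronModel) -> int:
        """Number of shared edges (bonds) internal to the face subset."""
        return sum(
            1
            for a, b in itertools.combinations(sorted(self.faces), 2)
            if b in model.adjacency[a]
        )

    def is_connected(self, model: PolyhedronModel) -> bool:
        faces = self.faces
        if not faces:
            return False
        seen = {next(iter(faces))}
        stack = [next(iter(faces))]
        while stack:
            f = stack.pop()
            for g in model.adjacency[f]:
                if g in faces and g not in seen:
                    seen.add(g)
                    stack.append(g)
        return len(seen) == len(faces)


def _validate_oligomer(o: Oligomer, model: PolyhedronModel) -> None:
    if not o.faces:
        raise ValueError("oligomer is empty")
    bad = [f for f in o.faces if not 1 <= f <= model.face_count]
    if bad:
        raise ValueError(f"invalid face indices {bad}; must be 1..{model.face_count}")


def _icosahedron_vertices() -> np.ndarray:
    """12 unit vectors: cyclic permutations of (0, ±1, ±φ), normalized."""
    base = []
    for s1, s2 in itertools.product((1.0, -1.0), repeat=2):
        base.append((0.0, s1, s2 * _PHI))
        base.append((s1, s2 * _PHI, 0.0))
        base.append((s2 * _PHI, 0.0, s1))
    v = np.array(base)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    # deterministic ordering: face 1 is the lexicographically largest vector
    order = np.lexsort((v[:, 0], v[:, 1], v[:, 2]))[::-1]
    return v[order]


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _permutation_of(rot: np.ndarray, centroids: np.ndarray) -> np.ndarray | None:
    """Permutation induced by ``rot`` on the centroid set, or None."""
    mapped = centroids @ rot.T
    d = np.linalg.norm(mapped[:, None, :] - centroids[None, :, :], axis=2)
    idx = np.argmin(d, axis=1)
    if np.any(d[np.arange(len(centroids)), idx] > CENTROID_TOL):
        return None
    if len(set(idx.tolist())) != len(centroids):
        return None
    return idx


def build_dodecahedron() -> PolyhedronModel:
    """Construct the dodecamer geometry and its full rotation set.

    The 60 rotations are organized as (identity + 11 rotations placing each
    face at the reference position of face 1) composed with (identity + 4
    in-plane rotations about the face-1 axis, i.e. powers of the 2π/5 turn).
    Closure of this set under composition is the icosahedral rotation group.
    """
    cents = _icosahedron_vertices()
    n = len(cents)

    # adjacency: the 5 nearest centroids share an edge with a given face
    d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
    adjacency: dict[int, tuple[int, ...]] = {}
    for i in range(n):
        order = np.argsort(d[i])
        adjacency[i + 1] = tuple(sorted(int(j) + 1 for j in order[1:6]))

    # in-plane 5-fold rotations about the face-1 axis
    spins = [_axis_rotation(cents[0], 2.0 * np.pi * k / 5.0) for k in range(5)]

    # one representative rotation carrying face 1 to each face f: generate the
    # group by closure from the 5-fold spin and a 2-fold edge flip, then pick
    # representatives by where they send face 1
    flip_axis = cents[0] + cents[adjacency[1][0] - 1]
    generators = [spins[1], _axis_rotation(flip_axis, np.pi)]
    group: list[np.ndarray] = [np.eye(3)]
    frontier = list(group)
    while frontier:
        new_frontier = []
        for g in frontier:
            for h in generators:
                cand = h @ g
                if not any(np.allclose(cand, e, atol=CENTROID_TOL) for e in group):
                    group.append(cand)
                    new_frontier.append(cand)
        frontier = new_frontier
    if len(group) != 60:  # pragma: no cover - geometric construction invariant
        raise RuntimeError(f"rotation closure yielded {len(group)} elements, expected 60")

    placements: dict[int, np.ndarray] = {}
    for g in group:
        perm = _permutation_of(g, cents)
        assert perm is not None
        target = int(perm[0])
        if target not in placements:
            placements[target] = g

    rotations = []
    perms = []
    for f in range(n):  # face-placement representative, then the 5 spins
        base = placements[f]
        for s in spins:
            rot = base @ s
            perm = _permutation_of(rot, cents)
            assert perm is not None
            rotations.append(rot)
            perms.append(perm)

    return PolyhedronModel(
        face_count=n,
        edges_per_face=5,
        centroids=cents,
        adjacency=adjacency,
        rotations=np.array(rotations),
        face_permutations=np.array(perms, dtype=np.int64),
    )


def orbit_keys(faces: frozenset[int], model: PolyhedronModel) -> frozenset[frozenset[int]]:
    """All images of a face set under the rotation group."""
    idx = np.array(sorted(f - 1 for f in faces))
    return frozenset(
        frozenset(int(j) + 1 for j in perm[idx]) for perm in model.face_permutations
    )


def canonical_key(faces: frozenset[int], model: PolyhedronModel) -> tuple[int, ...]:
    """Lexicographically minimal sorted face tuple over the 60 rotations."""
    idx = np.array(sorted(f - 1 for f in faces))
    images = model.face_permutations[:, idx] + 1
    images.sort(axis=1)
    best = min(map(tuple, images.tolist()))
    return tuple(best)


def are_isomorphic(a: Oligomer, b: Oligomer, model: PolyhedronModel) -> bool:
    """True iff some rotation in the 60-element set maps a's faces onto b's.

    Each rotation is applied to the first oligomer and the resulting face set
    compared with the second for identity; the relation is symmetric because
    the rotation set is a group.
    """
    _validate_oligomer(a, model)
    _validate_oligomer(b, model)
    if a.size != b.size:
        return False
    target = b.faces
    idx = np.array(sorted(f - 1 for f in a.faces))
    for perm in model.face_permutations:
        if frozenset(int(j) + 1 for j in perm[idx]) == target:
            return True
    return False


@dataclass
class SpeciesTable:
    """Unique intermediates of the dodecamer network with reaction degeneracies.

    Species are labeled (j, k): the k-th unique species of size j, with k
    assigned in order of discovery.  Edges are monomer additions only
    (m = j + 1).  ``forward_degeneracy[(j,k),(m,n)] = a`` counts the distinct
    free binding sites (boundary edges) of (j,k) whose filling yields an
    oligomer isomorphic to (m,n); ``backward_degeneracy[(m,n),(j,k)] = b``
    counts the single-face removals of (m,n) leaving a connected oligomer
    isomorphic to (j,k).
    """

    species: dict[tuple[int, int], Oligomer]
    forward_degeneracy: dict[tuple[tuple[int, int], tuple[int, int]], int]
    backward_degeneracy: dict[tuple[tuple[int, int], tuple[int, int]], int]
    bond_counts: dict[tuple[int, int], int]
    model: PolyhedronModel = field(repr=False)

    @property
    def labels(self) -> list[tuple[int, int]]:
        return sorted(self.species)

    def index(self) -> dict[tuple[int, int], int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def count_by_size(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for j, _ in self.species:
            out[j] = out.get(j, 0) + 1
        return out

    def reactions(self) -> list[tuple[tuple[int, int], tuple[int, int], int, int]]:
        """Monomer-addition edges as (reactant, product, a, b)."""
        out = []
        for (src, dst), a in sorted(self.forward_degeneracy.items()):
            b = self.backward_degeneracy[(dst, src)]
            out.append((src, dst, a, b))
        return out

    # ------------------------------------------------------------------ io
    def to_tsv(self, species_path: str | Path, degeneracy_path: str | Path) -> None:
        rows = [
            {
                "size": j,
                "index": k,
                "face_list": ",".join(map(str, sorted(o.faces))),
                "bond_count": self.bond_counts[(j, k)],
            }
            for (j, k), o in sorted(self.species.items())
        ]
        pd.DataFrame(rows).to_csv(species_path, sep="\t", index=False)
        edge_rows = [
            {"j": src[0], "k": src[1], "m": dst[0], "n": dst[1], "a": a, "b": b}
            for src, dst, a, b in self.reactions()
        ]
        pd.DataFrame(edge_rows).to_csv(degeneracy_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        species_path: str | Path,
        degeneracy_path: str | Path,
        model: PolyhedronModel,
    ) -> "SpeciesTable":
        sp = pd.read_csv(species_path, sep="\t")
        species = {}
        bond_counts = {}
        for _, row in sp.iterrows():
            lab = (int(row["size"]), int(row["index"]))
            species[lab] = Oligomer(frozenset(int(x) for x in str(row["face_list"]).split(",")))
            bond_counts[lab] = int(row["bond_count"])
        dg = pd.read_csv(degeneracy_path, sep="\t")
        fwd, bwd = {}, {}
        for _, row in dg.iterrows():
            src = (int(row["j"]), int(row["k"]))
            dst = (int(row["m"]), int(row["n"]))
            fwd[(src, dst)] = int(row["a"])
            bwd[(dst, src)] = int(row["b"])
        return cls(species, fwd, bwd, bond_counts, model)


def enumerate_species(model: PolyhedronModel) -> SpeciesTable:
    """Enumerate all unique intermediates and their reaction degeneracies.

    Breadth-first growth from the size-1 species fixed to contain face 1:
    every free binding site (an edge between a member face and an absent
    neighbor) of every unique j-mer is filled by a monomer in turn; each
    generated (j+1)-mer is canonicalized by isomorphism against the stored
    species of its size, creating a new species when none matches, and the
    forward degeneracy a on that edge is incremented.  Backward degeneracies
    are computed afterwards by exhaustive single-face removal with a
    connectivity check.
    """
    monomer = Oligomer(frozenset({1}))
    species: dict[tuple[int, int], Oligomer] = {(1, 1): monomer}
    fwd: dict[tuple[tuple[int, int], tuple[int, int]], int] = {}
    # canonical-key cache accelerates lookups; are_isomorphic remains the
    # semantic definition (and the test oracle)
    canon: dict[tuple[int, ...], tuple[int, int]] = {
        canonical_key(monomer.faces, model): (1, 1)
    }

    current = [(1, 1)]
    for j in range(1, model.face_count):
        next_level: list[tuple[int, int]] = []
        for lab in current:
            olig = species[lab]
            for f in sorted(olig.faces):
                for g in sorted(model.adjacency[f]):
                    if g in olig.faces:
                        continue
                    grown = Oligomer(olig.faces | {g})
                    key = canonical_key(grown.faces, model)
                    if key in canon:
                        dst = canon[key]
                    else:
                        dst = (j + 1, len(next_level) + 1)
                        species[dst] = grown
                        canon[key] = dst
                        next_level.append(dst)
                    fwd[(lab, dst)] = fwd.get((lab, dst), 0) + 1
        current = next_level

    bwd: dict[tuple[tuple[int, int], tuple[int, int]], int] = {}
    for (src, dst) in fwd:
        bwd[(dst, src)] = 0
    for lab, olig in species.items():
        if lab[0] == 1:
            continue
        for f in sorted(olig.faces):
            reduced = Oligomer(olig.faces - {f})
            if not reduced.is_connected(model):
                continue
            src = canon[canonical_key(reduced.faces, model)]
            bwd[(lab, src)] = bwd.get((lab, src), 0) + 1

    bond_counts = {lab: o.bond_count(model) for lab, o in species.items()}
    return SpeciesTable(species, fwd, bwd, bond_counts, model)
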