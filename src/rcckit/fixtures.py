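"""Synthetic structures and graphs with known properties, plus the
end-to-end brute-force oracle.

Everything here is a pure function of its arguments (and seed), so the test
suite needs no downloaded data.  Helix parameters are canonical α-helix
values (rise 1.5 Å/residue, 100°/residue twist, 2.3 Å radius); random chains
are self-avoiding walks with fixed 3.8 Å CA–CA steps.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .clique_enum import Graph, brute_force_maximal_cliques
from .contact_graph import ContactParams, brute_force_contact_graph
from .errors import GenerationError
from .rcc_core import RCCVector, rcc_vector
from .structure_io import Atom, Residue

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST_DEG = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å

CA_STEP = 3.8  # Å, consecutive CA distance in random chains
CLASH_RADIUS = 4.0  # Å, non-consecutive CA exclusion
_MAX_ATTEMPTS = 10_000

ATOM_MODES = ("ca_only", "backbone", "backbone_plus_dummy_sidechain")

#: Pseudo side-chain pseudo-atom distance from CA (dummy mode).
SIDECHAIN_OFFSET = 2.4


def _local_frames(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue orthonormal frame (tangent t, normal u, binormal b)."""
    n = len(ca)
    t = np.zeros_like(ca)
    if n == 1:
        t[0] = (1.0, 0.0, 0.0)
    else:
        t[0] = ca[1] - ca[0]
        t[-1] = ca[-1] - ca[-2]
        if n > 2:
            t[1:-1] = ca[2:] - ca[:-2]
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    # pick the lab axis least aligned with t to get a stable perpendicular
    ref = np.eye(3)[np.argmin(np.abs(t), axis=1)]
    u = np.cross(t, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    b = np.cross(t, u)
    return t, u, b


def _decorate(ca: np.ndarray, atom_mode: str) -> list[list[Atom]]:
    if atom_mode not in ATOM_MODES:
        raise ValueError(f"atom_mode must be one of {ATOM_MODES}, got {atom_mode!r}")
    t, u, b = _local_frames(ca)
    per_residue: list[list[Atom]] = []
    for i in range(len(ca)):
        atoms = [Atom(name="CA", element="C", coords=ca[i])]
        if atom_mode != "ca_only":
            # fixed offsets in the local frame; geometry is schematic but
            # non-degenerate and chirally consistent along the chain
            atoms.insert(
                0,
                Atom(name="N", element="N", coords=ca[i] - 1.2 * t[i] + 0.5 * b[i]),
            )
            atoms.append(
                Atom(name="C", element="C", coords=ca[i] + 1.2 * t[i] + 0.5 * b[i])
            )
            atoms.append(
                Atom(
                    name="O",
                    element="O",
                    coords=ca[i] + 1.2 * t[i] + 0.5 * b[i] + 1.2 * u[i],
                )
            )
        if atom_mode == "backbone_plus_dummy_sidechain":
            atoms.append(
                Atom(
                    name="CB",
                    element="C",
                    coords=ca[i] - SIDECHAIN_OFFSET * u[i],
                )
            )
        per_residue.append(atoms)
    return per_residue


def _to_residues(
    per_residue_atoms: list[list[Atom]], atom_mode: str, chain_id: str = "A"
) -> list[Residue]:
    name = "GLY" if atom_mode in ("ca_only", "backbone") else "ALA"
    return [
        Residue(
            chain_id=chain_id,
            author_seq_id=i + 1,
            ordinal_index=i,
            residue_name=name,
            atoms=atoms,
        )
        for i, atoms in enumerate(per_residue_atoms)
    ]


def make_ideal_helix(n: int, atom_mode: str = "ca_only") -> list[Residue]:
    """Ideal α-helix CA trace, optionally decorated with backbone/CB atoms."""
    if n < 1:
        raise ValueError("need at least one residue")
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST_DEG) * i
    ca = np.column_stack(
        (
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * i,
        )
    )
    return _to_residues(_decorate(ca, atom_mode), atom_mode)


def make_extended_chain(n: int, atom_mode: str = "ca_only") -> list[Residue]:
    """Straight chain with 3.8 Å CA spacing (β-strand-like sparsity)."""
    if n < 1:
        raise ValueError("need at least one residue")
    ca = np.column_stack(
        (CA_STEP * np.arange(n), np.zeros(n), np.zeros(n))
    ).astype(float)
    return _to_residues(_decorate(ca, atom_mode), atom_mode)


def make_random_chain(n: int, seed: int, atom_mode: str = "ca_only") -> list[Residue]:
    """Self-avoiding random walk: 3.8 Å steps, 4.0 Å clash rejection.

    Deterministic in (n, seed).  Raises :class:`GenerationError` if a step
    cannot be placed within 10,000 rejection attempts.
    """
    if n < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    ca = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(_MAX_ATTEMPTS):
            v = rng.normal(size=3)
            v *= CA_STEP / np.linalg.norm(v)
            cand = ca[i - 1] + v
            if i >= 2:
                dists = np.linalg.norm(ca[: i - 1] - cand, axis=1)
                if dists.min() < CLASH_RADIUS:
                    continue
            ca[i] = cand
            break
        else:
            raise GenerationError(
                f"could not place residue {i} after {_MAX_ATTEMPTS} attempts"
            )
    return _to_residues(_decorate(ca, atom_mode), atom_mode)


def make_random_graph(n: int, p: float, seed: int) -> Graph:
    """Erdős–Rényi G(n, p), reproducible from the seed."""
    if n < 1:
        raise ValueError("need at least one vertex")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = Graph(n)
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < p:
                g.add_edge(u, v)
    return g


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_transform(
    residues: Sequence[Residue],
    rotation: np.ndarray,
    translation: np.ndarray,
) -> list[Residue]:
    """Apply x → R·x + t to every atom; metadata unchanged.

    ``rotation`` must be orthonormal with determinant +1 (checked to 1e-9).
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float).reshape(3)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
        raise ValueError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
        raise ValueError("rotation matrix determinant is not +1")
    out = []
    for residue in residues:
        atoms = [
            Atom(
                name=a.name,
                element=a.element,
                coords=R @ a.coords + t,
                occupancy=a.occupancy,
                altloc=a.altloc,
            )
            for a in residue.atoms
        ]
        out.append(
            Residue(
                chain_id=residue.chain_id,
                author_seq_id=residue.author_seq_id,
                ordinal_index=residue.ordinal_index,
                residue_name=residue.residue_name,
                atoms=atoms,
                insertion_code=residue.insertion_code,
            )
        )
    return out


def brute_force_rcc(
    residues: Sequence[Residue], params: ContactParams
) -> RCCVector:
    """Ground-truth RCC vector with zero optimisations.

    All-pairs contact graph + exhaustive subset clique enumeration +
    classification.  Raises :class:`~rcckit.errors.GraphSizeError` when the
    contact graph is too large for the exhaustive stage.
    """
    graph = brute_force_contact_graph(residues, params)
    g = Graph(graph.n_nodes, graph.edges)
    cliques = brute_force_maximal_cliques(g)
    return rcc_vector(
        ([graph.nodes[v] for v in clique] for clique in cliques),
        params=params,
    )
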