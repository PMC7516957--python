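"""Residue cluster classes: classify maximal cliques, assemble RCC vectors.

A maximal clique of 3–6 residues is classified by its adjacency partition:
sort the members by (chain, ordinal), group maximal runs of same-chain,
consecutive-ordinal residues, and collect the run lengths as a non-decreasing
integer partition.  Residues in different chains are never adjacent.  The 26
(size, partition) classes are kept in a fixed canonical order so that feature
columns are comparable across runs; cliques smaller than 3 or larger than 6
contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .contact_graph import ContactGraph, ContactParams, ResidueKey

MIN_CLIQUE_SIZE = 3
MAX_CLIQUE_SIZE = 6

# Canonical catalog order.  Within each size the listing is intentionally NOT
# sorted by any partition order — it reproduces the established convention
# verbatim so vectors line up column-for-column with existing feature tables.
_CATALOG_SPEC: tuple[tuple[int, tuple[int, ...]], ...] = (
    (3, (1, 1, 1)),
    (3, (1, 2)),
    (3, (3,)),
    (4, (1, 1, 1, 1)),
    (4, (1, 1, 2)),
    (4, (2, 2)),
    (4, (1, 3)),
    (4, (4,)),
    (5, (1, 1, 1, 1, 1)),
    (5, (1, 1, 1, 2)),
    (5, (1, 1, 3)),
    (5, (1, 4)),
    (5, (1, 2, 2)),
    (5, (2, 3)),
    (5, (5,)),
    (6, (1, 1, 1, 1, 1, 1)),
    (6, (1, 1, 1, 1, 2)),
    (6, (1, 1, 1, 3)),
    (6, (1, 1, 2, 2)),
    (6, (1, 1, 4)),
    (6, (1, 2, 3)),
    (6, (1, 5)),
    (6, (2, 2, 2)),
    (6, (2, 4)),
    (6, (3, 3)),
    (6, (6,)),
)

N_CLASSES = len(_CATALOG_SPEC)


@dataclass(frozen=True)
class CliqueClass:
    """One of the 26 (size, partition) classes; ``index`` is its catalog slot."""

    size: int
    partition: tuple[int, ...]
    index: int

    def __post_init__(self) -> None:
        if sum(self.partition) != self.size:
            raise ValueError(
                f"partition {self.partition} does not sum to size {self.size}"
            )
        if list(self.partition) != sorted(self.partition):
            raise ValueError(f"partition {self.partition} not non-decreasing")

    @property
    def column_name(self) -> str:
        """Stable export column name, e.g. ``c4_22`` for size 4, [2,2]."""
        return f"c{self.size}_{''.join(map(str, self.partition))}"


def class_catalog() -> tuple[CliqueClass, ...]:
    """The 26 clique classes in canonical order (sizes 3/4/5/6 → 3/5/7/11)."""
    return tuple(
        CliqueClass(size=size, partition=partition, index=i)
        for i, (size, partition) in enumerate(_CATALOG_SPEC)
    )


_CATALOG = class_catalog()
_LOOKUP = {(c.size, c.partition): c for c in _CATALOG}
COLUMN_NAMES = tuple(c.column_name for c in _CATALOG)


def adjacency_partition(members: Iterable[ResidueKey]) -> tuple[int, ...]:
    """Run-length partition of a clique's members.

    ``members`` are (chain_id, ordinal_index) pairs; duplicates are a
    contract violation.  Returns run lengths sorted non-decreasing.
    """
    keys = sorted(members)
    if len(set(keys)) != len(keys):
        raise ValueError(f"duplicate members in clique: {keys}")
    if not keys:
        raise ValueError("empty clique")
    runs: list[int] = [1]
    for prev, cur in zip(keys, keys[1:]):
        if cur[0] == prev[0] and cur[1] == prev[1] + 1:
            runs[-1] += 1
        else:
            runs.append(1)
    return tuple(sorted(runs))


def classify_clique(
    members: Iterable[ResidueKey],
    catalog: Sequence[CliqueClass] = _CATALOG,
) -> Optional[CliqueClass]:
    """Catalog entry for a clique, or None when its size is outside [3, 6]."""
    keys = list(members)
    size = len(keys)
    if size < MIN_CLIQUE_SIZE or size > MAX_CLIQUE_SIZE:
        return None
    partition = adjacency_partition(keys)
    cls = _LOOKUP[(size, partition)]
    return catalog[cls.index]


@dataclass(frozen=True)
class RCCVector:
    """26 maximal-clique counts in canonical class order."""

    counts: tuple[int, ...]
    params: Optional[ContactParams] = None
    structure_id: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) != N_CLASSES:
            raise ValueError(f"expected {N_CLASSES} counts, got {len(self.counts)}")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(COLUMN_NAMES, self.counts))


def rcc_vector(
    cliques: Iterable[Iterable[ResidueKey]],
    params: Optional[ContactParams] = None,
    structure_id: str = "",
    min_size: int = MIN_CLIQUE_SIZE,
    max_size: int = MAX_CLIQUE_SIZE,
) -> RCCVector:
    """Count classified cliques per catalog slot.

    ``min_size``/``max_size`` may narrow (never widen) the [3, 6] window.
    """
    lo = max(min_size, MIN_CLIQUE_SIZE)
    hi = min(max_size, MAX_CLIQUE_SIZE)
    counts = [0] * N_CLASSES
    for members in cliques:
        keys = list(members)
        if not (lo <= len(keys) <= hi):
            continue
        cls = classify_clique(keys)
        if cls is not None:
            counts[cls.index] += 1
    return RCCVector(
        counts=tuple(counts), params=params, structure_id=structure_id
    )


def rcc_from_contact_graph(
    graph: ContactGraph,
    structure_id: str = "",
    min_size: int = MIN_CLIQUE_SIZE,
    max_size: int = MAX_CLIQUE_SIZE,
) -> RCCVector:
    """Enumerate maximal cliques of the contact graph and count classes."""
    from .clique_enum import Graph, maximal_cliques

    g = Graph(graph.n_nodes, graph.edges)
    cliques = maximal_cliques(g)
    return rcc_vector(
        ([graph.nodes[v] for v in clique] for clique in cliques),
        params=graph.params,
        structure_id=structure_id,
        min_size=min_size,
        max_size=max_size,
    )
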