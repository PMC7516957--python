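# rcckit

Residue cluster class (RCC) fingerprints of protein 3D structures.

Given a PDB file and a contact distance threshold *d*, rcckit

1. parses the structure into per-chain ordered residues (0-based ordinal
   indices, one altloc conformer per atom, waters excluded, optional
   backbone-only atom set),
2. builds the residue contact graph — edge ⇔ some atom pair between the two
   residues is within *d* Å — using a cubic grid hash of cell width *d* plus
   per-residue bounding-sphere pruning, exactly equivalent to the all-pairs
   brute force,
3. enumerates all maximal cliques (pivoting under a degeneracy ordering),
4. classifies each clique of size 3–6 by its sequence-adjacency run
   partition (e.g., residues 45, 46, 101, 102 → `[2,2]`) into one of 26
   canonical classes, and
5. emits the 26-dimensional count vector, suitable as an ML feature vector
   for structural or functional classification.

Every optimised stage has an independent brute-force oracle (all-pairs
contact scan, exhaustive subset clique scan, end-to-end pipeline) that the
test suite checks against exactly.

## CLI

```sh
# one structure, defaults: d ∈ {5,6,7,8,9,10,15} Å, side chains included
rcc compute structure.pdb --output features.csv

# batch over a glob, two thresholds, both side-chain settings, 4 workers
rcc compute 'pdbs/*.pdb' -d 5 -d 8 --both-side-chain-settings \
    --workers 4 --output features.csv

# backbone-only contacts on one chain, JSON-lines output, edge-list dump
rcc compute structure.pdb -d 5 --no-side-chains --chains A \
    --format jsonl --output features.jsonl --edge-list edges.tsv

# the 26-class catalog in canonical order
rcc classes
```

Exit codes for `compute`: 0 all inputs ok, 2 partial failure (failed inputs
are reported on stderr and skipped), 1 total failure.

The CSV schema is `structure_id, chain, d, side_chains, n_residues,
n_edges` followed by the 26 class columns in canonical order, named
`c<size>_<partition>` (e.g. `c3_111`, `c4_22`, `c6_123`).

## Python API

```python
from rcckit import (ContactParams, parse_structure, select_residues,
                    build_contact_graph, rcc_from_contact_graph)

structure = parse_structure("structure.pdb")
residues = select_residues(structure)            # or chain_ids=["A"]
graph = build_contact_graph(residues, ContactParams(d=5.0))
vector = rcc_from_contact_graph(graph, structure_id=structure.id)
print(vector.as_dict())                          # {'c3_111': ..., ...}
```

`rcckit.fixtures` generates synthetic structures (ideal α-helices,
self-avoiding random chains) and Erdős–Rényi graphs so everything is
testable without downloads.

Contact pruning has two modes: `filter_mode="sound"` (default; triangle-
inequality sphere bounds, provably identical to brute force) and
`filter_mode="paper"` (literal historic quick-include/exclude rules, which
can misclassify pairs of spatially extended residues;
`rcckit.contact_graph.filter_mode_disagreement` reports any divergence).

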