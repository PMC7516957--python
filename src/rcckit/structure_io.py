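"""Read PDB files into an ordered residue/atom model.

This module turns a PDB deposition into the minimal polymer model the rest of
the pipeline needs: per-chain ordered lists of residues, each holding the
retained heavy atoms.  Residues get a 0-based ``ordinal_index`` per chain in
file order — the substrate for all sequence-adjacency decisions downstream.

Filtering policy (see also the package README):

* one model per structure (default: the first one);
* one altloc conformer per atom (default: highest occupancy, ties broken by
  the alphabetically first altloc id);
* hydrogens and deuteriums dropped by default;
* waters always dropped; HETATM residues kept only when they are recognisable
  amino acids sitting in a polymer chain (e.g., MSE selenomethionine).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.PDB.Polypeptide import is_aa

from .errors import EmptyStructureError, PDBInputError, UnknownChainError

#: Conventional peptide backbone heavy atoms.  OXT is the terminal carboxyl
#: oxygen; CA-only traces remain usable because CA is in the set.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "DIS"})
_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


@dataclass(frozen=True)
class Atom:
    """A single (possibly altloc-resolved) heavy atom.

    ``coords`` is a length-3 float array in Ångström.  Instances are treated
    as immutable; transformations produce new atoms.
    """

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        object.__setattr__(self, "coords", coords)


@dataclass
class Residue:
    """An ordered polymer unit.

    ``ordinal_index`` is the 0-based position within the chain's observed
    polymer sequence — consecutive with no gaps, regardless of author
    numbering.  ``author_seq_id``/``insertion_code`` are provenance only.
    """

    chain_id: str
    author_seq_id: int
    ordinal_index: int
    residue_name: str
    atoms: list[Atom]
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int]:
        """Global residue id used by the contact graph: (chain, ordinal)."""
        return (self.chain_id, self.ordinal_index)

    def coord_array(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array."""
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class ResidueEnvelope:
    """Bounding sphere of a residue's retained atoms."""

    center: np.ndarray
    radius: float


@dataclass
class Structure:
    """One model of a parsed deposition: ordered chains of ordered residues."""

    id: str
    chains: list[list[Residue]] = field(default_factory=list)
    model_number: int = 0

    @property
    def chain_ids(self) -> list[str]:
        return [chain[0].chain_id for chain in self.chains if chain]

    @property
    def n_residues(self) -> int:
        return sum(len(chain) for chain in self.chains)


def _looks_like_text(source: object) -> bool:
    return isinstance(source, str) and "\n" in source


def _pick_altloc(children: Sequence, policy: str):
    if policy != "occupancy":
        raise ValueError(f"unknown altloc policy {policy!r}")
    # Highest occupancy wins; ties go to the alphabetically first altloc id.
    return sorted(
        children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc())
    )[0]


def _is_polymer_amino_acid(bio_residue) -> bool:
    hetflag = bio_residue.id[0]
    if hetflag == "W" or bio_residue.get_resname().strip() in _WATER_NAMES:
        return False
    # Standard ATOM residues and amino-acid HETATMs (MSE etc.) both pass;
    # ligands, ions and nucleotides do not.
    return is_aa(bio_residue, standard=False)


def parse_structure(
    source,
    *,
    model: int | str = "first",
    altloc_policy: str = "occupancy",
    include_hydrogens: bool = False,
    structure_id: str | None = None,
) -> Structure:
    """Parse PDB text or a PDB file into a :class:`Structure`.

    Parameters
    ----------
    source:
        Path to a PDB file, or the PDB text itself (detected by embedded
        newlines), or an open text handle.
    model:
        ``"first"`` (default) or a 0-based index into the model list.
    altloc_policy:
        ``"occupancy"``: keep the highest-occupancy conformer per atom,
        ties broken by the alphabetically first altloc id.
    include_hydrogens:
        Keep H/D atoms (excluded by default; most depositions lack them).

    Raises
    ------
    PDBInputError
        The input cannot be read or parsed.
    EmptyStructureError
        No amino-acid residues survive filtering.
    """
    if hasattr(source, "read"):
        handle = source
        sid = structure_id or "structure"
    elif _looks_like_text(source):
        handle = io.StringIO(source)
        sid = structure_id or "structure"
    else:
        path = Path(source)
        if not path.is_file():
            raise PDBInputError(f"no such file: {path}")
        handle = None
        sid = structure_id or path.stem

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            if handle is not None:
                bio_structure = parser.get_structure(sid, handle)
            else:
                bio_structure = parser.get_structure(sid, str(path))
    except Exception as exc:  # Bio.PDB raises a zoo of exception types
        raise PDBInputError(f"cannot parse {sid!r} as PDB: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise EmptyStructureError(f"{sid!r}: no models in file")
    if model == "first":
        bio_model = models[0]
    else:
        try:
            bio_model = models[int(model)]
        except (IndexError, ValueError) as exc:
            raise PDBInputError(
                f"{sid!r}: model {model!r} not available ({len(models)} models)"
            ) from exc

    chains: list[list[Residue]] = []
    for bio_chain in bio_model:
        residues: list[Residue] = []
        ordinal = 0
        for bio_residue in bio_chain:
            if not _is_polymer_amino_acid(bio_residue):
                continue
            atoms: list[Atom] = []
            for bio_atom in bio_residue:
                if bio_atom.is_disordered():
                    bio_atom = _pick_altloc(
                        bio_atom.disordered_get_list(), altloc_policy
                    )
                element = (bio_atom.element or "").strip().upper()
                if not include_hydrogens and element in _HYDROGEN_ELEMENTS:
                    continue
                atoms.append(
                    Atom(
                        name=bio_atom.get_name().strip(),
                        element=element,
                        coords=np.asarray(bio_atom.coord, dtype=float),
                        occupancy=float(bio_atom.get_occupancy() or 1.0),
                        altloc=(bio_atom.get_altloc() or "").strip(),
                    )
                )
            if not atoms:
                continue
            hetflag, resseq, icode = bio_residue.id
            residues.append(
                Residue(
                    chain_id=bio_chain.id.strip() or bio_chain.id,
                    author_seq_id=int(resseq),
                    ordinal_index=ordinal,
                    residue_name=bio_residue.get_resname().strip(),
                    atoms=atoms,
                    insertion_code=icode.strip(),
                )
            )
            ordinal += 1
        if residues:
            chains.append(residues)

    structure = Structure(id=sid, chains=chains, model_number=bio_model.id)
    if structure.n_residues == 0:
        raise EmptyStructureError(f"{sid!r}: no amino-acid residues after filtering")
    return structure


def select_residues(
    structure: Structure, chain_ids: Iterable[str] | None = None
) -> list[Residue]:
    """Flatten the structure to a single ordered residue list.

    With ``chain_ids`` given, only those chains are kept; output order is
    always file order, never request order.  Ordinal indices are untouched.
    """
    if chain_ids is None:
        return [r for chain in structure.chains for r in chain]
    wanted = set(chain_ids)
    present = set(structure.chain_ids)
    missing = wanted - present
    if missing:
        raise UnknownChainError(
            f"chain(s) {sorted(missing)} not in structure "
            f"{structure.id!r} (has {sorted(present)})"
        )
    return [
        r
        for chain in structure.chains
        if chain and chain[0].chain_id in wanted
        for r in chain
    ]


def strip_side_chains(residues: Sequence[Residue]) -> list[Residue]:
    """Keep only backbone atoms (N, CA, C, O, OXT) in each residue.

    Residues left with zero backbone atoms are dropped; ordinal indices are
    NOT renumbered, so sequence adjacency of the survivors is preserved.
    Idempotent.
    """
    out: list[Residue] = []
    for residue in residues:
        kept = [a for a in residue.atoms if a.name in BACKBONE_ATOM_NAMES]
        if kept:
            out.append(replace(residue, atoms=kept))
    return out


def residue_envelope(residue: Residue) -> ResidueEnvelope:
    """Bounding sphere: geometric center of the atoms, radius to the farthest.

    Every retained atom lies within ``radius`` of ``center`` (to 1e-9 Å).
    """
    if not residue.atoms:
        raise ValueError(f"residue {residue.key} has no atoms")
    coords = residue.coord_array()
    center = coords.mean(axis=0)
    radius = float(np.linalg.norm(coords - center, axis=1).max())
    return ResidueEnvelope(center=center, radius=radius)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: single-letter elements start in column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(residues: Sequence[Residue], path=None) -> str:
    """Serialise residues as column-exact PDB ATOM records.

    Coordinates are written with 3 decimals (the format's precision); chains
    are separated by TER records.  Returns the text; also writes to ``path``
    when given.
    """
    lines: list[str] = []
    serial = 1
    prev_chain: str | None = None
    for residue in residues:
        if prev_chain is not None and residue.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = residue.chain_id
        for atom in residue.atoms:
            x, y, z = atom.coords
            lines.append(
                "ATOM  {serial:5d} {name}{alt:1s}{res:>3s} {chain:1s}"
                "{seq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
                "{bfac:6.2f}          {elem:>2s}".format(
                    serial=serial,
                    name=_format_atom_name(atom.name, atom.element),
                    alt=atom.altloc[:1] or " ",
                    res=residue.residue_name,
                    chain=residue.chain_id[:1] or "A",
                    seq=residue.author_seq_id,
                    icode=residue.insertion_code[:1] or " ",
                    x=x,
                    y=y,
                    z=z,
                    occ=atom.occupancy,
                    bfac=0.0,
                    elem=atom.element[:2],
                )
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
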