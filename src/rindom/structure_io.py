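"""Read protein structures into a light residue/atom model.

The rest of the package only ever consumes pairwise distances between
per-residue representative points, so the model kept here is deliberately
minimal: ordered chains of standard amino-acid residues, each with its heavy
atoms and coordinates.  Parsing is delegated to gemmi; this module applies the
filtering policy (first model, standard residues, no waters/hetero groups, no
hydrogens, highest-occupancy alternate locations) and exposes the three vertex
strategies used to turn a residue into one or more points in space:

``CA``
    the alpha-carbon position (radius 0),
``CENTROID``
    the unweighted mean of the side-chain heavy atoms (glycine, which has no
    side chain, falls back to its alpha carbon),
``ANYATOM``
    every heavy atom together with its van der Waals radius, so that
    downstream distances can be measured surface-to-surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids; everything else
#: (waters, ligands, modified residues) is dropped at parse time.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU "
    "LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Backbone atom names excluded from side-chain centroids.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Residue identity within a model: (chain id, author residue number, icode).
ResidueKey = tuple[str, int, str]


class StructureError(ValueError):
    """Problem with a structure file or model."""


class EmptyStructureError(StructureError):
    """No residues survived parsing/filtering."""


class VertexStrategy(str, Enum):
    """How a residue is represented as vertex geometry."""

    CA = "CA"
    CENTROID = "CENTROID"
    ANYATOM = "ANYATOM"


@dataclass(frozen=True)
class Atom:
    """A single heavy atom."""

    name: str
    element: str
    position: np.ndarray  # (3,) Cartesian coordinates, Angstrom
    alt_loc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name}: bad position {pos!r}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )


@dataclass
class Residue:
    """One amino-acid residue with its retained heavy atoms."""

    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """Ordered residues per chain for one structure (first model only)."""

    structure_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def residues(self, chain_ids: list[str] | None = None) -> Iterator[Residue]:
        """Iterate residues in chain-then-file order.

        ``chain_ids`` restricts (and orders) the chains; by default all chains
        are visited in file order.
        """
        ids = list(self.chains) if chain_ids is None else list(chain_ids)
        for cid in ids:
            yield from self.chains.get(cid, [])

    @property
    def n_residues(self) -> int:
        return sum(len(rs) for rs in self.chains.values())


@dataclass(frozen=True)
class RadiusTable:
    """Van der Waals radii per element, Angstrom.

    ``default`` is used for elements absent from the table (standard residues
    only contain C, N, O and S heavy atoms, so it is rarely exercised).
    """

    radii: Mapping[str, float]
    default: float = 1.70

    def __post_init__(self) -> None:
        # zero radii are permitted so that surface-gap distances can degrade
        # to plain center distances; negative radii never make sense
        for elem, r in self.radii.items():
            if not r >= 0:
                raise StructureError(f"radius for {elem} must be >= 0, got {r}")
        if not self.default >= 0:
            raise StructureError("default radius must be >= 0")

    def get(self, element: str) -> float:
        return self.radii.get(element.upper(), self.default)


#: Built-in van der Waals radii (Bondi-style values).
VDW_RADII = RadiusTable({"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80})


# ---------------------------------------------------------------------------
# Parsing


def _pick_alt_locs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties -> first in file."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occupancy > best[atom.name].occupancy:
            best[atom.name] = atom
    return [best[name] for name in order]


def parse_pdb(
    path: str | Path,
    chain_filter: set[str] | None = None,
    structure_id: str | None = None,
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Only the first model is read.  ATOM records of the 20 standard residues
    are kept; HETATM groups, waters and hydrogens are dropped; for alternate
    locations the highest-occupancy copy wins (ties go to the first in file);
    residues left without any heavy atom are dropped.

    Parameters
    ----------
    path:
        PDB file to read.
    chain_filter:
        If given, only these chain ids are retained.
    structure_id:
        Identifier stored on the model; defaults to the file stem.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    model = StructureModel(structure_id or path.stem)
    for chain in st[0]:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        residues: list[Residue] = []
        for res in chain:
            if res.name not in STANDARD_RESIDUES or res.het_flag == "H":
                continue
            atoms = []
            for atom in res:
                if atom.is_hydrogen():
                    continue
                alt = atom.altloc if atom.altloc not in ("\0", " ") else ""
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name.upper(),
                        position=np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                        ),
                        alt_loc=alt,
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                    )
                )
            atoms = _pick_alt_locs(atoms)
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(chain.name, res.seqid.num, icode, res.name, atoms)
            )
        if residues:
            model.chains[chain.name] = residues

    if model.n_residues == 0:
        raise EmptyStructureError(f"{path}: no residues after filtering")
    return model


# ---------------------------------------------------------------------------
# Writing (used for synthetic structures and round-trip fixtures)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal, valid PDB file for *model*.

    Deterministic: identical models produce byte-identical files.
    """
    lines: list[str] = []
    serial = 1
    for cid, residues in model.chains.items():
        for res in residues:
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:4s}{atom.alt_loc or ' ':1s}"
                    f"{res.res_name:>3s} {cid:1s}{res.seq_num:4d}"
                    f"{res.icode or ' ':1s}   "
                    f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}"
                    f"{atom.position[2]:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1].res_name:>3s} {cid:1s}"
                     f"{residues[-1].seq_num:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Vertex geometry


def representative_points(
    residue: Residue,
    strategy: VertexStrategy,
    radii: RadiusTable = VDW_RADII,
) -> list[tuple[np.ndarray, float]] | None:
    """Points (position, radius) representing *residue* under *strategy*.

    Returns ``None`` when the residue cannot be represented (e.g. missing
    alpha carbon); callers exclude such residues from the network and log the
    reason rather than raising.
    """
    strategy = VertexStrategy(strategy)
    if strategy is VertexStrategy.CA:
        ca = residue.atom("CA")
        if ca is None:
            return None
        return [(ca.position, 0.0)]
    if strategy is VertexStrategy.CENTROID:
        side = [a for a in residue.atoms if a.name not in BACKBONE_ATOMS]
        if side:
            centroid = np.mean([a.position for a in side], axis=0)
            return [(centroid, 0.0)]
        # glycine (or a side-chain-less residue): fall back to the Ca
        ca = residue.atom("CA")
        if ca is None:
            return None
        return [(ca.position, 0.0)]
    # ANYATOM: every heavy atom with its van der Waals radius
    if not residue.atoms:
        return None
    return [(a.position, radii.get(a.element)) for a in residue.atoms]
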