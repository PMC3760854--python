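"""FASTA and PDB handling for the docking side of the pipeline.

The docking workflow starts from a receptor structure that was solved with a
short peptide bound to it.  The bound peptide chain tells us where the
peptide-binding site is: its axis-aligned bounding box (plus a margin)
becomes the docking search box, and the chain itself is then removed so the
site is free for the fragment ligands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ChainNotFoundError, FormatError

#: the 20 standard amino acids, in the one-hot channel order used throughout
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: letters accepted on input (X = unknown residue)
INPUT_ALPHABET = set(AMINO_ACIDS) | {"X"}

#: default margin added on each side of the bound peptide's bounding box (Å)
DEFAULT_BOX_PADDING = 5.0
#: default cap on any search-box edge (Å); docking engines degrade on very
#: large boxes, so oversized boxes are clamped with a warning
DEFAULT_MAX_BOX_EDGE = 30.0


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: an identifier and an uppercase residue string."""

    id: str
    seq: str


@dataclass(frozen=True)
class Atom:
    """A single atom with its chain/residue context and coordinates in Å."""

    chain: str
    res_seq: int
    res_name: str
    name: str
    x: float
    y: float
    z: float
    hetero: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class StructureModel:
    """A flat atom list with a chain index over the polymer (ATOM) records.

    HETATM entries are kept (``hetero=True``) but do not contribute to the
    chain index or to bounding boxes, because the search box must track the
    peptide's amino-acid atoms, not waters or ions.
    """

    atoms: list[Atom] = field(default_factory=list)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            if not a.hetero:
                seen.setdefault(a.chain, None)
        return list(seen)

    def chain_atoms(self, chain: str, include_hetero: bool = False) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain == chain and (include_hetero or not a.hetero)
        ]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class SearchBox:
    """Axis-aligned docking box: centre plus edge lengths, both in Å."""

    centre: tuple[float, float, float]
    dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError(f"box dimensions must be positive, got {self.dims}")

    def contains(self, point: Sequence[float]) -> bool:
        return all(
            c - d / 2 <= p <= c + d / 2
            for p, c, d in zip(point, self.centre, self.dims)
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and whitespace-stripped; records with an empty
    identifier, an empty sequence or letters outside the 20 standard amino
    acids (plus ``X``) raise :class:`FormatError` naming the record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - INPUT_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-amino-acid "
                f"letters {sorted(bad)}"
            )
        records.append(SequenceRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _validate_coordinate_fields(path: Path) -> None:
    # Bio.PDB's permissive parser silently drops malformed atoms; a cheap
    # pre-scan lets us report the offending line number instead.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fld = line[lo:hi]
                    try:
                        float(fld)
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: unparseable coordinate "
                            f"field {fld!r}"
                        ) from None


def parse_pdb(path: str | Path) -> StructureModel:
    """Parse ATOM/HETATM records of a PDB file into a :class:`StructureModel`.

    Non-atom records are ignored.  Disordered atoms keep their first
    alternate location only, so parsing is deterministic.
    """
    path = Path(path)
    text = path.read_text()
    if not any(line.startswith(("ATOM  ", "HETATM")) for line in text.splitlines()):
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    _validate_coordinate_fields(path)

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    atoms: list[Atom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                hetero = residue.id[0].strip() != ""
                for atom in residue.get_unpacked_list():
                    if atom.is_disordered() and atom.get_altloc() not in ("", "A", " "):
                        continue  # keep the first altloc only
                    x, y, z = map(float, atom.coord)
                    atoms.append(
                        Atom(
                            chain=chain.id,
                            res_seq=int(residue.id[1]),
                            res_name=residue.resname.strip(),
                            name=atom.get_name(),
                            x=x,
                            y=y,
                            z=z,
                            hetero=hetero,
                        )
                    )
        break  # first NMR/crystallographic model only
    return StructureModel(atoms=atoms)


def write_pdb(model: StructureModel, path) -> None:
    """Write a :class:`StructureModel` as PDB text to a path or file object."""
    builder = StructureBuilder()
    builder.init_structure("model")
    builder.init_model(0)
    builder.init_seg("    ")
    current: tuple[str, int, str] | None = None
    serial = 0
    for a in model.atoms:
        key = (a.chain, a.res_seq, a.res_name)
        if current is None or key[0] != current[0]:
            builder.init_chain(a.chain)
        if key != current:
            hetfield = "H" if a.hetero else " "
            builder.init_residue(a.res_name, hetfield, a.res_seq, " ")
            current = key
        serial += 1
        builder.init_atom(
            a.name,
            np.array([a.x, a.y, a.z], dtype=float),
            0.0,
            1.0,
            " ",
            a.name.center(4),
            serial,
            element=a.name[0],
        )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(path if hasattr(path, "write") else str(path))


# ---------------------------------------------------------------------------
# Search box and chain stripping
# ---------------------------------------------------------------------------

def compute_search_box(
    model: StructureModel,
    peptide_chain: str,
    padding: float = DEFAULT_BOX_PADDING,
    max_edge: float = DEFAULT_MAX_BOX_EDGE,
) -> SearchBox:
    """Derive the docking search box from the bound peptide chain.

    The centre is the midpoint of the chain's axis-aligned bounding box and
    each edge is the box extent plus ``2 * padding``, so the box covers the
    bound peptide with a margin.  Edges longer than ``max_edge`` are clamped
    (with a warning) because very large boxes are unreliable to search.
    """
    atoms = model.chain_atoms(peptide_chain)
    if not atoms:
        raise ChainNotFoundError(
            f"chain {peptide_chain!r} not found or has no polymer atoms "
            f"(available: {model.chains})"
        )
    coords = np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    centre = tuple(float(c) for c in (lo + hi) / 2.0)
    dims = []
    for axis, extent in enumerate(hi - lo):
        edge = float(extent) + 2.0 * padding
        if edge > max_edge:
            warnings.warn(
                f"search-box edge on axis {'xyz'[axis]} ({edge:.1f} Å) exceeds "
                f"the maximum of {max_edge:.1f} Å and was clamped",
                stacklevel=2,
            )
            edge = max_edge
        dims.append(edge)
    return SearchBox(centre=centre, dims=tuple(dims))


def strip_chain(model: StructureModel, chain: str) -> StructureModel:
    """Return a copy of ``model`` with every atom of ``chain`` removed."""
    if not any(a.chain == chain for a in model.atoms):
        raise ChainNotFoundError(
            f"chain {chain!r} not found (available: {model.chains})"
        )
    kept = [a for a in model.atoms if a.chain != chain]
    if not kept:
        warnings.warn(
            f"stripping chain {chain!r} left an empty structure", stacklevel=2
        )
    return StructureModel(atoms=kept)


def format_box_config(box: SearchBox) -> str:
    """Render a search box as a Vina-style key=value config block."""
    cx, cy, cz = box.centre
    dx, dy, dz = box.dims
    lines = [
        f"center_x = {cx:.3f}",
        f"center_y = {cy:.3f}",
        f"center_z = {cz:.3f}",
        f"size_x = {dx:.3f}",
        f"size_y = {dy:.3f}",
        f"size_z = {dz:.3f}",
    ]
    return "\n".join(lines) + "\n"


def write_box_config(box: SearchBox, path: str | Path) -> None:
    Path(path).write_text(format_box_config(box))


def read_box_config(path: str | Path) -> SearchBox:
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            values[key.strip()] = float(val)
    try:
        centre = (values["center_x"], values["center_y"], values["center_z"])
        dims = (values["size_x"], values["size_y"], values["size_z"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing box key {exc}") from None
    return SearchBox(centre=centre, dims=dims)
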