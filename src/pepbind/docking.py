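"""Fragment docking: engine adapters, best-pose selection and score tracks.

Each k-mer fragment of a candidate region is docked into the receptor's
search box and the best (lowest, i.e. most favourable, kcal/mol) pose
affinity is kept.  Fragment scores are then mapped onto residues — a residue
inherits the best score of any fragment covering it — and normalised per
region into [0, 1] so that 1 marks the most favourably docking residue and
0 corresponds to a non-binding (zero or positive affinity) one.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .errors import EngineError, ValidationError
from .regions import FRAGMENT_LENGTH, ProteinRegion, generate_fragments
from .structures import SearchBox, StructureModel, write_box_config, write_pdb

#: per-residue track kinds understood by the pipeline
TRACK_KINDS = (
    "raw_score",
    "normalized_score",
    "disorder",
    "prediction",
    "label",
    "ss_helix",
    "ss_strand",
    "ss_coil",
)


@dataclass(frozen=True)
class FragmentScore:
    """Best docking affinity (kcal/mol) of one fragment of a region."""

    offset: int  # 1-based on the region
    kmer: str
    best_score: float


@dataclass
class ResidueTrack:
    """One number per region residue, tagged with what the numbers mean."""

    region_id: str
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in TRACK_KINDS:
            raise ValidationError(f"unknown track kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.values)


@runtime_checkable
class DockingEngine(Protocol):
    """Adapter contract: return one or more pose affinities for a fragment.

    Implementations must either return a non-empty list of pose scores
    (kcal/mol, lower is better) or raise; silently returning an empty list
    is treated as an engine failure by :func:`dock_fragment`.
    """

    def dock(
        self,
        receptor: StructureModel,
        box: SearchBox,
        peptide: str,
        offset: int,
    ) -> list[float]:
        ...


class LigandPreparer(Protocol):
    """Adapter contract: turn a peptide k-mer into a 3D ligand file."""

    def prepare(self, peptide: str, workdir: Path) -> Path:
        ...


def dock_fragment(
    engine: DockingEngine,
    receptor: StructureModel,
    box: SearchBox,
    offset: int,
    kmer: str,
) -> FragmentScore:
    """Dock one fragment and keep the top-ranked (minimum) pose affinity."""
    try:
        poses = engine.dock(receptor, box, kmer, offset)
    except EngineError:
        raise
    except Exception as exc:  # adapter misbehaviour must carry the fragment id
        raise EngineError(f"engine failed on fragment {offset} ({kmer}): {exc}") from exc
    if not poses:
        raise EngineError(f"engine returned no poses for fragment {offset} ({kmer})")
    return FragmentScore(offset=offset, kmer=kmer, best_score=float(min(poses)))


def dock_region(
    engine: DockingEngine,
    receptor: StructureModel,
    box: SearchBox,
    region: ProteinRegion,
    k: int = FRAGMENT_LENGTH,
) -> list[FragmentScore]:
    """Dock every overlapping k-mer of a region (no retry policy here)."""
    return [
        dock_fragment(engine, receptor, box, offset, kmer)
        for offset, kmer in generate_fragments(region, k)
    ]


def aggregate_to_residues(
    scores: Sequence[FragmentScore],
    region_length: int,
    k: int = FRAGMENT_LENGTH,
    region_id: str = "",
    method: str = "min",
) -> ResidueTrack:
    """Map fragment scores onto residues.

    A residue takes the minimum (most favourable) ``best_score`` over all
    fragments covering it; ``method="mean"`` averages instead.  Every residue
    must be covered by at least one fragment.
    """
    if method not in ("min", "mean"):
        raise ValidationError(f"unknown aggregation method {method!r}")
    covering: list[list[float]] = [[] for _ in range(region_length)]
    for fs in scores:
        if fs.offset < 1 or fs.offset + k - 1 > region_length:
            raise ValidationError(
                f"fragment at offset {fs.offset} (k={k}) outside region of "
                f"length {region_length}"
            )
        for i in range(fs.offset - 1, fs.offset - 1 + k):
            covering[i].append(fs.best_score)
    gaps = [i + 1 for i, c in enumerate(covering) if not c]
    if gaps:
        raise ValidationError(f"residues without fragment coverage: {gaps[:5]}...")
    agg = min if method == "min" else (lambda xs: sum(xs) / len(xs))
    values = np.array([agg(c) for c in covering], dtype=float)
    return ResidueTrack(region_id=region_id, values=values, kind="raw_score")


def normalize_scores(track: ResidueTrack) -> ResidueTrack:
    """Normalise a raw affinity track into [0, 1] within its region.

    The most negative affinity in the region maps to 1, an affinity of zero
    (or any positive value) maps to 0, and intermediate values scale
    linearly as |s| / |s_min|.  Normalisation is per region: affinities from
    different receptors are not directly comparable.
    """
    raw = np.asarray(track.values, dtype=float)
    if raw.size == 0:
        raise ValidationError("empty score track")
    s_min = raw.min()
    if s_min >= 0:
        warnings.warn(
            "no negative docking scores in track; normalised track is all zero",
            stacklevel=2,
        )
        values = np.zeros_like(raw)
    else:
        values = np.where(raw < 0, np.clip(-raw, 0.0, -s_min) / (-s_min), 0.0)
    return ResidueTrack(region_id=track.region_id, values=values, kind="normalized_score")


# ---------------------------------------------------------------------------
# AutoDock Vina adapter
# ---------------------------------------------------------------------------

_VINA_ROW = re.compile(r"^\s*\d+\s+(-?\d+(?:\.\d+)?)\s+\d")


def parse_vina_output(text: str) -> list[float]:
    """Extract pose affinities (kcal/mol) from a Vina result table.

    Vina prints a table with columns ``mode | affinity | rmsd l.b. | rmsd
    u.b.``; one affinity per pose row is returned, in table order.
    """
    affinities: list[float] = []
    for line in text.splitlines():
        m = _VINA_ROW.match(line)
        if m:
            affinities.append(float(m.group(1)))
    return affinities


class RDKitLigandPreparer:
    """Build a 3D peptide ligand file from a k-mer via RDKit.

    The k-mer is turned into a molecule (standard backbone chemistry), a 3D
    conformer is embedded with ETKDG, and the result is written as a PDB
    file ready for the external docking toolchain.
    """

    def __init__(self, seed: int = 0) -> None:
        self.seed = seed

    def to_smiles(self, peptide: str) -> str:
        from rdkit import Chem

        mol = Chem.MolFromSequence(peptide)
        if mol is None:
            raise EngineError(f"could not build a molecule from peptide {peptide!r}")
        return Chem.MolToSmiles(mol)

    def prepare(self, peptide: str, workdir: Path) -> Path:
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.MolFromSequence(peptide)
        if mol is None:
            raise EngineError(f"could not build a molecule from peptide {peptide!r}")
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = self.seed
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise EngineError(f"3D embedding failed for peptide {peptide!r}")
        out = Path(workdir) / f"ligand_{peptide}.pdb"
        Chem.MolToPDBFile(mol, str(out))
        return out


class VinaEngine:
    """Adapter around a local AutoDock Vina binary.

    Receptor, ligand and box-config files are written to a working
    directory, the binary is invoked, and the pose table on stdout is
    parsed.  The ligand path goes through a :class:`LigandPreparer` so that
    peptide-to-3D conversion stays pluggable.
    """

    def __init__(
        self,
        preparer: LigandPreparer,
        binary: str = "vina",
        workdir: str | Path = ".",
        extra_args: Sequence[str] = (),
    ) -> None:
        self.binary = binary
        self.preparer = preparer
        self.workdir = Path(workdir)
        self.extra_args = list(extra_args)

    def dock(
        self,
        receptor: StructureModel,
        box: SearchBox,
        peptide: str,
        offset: int,
    ) -> list[float]:
        if shutil.which(self.binary) is None:
            raise EngineError(
                f"docking binary {self.binary!r} not found on PATH; install "
                "AutoDock Vina or use the mock engine (--engine mock)"
            )
        self.workdir.mkdir(parents=True, exist_ok=True)
        receptor_path = self.workdir / "receptor.pdb"
        write_pdb(receptor, receptor_path)
        config_path = self.workdir / "box.cfg"
        write_box_config(box, config_path)
        ligand_path = self.preparer.prepare(peptide, self.workdir)
        cmd = [
            self.binary,
            "--receptor",
            str(receptor_path),
            "--ligand",
            str(ligand_path),
            "--config",
            str(config_path),
            *self.extra_args,
        ]
        result = subprocess.run(cmd, capture_output=True, text=True)
        if result.returncode != 0:
            raise EngineError(
                f"vina exited with status {result.returncode} on fragment "
                f"{offset} ({peptide}): {result.stderr.strip()[:500]}"
            )
        return parse_vina_output(result.stdout)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def fragment_scores_frame(scores: Sequence[FragmentScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offset": [s.offset for s in scores],
            "kmer": [s.kmer for s in scores],
            "best_score": [s.best_score for s in scores],
        }
    )


def track_table(region: ProteinRegion, tracks: Sequence[ResidueTrack]) -> pd.DataFrame:
    """Tabulate tracks over a region: position, residue, one column per kind."""
    frame = pd.DataFrame(
        {
            "position": np.arange(region.start, region.end + 1),
            "residue": list(region.seq),
        }
    )
    for t in tracks:
        if len(t) != len(region):
            raise ValidationError(
                f"track {t.kind!r} length {len(t)} does not match region length "
                f"{len(region)}"
            )
        frame[t.kind] = t.values
    return frame
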