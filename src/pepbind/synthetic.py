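"""Synthetic inputs for offline end-to-end runs.

Real inputs to the method are disordered 50-residue regions with a known
binding span, per-residue structure tracks from external predictors, and
docking affinities from an external engine.  This module fabricates all of
them with controlled statistics: sequences with one planted contiguous
binding span (3-12 residues, the classic short-linear-motif length range),
smooth high-disorder tracks that pass the mean-disorder filter,
coil-leaning secondary-structure simplexes, a deterministic mock docking
engine whose affinities are anti-correlated with the labels plus Gaussian
noise, and toy receptor+peptide PDB files with a known peptide bounding box.

Everything is a pure function of its spec (seeded), so corpora regenerate
bit-identically at test time.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field

import numpy as np

from .docking import aggregate_to_residues, dock_region, normalize_scores, ResidueTrack
from .errors import ConfigurationError
from .regions import FRAGMENT_LENGTH, ProteinRegion
from .structures import AMINO_ACIDS, Atom, SearchBox, StructureModel, write_pdb

#: baseline mock affinity (kcal/mol magnitude) of a fragment with no binding residues
MOCK_BASE_AFFINITY = 4.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for a synthetic corpus.

    ``n_regions=84`` and ``region_length=50`` mirror the size of the kind of
    motif corpus the method is trained on; ``span_range`` is the 3-12
    residue length range typical of short linear motifs.  ``effect`` is the
    extra (negative) affinity a fully binding fragment gains over the
    baseline and ``sigma`` the affinity noise, both in kcal/mol.
    """

    n_regions: int = 84
    region_length: int = 50
    span_range: tuple[int, int] = (3, 12)
    effect: float = 2.0
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.span_range
        if not (1 <= lo <= hi <= self.region_length):
            raise ConfigurationError(
                f"span range {self.span_range} infeasible for region length "
                f"{self.region_length}"
            )
        if self.sigma < 0 or self.n_regions < 1:
            raise ConfigurationError("sigma must be >= 0 and n_regions >= 1")


@dataclass
class RegionSample:
    """One synthetic region with its structural tracks (and docking track)."""

    region: ProteinRegion
    ss: np.ndarray  # (L, 3) helix/strand/coil simplex
    disorder: np.ndarray  # (L,) in [0, 1]
    vina: ResidueTrack | None = field(default=None)  # normalised docking track


def _smooth_disorder(rng: np.random.Generator, length: int) -> np.ndarray:
    # moving-average of white noise around a high baseline, clipped so the
    # window mean is guaranteed to clear the 0.5 disorder-filter threshold
    width = 9
    noise = rng.normal(0.0, 0.15, size=length + width - 1)
    smooth = np.convolve(noise, np.ones(width) / width, mode="valid")
    return np.clip(0.75 + smooth, 0.51, 0.99)


def gen_regions(spec: SyntheticSpec) -> list[RegionSample]:
    """Generate labelled regions with disorder and secondary-structure tracks.

    Each region carries exactly one contiguous positive span; sequence
    composition is uniform over the 20 amino acids (no compositional signal,
    so sequence-only models have nothing to learn); secondary structure is
    drawn from a coil-tilted Dirichlet, as expected inside disordered
    regions.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AMINO_ACIDS))
    samples = []
    L = spec.region_length
    for i in range(spec.n_regions):
        seq = "".join(rng.choice(letters, size=L))
        span_len = int(rng.integers(spec.span_range[0], spec.span_range[1] + 1))
        span_start = int(rng.integers(0, L - span_len + 1))
        labels = np.zeros(L, dtype=np.int8)
        labels[span_start : span_start + span_len] = 1
        region = ProteinRegion(
            parent_id=f"synth{i:03d}",
            parent_length=L,
            start=1,
            end=L,
            seq=seq,
            labels=labels,
        )
        ss = rng.dirichlet([1.0, 1.0, 4.0], size=L)  # helix, strand, coil
        disorder = _smooth_disorder(rng, L)
        samples.append(RegionSample(region=region, ss=ss, disorder=disorder))
    return samples


class MockDockingEngine:
    """Deterministic stand-in for an external docking engine.

    The best pose affinity of a fragment is
    ``-(base + effect * fraction_of_fragment_residues_labelled_positive)``
    plus Gaussian noise, so binding fragments dock more favourably.  Two
    strictly worse decoy poses are returned after the best one so that
    best-pose selection is exercised.  Noise is keyed on (seed, offset,
    peptide), making every call reproducible regardless of call order.
    """

    def __init__(
        self,
        labels=None,
        effect: float = 2.0,
        sigma: float = 0.1,
        seed: int = 0,
        base: float = MOCK_BASE_AFFINITY,
    ) -> None:
        if sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        self.labels = None if labels is None else np.asarray(labels, dtype=float)
        self.effect = effect
        self.sigma = sigma
        self.seed = seed
        self.base = base

    def dock(self, receptor, box, peptide: str, offset: int) -> list[float]:
        k = len(peptide)
        if self.labels is None:
            frac = 0.0
        else:
            frac = float(self.labels[offset - 1 : offset - 1 + k].mean())
        rng = np.random.default_rng(
            [self.seed, offset, zlib.crc32(peptide.encode())]
        )
        noise = rng.normal(0.0, self.sigma) if self.sigma > 0 else 0.0
        best = -(self.base + self.effect * frac) + noise
        decoys = best + np.abs(rng.uniform(0.5, 2.0, size=2)).cumsum()
        return [best, *decoys.tolist()]


def mock_engine(
    labels=None, effect: float = 2.0, sigma: float = 0.1, seed: int = 0
) -> MockDockingEngine:
    """Adapter factory matching the docking-engine contract."""
    return MockDockingEngine(labels=labels, effect=effect, sigma=sigma, seed=seed)


def gen_toy_pdb(
    seed: int = 0,
    peptide_length: int = 3,
    peptide_box: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.0, 0.0, 0.0),
        (10.0, 10.0, 10.0),
    ),
) -> str:
    """A tiny two-chain PDB: receptor chain A and bound peptide chain B.

    The peptide CA atoms exactly span ``peptide_box`` (for lengths >= 2),
    so the search box derived from chain B is known in closed form.
    """
    if peptide_length < 1:
        raise ConfigurationError("peptide length must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.asarray(peptide_box[0], dtype=float)
    hi = np.asarray(peptide_box[1], dtype=float)
    atoms: list[Atom] = []
    # receptor: a short CA trace well away from the peptide box
    for i in range(8):
        x, y, z = 25.0 + 3.0 * i, 25.0 + float(rng.normal(0, 1)), 25.0
        atoms.append(Atom("A", i + 1, "GLY", "CA", x, y, z))
    # peptide: first and last CA pinned to the box corners, rest inside
    coords = [lo]
    if peptide_length >= 2:
        coords += [rng.uniform(lo, hi) for _ in range(peptide_length - 2)]
        coords.append(hi)
    for i, c in enumerate(coords):
        atoms.append(Atom("B", i + 1, "ALA", "CA", float(c[0]), float(c[1]), float(c[2])))
    model = StructureModel(atoms=atoms)
    buf = io.StringIO()
    write_pdb(model, buf)
    return buf.getvalue()


def build_corpus(
    spec: SyntheticSpec, k: int = FRAGMENT_LENGTH
) -> list[RegionSample]:
    """Regions plus normalised mock docking tracks: the full offline corpus.

    Runs the real fragment pipeline (sliding k-mers, mock docking, best-pose
    selection, residue aggregation, per-region normalisation) for every
    region, so downstream consumers see exactly what a live docking run
    would produce.
    """
    samples = gen_regions(spec)
    receptor = StructureModel(atoms=[Atom("A", 1, "GLY", "CA", 0.0, 0.0, 0.0)])
    box = SearchBox(centre=(0.0, 0.0, 0.0), dims=(10.0, 10.0, 10.0))
    for i, sample in enumerate(samples):
        engine = mock_engine(
            labels=sample.region.labels,
            effect=spec.effect,
            sigma=spec.sigma,
            seed=spec.seed + i,
        )
        scores = dock_region(engine, receptor, box, sample.region, k)
        raw = aggregate_to_residues(
            scores, len(sample.region), k, region_id=sample.region.parent_id
        )
        sample.vina = normalize_scores(raw)
    return samples
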