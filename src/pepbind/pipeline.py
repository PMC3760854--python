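"""High-level workflows: simulate, dock, train, predict, evaluate.

These functions are what the command-line interface calls; they are equally
usable straight from Python.  Every workflow is reproducible from its
inputs plus a seed, and writes plain-text outputs (TSV/FASTA/PDB) together
with a JSON manifest recording the parameters in effect.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .brnn import (
    ALL_FEATURES,
    BRNNModel,
    FEATURE_COMBOS,
    TrainingConfig,
    cross_validate,
    encode_inputs,
    ensemble_predict,
    train_ensemble,
)
from .docking import (
    DockingEngine,
    FragmentScore,
    ResidueTrack,
    aggregate_to_residues,
    dock_fragment,
    fragment_scores_frame,
    normalize_scores,
    track_table,
)
from .errors import ConfigurationError, EngineError
from .evaluation import roc_auc, roc_points, write_curve
from .regions import (
    FRAGMENT_LENGTH,
    ProteinRegion,
    WINDOW_LENGTH,
    extract_window,
    generate_fragments,
    scan_motif,
)
from .structures import (
    SearchBox,
    StructureModel,
    compute_search_box,
    parse_pdb,
    read_fasta,
    strip_chain,
    write_box_config,
    write_fasta,
    write_pdb,
    SequenceRecord,
)
from .synthetic import RegionSample, SyntheticSpec, build_corpus, gen_toy_pdb

#: decision threshold above which a residue (or motif average) is flagged
#: as predicted binding; at this cut-off the false positive rate stays low
#: while a usable share of true binding residues is retained
DECISION_THRESHOLD = 0.4

#: desk-scale training schedule used by demos and experiments; the reference
#: schedule (10,000 epochs, lr 0.01) is impractically long for interactive
#: runs and the synthetic corpora converge far earlier
DESK_CONFIG = TrainingConfig(epochs=120, lr=0.5, patience=50)


def write_manifest(outdir: Path, command: str, params: dict) -> None:
    manifest = {
        "tool": "pepbind",
        "version": __version__,
        "python": platform.python_version(),
        "command": command,
        "parameters": params,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a full synthetic fixture set: FASTA, tracks TSV and a toy PDB."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus = build_corpus(spec)
    fasta = outdir / "regions.fasta"
    write_fasta(
        [SequenceRecord(s.region.parent_id, s.region.seq) for s in corpus], fasta
    )
    rows = []
    for s in corpus:
        frame = track_table(
            s.region,
            [
                ResidueTrack(s.region.parent_id, s.region.labels, "label"),
                ResidueTrack(s.region.parent_id, s.disorder, "disorder"),
                ResidueTrack(s.region.parent_id, s.ss[:, 0], "ss_helix"),
                ResidueTrack(s.region.parent_id, s.ss[:, 1], "ss_strand"),
                ResidueTrack(s.region.parent_id, s.ss[:, 2], "ss_coil"),
                s.vina,
            ],
        )
        frame.insert(0, "region", s.region.parent_id)
        rows.append(frame)
    tracks = outdir / "tracks.tsv"
    pd.concat(rows, ignore_index=True).to_csv(tracks, sep="\t", index=False, float_format="%.6g")
    pdb = outdir / "toy_receptor.pdb"
    pdb.write_text(gen_toy_pdb(seed=spec.seed))
    write_manifest(outdir, "simulate", {"spec": spec.__dict__})
    return {"fasta": fasta, "tracks": tracks, "pdb": pdb}


# ---------------------------------------------------------------------------
# dock
# ---------------------------------------------------------------------------

def dock_region_robust(
    engine: DockingEngine,
    receptor: StructureModel,
    box: SearchBox,
    region: ProteinRegion,
    k: int = FRAGMENT_LENGTH,
) -> list[FragmentScore]:
    """Dock all fragments; retry each failure once, then impute the median.

    A single bad fragment must not kill a region-scale run: after one retry
    a failing fragment gets the median raw score of the successful ones,
    with a warning naming it.
    """
    results: dict[int, FragmentScore] = {}
    failed: list[tuple[int, str]] = []
    for offset, kmer in generate_fragments(region, k):
        for attempt in (0, 1):
            try:
                results[offset] = dock_fragment(engine, receptor, box, offset, kmer)
                break
            except EngineError:
                if attempt == 1:
                    failed.append((offset, kmer))
    if failed and not results:
        raise EngineError("docking failed for every fragment of the region")
    if failed:
        median = float(np.median([fs.best_score for fs in results.values()]))
        for offset, kmer in failed:
            warnings.warn(
                f"fragment {offset} ({kmer}) failed twice; imputing the "
                f"region median score {median:.3f}",
                stacklevel=2,
            )
            results[offset] = FragmentScore(offset=offset, kmer=kmer, best_score=median)
    return [results[o] for o in sorted(results)]


def run_dock(
    engine: DockingEngine,
    receptor_pdb: str | Path,
    peptide_chain: str,
    region: ProteinRegion,
    outdir: str | Path,
    k: int = FRAGMENT_LENGTH,
) -> ResidueTrack:
    """Receptor preparation plus fragment docking for one region.

    Writes the stripped receptor, the box config, the per-fragment score
    table and the per-residue raw/normalised track; returns the normalised
    track.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = parse_pdb(receptor_pdb)
    box = compute_search_box(model, peptide_chain)
    receptor = strip_chain(model, peptide_chain)
    write_pdb(receptor, outdir / "receptor_stripped.pdb")
    write_box_config(box, outdir / "box.cfg")

    scores = dock_region_robust(engine, receptor, box, region, k)
    fragment_scores_frame(scores).to_csv(
        outdir / "fragments.tsv", sep="\t", index=False, float_format="%.6g"
    )
    raw = aggregate_to_residues(scores, len(region), k, region_id=region.parent_id)
    norm = normalize_scores(raw)
    track_table(region, [raw, norm]).to_csv(
        outdir / "residue_scores.tsv", sep="\t", index=False, float_format="%.6g"
    )
    write_manifest(
        outdir,
        "dock",
        {
            "receptor": str(receptor_pdb),
            "peptide_chain": peptide_chain,
            "fragment_length": k,
            "region": f"{region.parent_id}:{region.start}-{region.end}",
        },
    )
    return norm


# ---------------------------------------------------------------------------
# train / evaluate
# ---------------------------------------------------------------------------

def encode_corpus(
    corpus: Sequence[RegionSample], features: Iterable[str] = ALL_FEATURES
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Encode region samples into (feature matrix, label track) pairs."""
    dataset = []
    for s in corpus:
        x = encode_inputs(
            s.region,
            ss=s.ss,
            disorder=s.disorder,
            vina=None if s.vina is None else s.vina.values,
            features=frozenset(features) & (
                ALL_FEATURES if s.vina is not None else ALL_FEATURES - {"vina"}
            ),
        )
        dataset.append((x, s.region.labels.astype(float)))
    return dataset


def pooled_oof_auc(
    corpus: Sequence[RegionSample],
    config: TrainingConfig,
    features: Iterable[str],
) -> float:
    """Out-of-fold cross-validated AUC, residues pooled over all regions."""
    dataset = encode_corpus(corpus, features)
    preds, _ = cross_validate(dataset, config)
    scores = np.concatenate(preds)
    labels = np.concatenate([y for _, y in dataset])
    return roc_auc(scores, labels)


def feature_ablation_cv(
    corpus: Sequence[RegionSample],
    config: TrainingConfig,
    combos: Sequence[tuple[str, frozenset[str]]] = FEATURE_COMBOS,
) -> pd.DataFrame:
    """Cross-validated AUC for each structural-feature combination."""
    rows = [
        {"features": name, "auc": pooled_oof_auc(corpus, config, feats)}
        for name, feats in combos
    ]
    return pd.DataFrame(rows)


def run_train(
    spec: SyntheticSpec,
    config: TrainingConfig,
    outdir: str | Path,
    combos: Sequence[tuple[str, frozenset[str]]] = FEATURE_COMBOS,
    save_checkpoint: bool = True,
) -> pd.DataFrame:
    """Train on a synthetic corpus and report the per-combination AUC table.

    Also trains (and saves) a deployment ensemble on the full corpus with
    all features, for use by the predict workflow.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus = build_corpus(spec)
    if len(corpus) < config.folds:
        raise ConfigurationError(
            f"{len(corpus)} regions cannot be split into {config.folds} folds"
        )
    table = feature_ablation_cv(corpus, config, combos)
    table.to_csv(outdir / "auc_table.tsv", sep="\t", index=False, float_format="%.4f")
    if save_checkpoint:
        from .brnn import save_model

        models = train_ensemble(encode_corpus(corpus, ALL_FEATURES), config)
        for m in models:
            save_model(m, outdir / f"model_w{m.window}.json")
    write_manifest(
        outdir,
        "train",
        {"spec": spec.__dict__, "config": config.__dict__, "combos": [n for n, _ in combos]},
    )
    return table


def signal_recovery_experiment(
    seed: int = 0,
    config: TrainingConfig | None = None,
    spec: SyntheticSpec | None = None,
) -> dict[str, float]:
    """Cross-validated AUC of sequence+docking vs sequence-only models.

    On the standard synthetic corpus (84 regions of 50 residues, docking
    effect 2 kcal/mol, noise 0.1) the docking channel carries essentially
    all the signal, so the sequence+docking model should rank binding
    residues nearly perfectly while the sequence-only model stays near
    chance.
    """
    spec = spec if spec is not None else SyntheticSpec(seed=seed)
    config = config if config is not None else replace(DESK_CONFIG, seed=seed)
    corpus = build_corpus(spec)
    return {
        "auc_sequence_vina": pooled_oof_auc(corpus, config, {"vina"}),
        "auc_sequence_only": pooled_oof_auc(corpus, config, frozenset()),
    }


def run_evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    outdir: str | Path,
    plot: bool = False,
) -> float:
    """Pooled ROC/AUC report for a prediction track against labels."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curve = roc_points(scores, labels)
    write_curve(curve, outdir / "roc.tsv")
    if plot:
        from .evaluation import plot_curve

        plot_curve(curve, outdir / "roc.png")
    return curve.auc


# ---------------------------------------------------------------------------
# predict
# ---------------------------------------------------------------------------

@dataclass
class PredictionReport:
    """Per-residue predictions for one extracted region, plus motif averages."""

    region: ProteinRegion
    predictions: np.ndarray
    motif_averages: pd.DataFrame  # start, end, motif, mean_score, above_threshold
    threshold: float = DECISION_THRESHOLD

    def frame(self) -> pd.DataFrame:
        out = track_table(
            self.region,
            [ResidueTrack(self.region.parent_id, self.predictions, "prediction")],
        )
        out["above_threshold"] = self.predictions > self.threshold
        return out


def load_parent_tracks(path: str | Path) -> pd.DataFrame:
    """Read per-residue predictor tracks for a parent sequence.

    Expected TSV columns: ``position`` (1-based) plus any of ``ss_helix``,
    ``ss_strand``, ``ss_coil``, ``disorder``.  This is the pluggable surface
    for external secondary-structure and disorder predictors.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    if "position" not in frame.columns:
        raise ConfigurationError(f"{path}: tracks file must have a 'position' column")
    return frame.set_index("position").sort_index()


def _slice_tracks(tracks: pd.DataFrame | None, region: ProteinRegion):
    ss = disorder = None
    if tracks is not None:
        window = tracks.reindex(range(region.start, region.end + 1))
        cols = {"ss_helix", "ss_strand", "ss_coil"}
        if cols <= set(window.columns):
            ss = window[["ss_helix", "ss_strand", "ss_coil"]].to_numpy(float)
        if "disorder" in window.columns:
            disorder = window["disorder"].to_numpy(float)
    return ss, disorder


def run_predict(
    models: Sequence[BRNNModel],
    engine: DockingEngine,
    sequence: SequenceRecord,
    start: int,
    receptor_pdb: str | Path,
    peptide_chain: str,
    outdir: str | Path,
    tracks: pd.DataFrame | None = None,
    motif_pattern: str | None = None,
    window: int = WINDOW_LENGTH,
    k: int = FRAGMENT_LENGTH,
    threshold: float = DECISION_THRESHOLD,
) -> PredictionReport:
    """End-to-end prediction for one sequence region.

    Extracts the window starting at ``start``, docks its fragments into the
    receptor's peptide site, encodes the features that are available
    (missing tracks stay zero-filled) and averages the ensemble outputs.
    When a motif pattern is given, predictions are additionally averaged
    over each motif instance in the region and flagged against the decision
    threshold.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = len(sequence.seq)
    if not (1 <= start <= n):
        raise ConfigurationError(f"start residue {start} outside sequence of length {n}")
    end = min(start + window - 1, n)
    region = ProteinRegion(
        parent_id=sequence.id,
        parent_length=n,
        start=start,
        end=end,
        seq=sequence.seq[start - 1 : end],
    )
    vina = run_dock(engine, receptor_pdb, peptide_chain, region, outdir, k)
    ss, disorder = _slice_tracks(tracks, region)
    features = {"vina"}
    if ss is not None:
        features.add("ss")
    if disorder is not None:
        features.add("disorder")
    x = encode_inputs(region, ss=ss, disorder=disorder, vina=vina.values, features=features)
    preds = ensemble_predict(models, x)

    motif_rows = []
    if motif_pattern:
        for inst in scan_motif(region.seq, motif_pattern, parent_id=sequence.id):
            mean_score = float(preds[inst.start - 1 : inst.end].mean())
            motif_rows.append(
                {
                    "start": region.start + inst.start - 1,
                    "end": region.start + inst.end - 1,
                    "motif": inst.matched,
                    "mean_score": mean_score,
                    "above_threshold": mean_score > threshold,
                }
            )
    report = PredictionReport(
        region=region,
        predictions=preds,
        motif_averages=pd.DataFrame(
            motif_rows, columns=["start", "end", "motif", "mean_score", "above_threshold"]
        ),
        threshold=threshold,
    )
    report.frame().to_csv(outdir / "predictions.tsv", sep="\t", index=False, float_format="%.6g")
    if motif_rows:
        report.motif_averages.to_csv(
            outdir / "motif_averages.tsv", sep="\t", index=False, float_format="%.6g"
        )
    return report
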