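"""Date-based data splitting, two-fold cross-validation and error metrics.

The train/validation protocol emulates the arrival of novel genomes: the
genome set is split into three parts by release date.  The oldest part
serves exclusively as the reference database for the nearest-neighbor
search; the two recent parts are used interchangeably for training and
validation in a simple two-fold cross-validation (train on one, validate
on the other, average the two validation errors).  Errors are reported
as mean and median absolute error in percentage points, with signed
errors (predicted - truth) for bias inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .reference_db import BuildParams, ReferenceDatabase, build_reference_db
from .simulate import SimulatedBin, SyntheticWorld, simulate_bin
from .profiles import toy_annotate
from .stage2 import (
    LeakageError,
    Prediction,
    QueryBin,
    QualityModel,
    Stage2Config,
    predict_quality,
    train_quality_model,
)


@dataclass
class DateSplit:
    """Three disjoint genome-id sets determined by two split dates.

    Half-open convention: part1 = release < d1, part2 = d1 <= release
    < d2, part3 = release >= d2 (an entry dated exactly on a split date
    goes to the later part).
    """

    split_dates: Tuple[date, date]
    part1: Set[str]
    part2: Set[str]
    part3: Set[str]

    @property
    def parts(self) -> Tuple[Set[str], Set[str], Set[str]]:
        return (self.part1, self.part2, self.part3)


def date_split(entries, d1: date, d2: date) -> DateSplit:
    """Split dated entries (anything with genome_id and release_date)."""
    if not d1 < d2:
        raise ValueError(f"split dates must satisfy d1 < d2, got {d1} >= {d2}")
    parts: Tuple[Set[str], Set[str], Set[str]] = (set(), set(), set())
    for e in entries:
        if e.release_date is None:
            raise ValueError(f"entry {e.genome_id!r} has no release date")
        if e.release_date < d1:
            parts[0].add(e.genome_id)
        elif e.release_date < d2:
            parts[1].add(e.genome_id)
        else:
            parts[2].add(e.genome_id)
    return DateSplit((d1, d2), *parts)


@dataclass
class ErrorMetrics:
    """Absolute-error aggregates in percentage points."""

    mae: float
    median_ae: float
    sd: float  # standard deviation of the absolute errors
    signed_errors: np.ndarray

    @property
    def max_ae(self) -> float:
        return float(np.max(np.abs(self.signed_errors)))


def error_metrics(truth: Sequence[float], predicted: Sequence[float]) -> ErrorMetrics:
    """MAE / median AE / sd over (predicted - truth), scaled to %pt."""
    truth = np.asarray(truth, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if truth.shape != predicted.shape or truth.ndim != 1 or len(truth) < 1:
        raise ValueError("truth and predicted must be equal-length 1-d vectors")
    signed = (predicted - truth) * 100.0
    abs_err = np.abs(signed)
    return ErrorMetrics(
        mae=float(abs_err.mean()),
        median_ae=float(np.median(abs_err)),
        sd=float(abs_err.std()),
        signed_errors=signed,
    )


# ---------------------------------------------------------------------------
# Evaluating a predictor over a set of bins
# ---------------------------------------------------------------------------

@dataclass
class BinEvaluation:
    """Per-bin predictions plus stage-wise aggregates for one bin set."""

    predictions: List[Prediction]
    bins: List[QueryBin]
    stage1_completeness: ErrorMetrics
    stage1_contamination: ErrorMetrics
    final_completeness: ErrorMetrics
    final_contamination: ErrorMetrics
    n_rejected: int


def evaluate_bins(
    bins: Sequence[QueryBin],
    db: ReferenceDatabase,
    model: Optional[QualityModel],
    config: Optional[Stage2Config] = None,
) -> BinEvaluation:
    """Run the full pipeline on every bin and score against ground truth.

    Stage-I metrics use the marker-based estimates alone; final metrics
    use the pipeline output (stage II where routed, stage I otherwise).
    Rejected bins are counted but excluded from the error aggregates.
    """
    preds, kept = [], []
    for b in bins:
        p = predict_quality(b.profile, db, model, config, b.bin_id)
        preds.append(p)
        if p.stage_used != "rejected":
            kept.append((b, p))
    if not kept:
        raise ValueError("every bin was rejected; nothing to evaluate")
    tc = [b.truth_completeness for b, _ in kept]
    tk = [b.truth_contamination for b, _ in kept]
    s1c = [p.stage1.completeness_clamped for _, p in kept]
    s1k = [p.stage1.contamination for _, p in kept]
    fc = [p.completeness for _, p in kept]
    fk = [p.contamination for _, p in kept]
    return BinEvaluation(
        predictions=preds,
        bins=list(bins),
        stage1_completeness=error_metrics(tc, s1c),
        stage1_contamination=error_metrics(tk, s1k),
        final_completeness=error_metrics(tc, fc),
        final_contamination=error_metrics(tk, fk),
        n_rejected=len(bins) - len(kept),
    )


# ---------------------------------------------------------------------------
# Two-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    fold_a: BinEvaluation  # trained on part2, validated on part3
    fold_b: BinEvaluation  # trained on part3, validated on part2
    mae_completeness: float  # averaged over the two validation folds
    mae_contamination: float
    stage1_mae_completeness: float
    stage1_mae_contamination: float


def cross_validate_2fold(
    part2_bins: Sequence[QueryBin],
    part3_bins: Sequence[QueryBin],
    reference_db: ReferenceDatabase,
    config: Optional[Stage2Config] = None,
) -> CrossValidationResult:
    """Train on one part, validate on the other, in both directions."""
    g2 = {b.source_genome for b in part2_bins if b.source_genome}
    g3 = {b.source_genome for b in part3_bins if b.source_genome}
    if g2 & g3:
        raise LeakageError(
            f"parts share source genomes: {sorted(g2 & g3)[:5]}"
        )
    config = config or Stage2Config()
    model_a = train_quality_model(part2_bins, reference_db, config)
    fold_a = evaluate_bins(part3_bins, reference_db, model_a, config)
    model_b = train_quality_model(part3_bins, reference_db, config)
    fold_b = evaluate_bins(part2_bins, reference_db, model_b, config)
    return CrossValidationResult(
        fold_a=fold_a,
        fold_b=fold_b,
        mae_completeness=(
            fold_a.final_completeness.mae + fold_b.final_completeness.mae
        ) / 2.0,
        mae_contamination=(
            fold_a.final_contamination.mae + fold_b.final_contamination.mae
        ) / 2.0,
        stage1_mae_completeness=(
            fold_a.stage1_completeness.mae + fold_b.stage1_completeness.mae
        ) / 2.0,
        stage1_mae_contamination=(
            fold_a.stage1_contamination.mae + fold_b.stage1_contamination.mae
        ) / 2.0,
    )


# ---------------------------------------------------------------------------
# End-to-end synthetic-world experiment
# ---------------------------------------------------------------------------

def simulate_query_bins(
    world: SyntheticWorld,
    genome_ids: Set[str],
    n_bins_per_genome: int,
    rng: np.random.Generator,
    fragment_length: int = 20_000,
) -> List[QueryBin]:
    """Simulate and annotate bins for a genome subset.

    Contaminants are drawn from the same subset, so bins built from
    disjoint genome sets stay leakage-free.
    """
    genomes = [g for g in world.genomes if g.genome_id in genome_ids]
    pool = genomes
    out: List[QueryBin] = []
    for g in genomes:
        for j in range(n_bins_per_genome):
            sb = simulate_bin(
                g, pool, rng, fragment_length=fragment_length,
                bin_id=f"{g.genome_id}_b{j:02d}",
            )
            profile = toy_annotate(sb.contigs, world.catalog, sb.bin_id)
            out.append(
                QueryBin(
                    bin_id=sb.bin_id,
                    profile=profile,
                    truth_completeness=sb.truth_completeness,
                    truth_contamination=sb.truth_contamination,
                    source_genome=sb.source_genome,
                )
            )
    return out


@dataclass
class ExperimentResult:
    db: ReferenceDatabase
    split: DateSplit
    cv: CrossValidationResult


def run_world_experiment(
    world: SyntheticWorld,
    config: Optional[Stage2Config] = None,
    n_bins_per_genome: int = 20,
    fragment_length: int = 20_000,
    split_dates: Tuple[date, date] = (date(2021, 1, 1), date(2023, 1, 1)),
    seed: int = 1,
    build_params: Optional[BuildParams] = None,
) -> ExperimentResult:
    """Full protocol on a synthetic world.

    Date-split the genomes, build the reference database from the oldest
    part, simulate bins for the two recent parts (contaminants drawn
    within each part) and run the two-fold cross-validation.
    """
    config = config or Stage2Config()
    split = date_split(world.genomes, *split_dates)
    db = build_reference_db(
        world.reference_entries(split.part1), build_params or BuildParams()
    )
    rng = np.random.default_rng(seed)
    part2_bins = simulate_query_bins(
        world, split.part2, n_bins_per_genome, rng, fragment_length
    )
    part3_bins = simulate_query_bins(
        world, split.part3, n_bins_per_genome, rng, fragment_length
    )
    cv = cross_validate_2fold(part2_bins, part3_bins, db, config)
    return ExperimentResult(db=db, split=split, cv=cv)
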