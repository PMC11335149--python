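"""End-to-end experiment drivers: GED enhancement -> windows -> training ->
interpretation -> ablation, wired to the block-wise evaluation protocol.

These functions are the package's reproducible experiments on synthetic
cohorts: they are used by the command-line interface, the acceptance tests,
and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ablation as abl
from .data_model import (
    CVSplit,
    RegionTrialSet,
    WindowSample,
    assign_blocks,
    make_pair_index,
    make_within_splits,
    sliding_windows,
)
from .gedb import enhance_participant
from .interpret import align_filter_signs, kmeans_cosine, significant_interactions
from .model import InteractionDecoder, ModelConfig, build_model, extract_spatial_filters
from .training import TrainReport, evaluate_accuracy, split_windows, train_decoder


@dataclass
class FoldRun:
    """Everything a downstream analysis needs from one trained fold."""

    model: InteractionDecoder
    report: TrainReport
    windows: list[WindowSample]
    split: CVSplit


def windows_for_participant(
    trial_set: RegionTrialSet,
    train_trial_ids,
    block_ids: np.ndarray,
    window_seconds: float = 5.0,
    overlap: float = 0.5,
    shrinkage: float = 0.01,
) -> list[WindowSample]:
    """Enhance all trials (GED fit on the training trials only) and window them."""
    enhanced = enhance_participant(
        trial_set, train_trial_ids=train_trial_ids, shrinkage=shrinkage, block_ids=block_ids
    )
    out: list[WindowSample] = []
    for et in enhanced:
        out.extend(sliding_windows(et, window_seconds, overlap))
    return out


def run_within_fold(
    trial_set: RegionTrialSet,
    fold_id: int = 0,
    n_blocks: int = 4,
    split_seed: int = 0,
    window_seconds: float = 5.0,
    overlap: float = 0.5,
    epochs: int = 200,
    batch_size: int = 32,
    train_seed: int = 0,
    lr: float = 1e-3,
    config: ModelConfig | None = None,
) -> FoldRun:
    """Train and evaluate one within-participant fold.

    The GED components are fit on that fold's training blocks only, so the
    enhanced representation never sees validation or test statistics.
    """
    config = config or ModelConfig(fs=trial_set.fs)
    splits = make_within_splits(trial_set, n_blocks=n_blocks, seed=split_seed)
    split = splits[fold_id]
    blocks = assign_blocks(trial_set.conditions, n_blocks, split_seed, labels=trial_set.labels)
    windows = windows_for_participant(
        trial_set, split.train_ids, blocks, window_seconds, overlap
    )
    T = windows[0].data.shape[1]
    model = build_model(config, window_len=T, seed=train_seed)
    report = train_decoder(
        model, split, windows, epochs=epochs, batch_size=batch_size, seed=train_seed, lr=lr
    )
    return FoldRun(model=model, report=report, windows=windows, split=split)


def run_within_participant(
    trial_set: RegionTrialSet, folds: list[int] | None = None, **kwargs
) -> list[FoldRun]:
    """All (or selected) folds of the within-participant protocol."""
    n_blocks = kwargs.get("n_blocks", 4)
    folds = folds if folds is not None else list(range(n_blocks))
    return [run_within_fold(trial_set, fold_id=f, **kwargs) for f in folds]


@dataclass
class RecoveryResult:
    """One parameter-recovery replicate on planted synthetic data."""

    test_accuracy: float
    planted_pair_recovered: bool
    significant_union: set[int] = field(default_factory=set)
    band_drops: dict[str, float] = field(default_factory=dict)
    alpha_drop_largest: bool = False


def recovery_replicate(
    trial_set: RegionTrialSet,
    planted_pair: tuple[str, str] = ("RP", "LP"),
    fold_id: int = 0,
    split_seed: int = 0,
    train_seed: int = 0,
    epochs: int = 200,
    **kwargs,
) -> RecoveryResult:
    """Train one fold on planted data and ask three recovery questions.

    1. held-out accuracy of the trained decoder;
    2. does the planted region pair appear among the significant
       interactions of at least one cluster centroid of the model's
       (sign-aligned) spatial filters?
    3. does a band-stop of the planted (alpha) band hurt test accuracy more
       than stopping any other canonical band?
    """
    run = run_within_fold(
        trial_set,
        fold_id=fold_id,
        split_seed=split_seed,
        train_seed=train_seed,
        epochs=epochs,
        **kwargs,
    )
    model, split, windows = run.model, run.split, run.windows
    _, _, test_w = split_windows(windows, split)

    filters = align_filter_signs(extract_spatial_filters(model).filters)
    km = kmeans_cosine(filters, k=min(4, len(filters)), seed=train_seed)
    union: set[int] = set()
    for fid, centroid in enumerate(km.centroids):
        union.update(significant_interactions(centroid, filter_id=fid).indices.tolist())
    pidx = make_pair_index().index_of(*planted_pair)

    base_acc = run.report.test_accuracy
    drops = {}
    for code in abl.ABLATION_BANDS:
        filtered = abl.band_filter_inputs(test_w, code, mode="stop", fs=trial_set.fs)
        drops[code] = base_acc - evaluate_accuracy(model, filtered)
    alpha_largest = all(drops["alpha"] > v for c, v in drops.items() if c != "alpha")

    return RecoveryResult(
        test_accuracy=base_acc,
        planted_pair_recovered=pidx in union,
        significant_union=union,
        band_drops=drops,
        alpha_drop_largest=alpha_largest,
    )


def planted_recovery_study(
    n_replicates: int = 10,
    n_participants: int = 4,
    n_trials: int = 24,
    epochs: int = 70,
    seed: int = 0,
    window_seconds: float = 5.0,
    planted_pair: tuple[str, str] = ("RP", "LP"),
) -> list[RecoveryResult]:
    """Parameter-recovery study on the default planted cohort.

    Generates a reduced synthetic cohort (defaults: 4 participants, 24
    trials each) with the default planted effects, then runs
    ``n_replicates`` seeded replicates; replicate ``r`` trains one
    within-participant fold (a distinct participant/fold combination per
    replicate) and evaluates accuracy, planted-pair recovery in the
    significant interactions, and per-band input-ablation drops.
    """
    from .synthetic import GeneratorSpec, generate

    spec = GeneratorSpec(
        n_participants=n_participants, n_trials=n_trials, seed=seed % 2**31
    )
    cohort, _truth = generate(spec)
    results = []
    for r in range(n_replicates):
        ts = cohort[r % n_participants]
        results.append(
            recovery_replicate(
                ts,
                planted_pair=planted_pair,
                fold_id=(r % 4 + r // 4) % 4,
                split_seed=(seed + 17 * r) % 2**31,
                train_seed=(seed + 101 * r) % 2**31,
                epochs=epochs,
                window_seconds=window_seconds,
            )
        )
    return results


def chance_level_study(
    seed: int = 0,
    n_trials: int = 24,
    epochs: int = 40,
    folds: tuple[int, ...] = (0, 1),
    window_seconds: float = 5.0,
) -> tuple[float, int]:
    """Null control: label-shuffled planted data should decode at chance.

    Trains one model per listed fold on a label-shuffled participant and
    pools test-window hits across folds.  Returns (pooled accuracy, pooled
    window count).
    """
    from .synthetic import GeneratorSpec, generate
    from .training import evaluate_accuracy as _acc

    spec = GeneratorSpec(n_participants=1, n_trials=n_trials, seed=seed % 2**31)
    cohort, _ = generate(spec)
    null_ts = shuffle_labels(cohort[0], seed=(seed + 1) % 2**31)
    hits = 0
    total = 0
    for f in folds:
        run = run_within_fold(
            null_ts,
            fold_id=f,
            split_seed=(seed + f) % 2**31,
            train_seed=(seed + 31 * f) % 2**31,
            epochs=epochs,
            window_seconds=window_seconds,
        )
        _, _, test_w = split_windows(run.windows, run.split)
        acc = run.report.test_accuracy
        hits += round(acc * len(test_w))
        total += len(test_w)
    return hits / total, total


def shuffle_labels(trial_set: RegionTrialSet, seed: int = 0) -> RegionTrialSet:
    """Copy of a trial set with trial labels randomly permuted (null control).

    Shuffling at the trial level keeps all windows of a trial consistently
    labelled, so the block-wise protocol still prevents window leakage while
    destroying any label-signal association.
    """
    rng = np.random.default_rng(seed)
    labels = list(trial_set.labels)
    rng.shuffle(labels)
    return RegionTrialSet(
        participant_id=trial_set.participant_id,
        trials=trial_set.trials,
        fs=trial_set.fs,
        labels=labels,
        conditions=list(trial_set.conditions),
        region_order=trial_set.region_order,
    )
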