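"""Canonical containers, region/pair indexing, sliding windows, and CV protocols.

The decoding substrate is organised around 10 coarse cortical regions of
interest (left/right occipital, parietal, temporal, central, frontal).  Each
region contributes several source time courses per trial; after band
enhancement each region contributes exactly three channels (one per frequency
band), giving the canonical 30-channel representation the decoder consumes.

Two evaluation protocols are provided:

* within-participant: trials are assigned to 4 condition-stratified blocks;
  each fold uses 2 blocks for training, 1 for validation, 1 for testing, and
  every block is the test block exactly once.  Windows never straddle blocks,
  so 50%-overlapping windows cannot leak between partitions.
* cross-participant: each participant is the test set in ``n_repeats``
  iterations; in each iteration ``n_val`` other participants form the
  validation set and the rest the training set.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

logger = logging.getLogger(__name__)

#: Canonical region order: left hemisphere first, then right, each in
#: occipital, parietal, temporal, central, frontal order.
REGION_ORDER: tuple[str, ...] = ("LO", "LP", "LT", "LC", "LF", "RO", "RP", "RT", "RC", "RF")

#: Canonical band order for the enhanced 30-channel representation.
BAND_ORDER: tuple[str, ...] = ("delta_theta", "alpha", "beta")

LEFT_REGIONS: tuple[str, ...] = ("LO", "LP", "LT", "LC", "LF")
RIGHT_REGIONS: tuple[str, ...] = ("RO", "RP", "RT", "RC", "RF")

#: Bilateral lobe name -> (left code, right code).
LOBES: dict[str, tuple[str, str]] = {
    "occipital": ("LO", "RO"),
    "parietal": ("LP", "RP"),
    "temporal": ("LT", "RT"),
    "central": ("LC", "RC"),
    "frontal": ("LF", "RF"),
}

CLASSES: tuple[str, str] = ("left", "right")


class InvalidRegionError(ValueError):
    """A region code is unknown, duplicated, or missing."""


class InfeasibleSplitError(ValueError):
    """Requested cross-validation split cannot be constructed."""


@dataclass
class RegionTrialSet:
    """Per-participant collection of trials of region-grouped source signals.

    ``trials[k][region]`` is an ``(n_sources, n_samples)`` array of source
    time courses (arbitrary amplitude units).  All trials share the sampling
    rate and the per-region source count; trial length may vary.
    """

    participant_id: str
    trials: list[dict[str, np.ndarray]]
    fs: float
    labels: list[str]
    conditions: list[str]
    region_order: tuple[str, ...] = REGION_ORDER

    def __post_init__(self) -> None:
        if len(set(self.region_order)) != 10 or set(self.region_order) != set(REGION_ORDER):
            raise InvalidRegionError(
                f"region_order must be a permutation of the 10 canonical codes, got {self.region_order}"
            )
        if not (len(self.labels) == len(self.conditions) == len(self.trials)):
            raise ValueError("labels and conditions must have one entry per trial")
        for k, trial in enumerate(self.trials):
            if set(trial) != set(self.region_order):
                raise InvalidRegionError(f"trial {k} regions {sorted(trial)} != canonical set")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class EnhancedTrial:
    """The 30 x T band-enhanced representation of a single trial.

    Channels are ordered region-major: for each region in the canonical
    region order, its delta-theta, alpha, and beta components appear
    contiguously.
    """

    data: np.ndarray  # (30, T)
    channel_index: tuple[tuple[str, str], ...]
    fs: float
    label: str
    condition: str
    trial_id: int = -1
    block_id: int = -1
    participant_id: str = ""

    def __post_init__(self) -> None:
        if self.data.shape[0] != 30:
            raise ValueError(f"expected 30 channels, got {self.data.shape[0]}")


@dataclass
class WindowSample:
    """A 30 x T decoder input window with its provenance."""

    data: np.ndarray
    label: str
    trial_id: int
    block_id: int
    participant_id: str = ""
    condition: str = ""


@dataclass(frozen=True)
class PairIndex:
    """Canonical ordering of the 45 unordered region pairs."""

    pairs: tuple[tuple[str, str], ...]
    lookup: dict[tuple[str, str], int] = field(repr=False, default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def index_of(self, a: str, b: str) -> int:
        return self.lookup[(a, b)]

    def pairs_touching(self, region: str) -> list[int]:
        """Indices of all pairs that contain ``region``."""
        return [k for k, (a, b) in enumerate(self.pairs) if region in (a, b)]


@dataclass(frozen=True)
class CVSplit:
    """One cross-validation fold.

    For ``scope == "within"`` the id sets contain trial indices (all windows
    of a trial follow their trial); for ``scope == "cross"`` they contain
    participant ids.
    """

    fold_id: int
    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset
    scope: str

    def __post_init__(self) -> None:
        if (
            self.train_ids & self.val_ids
            or self.train_ids & self.test_ids
            or self.val_ids & self.test_ids
        ):
            raise ValueError("train/val/test sets must be pairwise disjoint")


def canonical_channel_index(
    region_order: tuple[str, ...] = REGION_ORDER,
    band_order: tuple[str, ...] = BAND_ORDER,
) -> tuple[tuple[str, str], ...]:
    """Region-major crossing of regions and bands: 30 (region, band) pairs."""
    return tuple((r, b) for r in region_order for b in band_order)


def make_pair_index(region_order: tuple[str, ...] = REGION_ORDER) -> PairIndex:
    """Enumerate unordered region pairs in lexicographic (i, j), i < j order.

    For the canonical 10 regions this yields the 45 interaction channels of
    the decoder; the symmetric ``lookup`` maps either orientation of a pair
    to its channel index.
    """
    if len(set(region_order)) != len(region_order):
        raise InvalidRegionError(f"duplicate region codes in {region_order}")
    pairs = tuple(
        (region_order[i], region_order[j])
        for i, j in itertools.combinations(range(len(region_order)), 2)
    )
    lookup: dict[tuple[str, str], int] = {}
    for k, (a, b) in enumerate(pairs):
        lookup[(a, b)] = k
        lookup[(b, a)] = k
    return PairIndex(pairs=pairs, lookup=lookup)


def sliding_windows(
    trial: EnhancedTrial, window_seconds: float, overlap_fraction: float = 0.5
) -> list[WindowSample]:
    """Cut a trial into fixed-length windows with fractional overlap.

    Windows start every ``round((1 - overlap) * T)`` samples and must lie
    fully inside the trial; a final partial window is dropped.  Each window
    inherits the trial's label, condition, and block id.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    T = int(round(window_seconds * trial.fs))
    n_samples = trial.data.shape[1]
    if T > n_samples:
        logger.warning(
            "window of %d samples longer than trial of %d samples; no windows produced",
            T,
            n_samples,
        )
        return []
    step = int(round((1.0 - overlap_fraction) * T))
    step = max(step, 1)
    out = []
    for start in range(0, n_samples - T + 1, step):
        out.append(
            WindowSample(
                data=trial.data[:, start : start + T],
                label=trial.label,
                trial_id=trial.trial_id,
                block_id=trial.block_id,
                participant_id=trial.participant_id,
                condition=trial.condition,
            )
        )
    return out


def assign_blocks(
    conditions: list[str], n_blocks: int, seed: int, labels: list[str] | None = None
) -> np.ndarray:
    """Stratified random assignment of trials to blocks.

    Trials are stratified by condition (and jointly by class label when
    given), shuffled within each stratum, and dealt round-robin over blocks,
    so each block receives an (as near as possible) equal share of every
    condition and class.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    strata = (
        list(conditions)
        if labels is None
        else [f"{c}|{l}" for c, l in zip(conditions, labels)]
    )
    blocks = np.empty(len(strata), dtype=int)
    slot = 0
    for stratum in sorted(set(strata)):
        idx = np.flatnonzero(np.asarray(strata, dtype=object) == stratum)
        rng.shuffle(idx)
        for i, t in enumerate(idx):
            blocks[t] = (slot + i) % n_blocks
        slot += len(idx)
    return blocks


def make_within_splits(
    trial_set: RegionTrialSet, n_blocks: int = 4, seed: int = 0
) -> list[CVSplit]:
    """Block-wise within-participant folds: 2 train / 1 val / 1 test blocks.

    Trials are assigned to ``n_blocks`` condition-stratified blocks (see
    :func:`assign_blocks`); fold ``f`` tests on block ``f``, validates on
    block ``(f + 1) % n_blocks``, and trains on the rest.  Id sets contain
    trial indices, so all windows of a trial stay in one partition.
    """
    if trial_set.n_trials < n_blocks:
        raise InfeasibleSplitError(
            f"{trial_set.n_trials} trials cannot fill {n_blocks} blocks"
        )
    blocks = assign_blocks(trial_set.conditions, n_blocks, seed, labels=trial_set.labels)
    splits = []
    for f in range(n_blocks):
        test_b = f
        val_b = (f + 1) % n_blocks
        test_ids = frozenset(np.flatnonzero(blocks == test_b).tolist())
        val_ids = frozenset(np.flatnonzero(blocks == val_b).tolist())
        train_ids = frozenset(
            np.flatnonzero((blocks != test_b) & (blocks != val_b)).tolist()
        )
        splits.append(
            CVSplit(fold_id=f, train_ids=train_ids, val_ids=val_ids, test_ids=test_ids, scope="within")
        )
    return splits


def make_cross_splits(
    participant_ids: list[str], n_val: int, n_repeats: int, seed: int = 0
) -> list[CVSplit]:
    """Leave-one-participant-out folds with randomly drawn validation sets.

    For each participant ``p`` and each of ``n_repeats`` iterations, ``p`` is
    the test set, ``n_val`` randomly chosen others form the validation set,
    and the remaining participants the training set.  With 18 participants,
    ``n_val=4`` and ``n_repeats=5`` this yields the 90-fold cross-participant
    scheme (13 training participants per fold).
    """
    ids = list(participant_ids)
    if n_val >= len(ids) - 1:
        raise InfeasibleSplitError(
            f"n_val={n_val} leaves no training participants out of {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    splits = []
    fold = 0
    for p in ids:
        others = [q for q in ids if q != p]
        for _ in range(n_repeats):
            val = rng.choice(len(others), size=n_val, replace=False)
            val_ids = frozenset(others[i] for i in val)
            train_ids = frozenset(others) - val_ids
            splits.append(
                CVSplit(
                    fold_id=fold,
                    train_ids=train_ids,
                    val_ids=val_ids,
                    test_ids=frozenset({p}),
                    scope="cross",
                )
            )
            fold += 1
    return splits


# ---------------------------------------------------------------------------
# Container I/O: one HDF5 file per participant plus a JSON sidecar.
# ---------------------------------------------------------------------------

def save_region_trial_set(path: str, trial_set: RegionTrialSet) -> None:
    """Write ``/trials/<k>/<region>`` matrices plus a ``<path>.json`` sidecar."""
    with h5py.File(path, "w") as h5:
        grp = h5.create_group("trials")
        for k, trial in enumerate(trial_set.trials):
            tg = grp.create_group(str(k))
            for region, mat in trial.items():
                tg.create_dataset(region, data=np.asarray(mat, dtype=np.float64))
    sidecar = {
        "participant_id": trial_set.participant_id,
        "fs": trial_set.fs,
        "labels": list(trial_set.labels),
        "conditions": list(trial_set.conditions),
        "region_order": list(trial_set.region_order),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_region_trial_set(path: str) -> RegionTrialSet:
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    trials: list[dict[str, np.ndarray]] = []
    with h5py.File(path, "r") as h5:
        keys = sorted(h5["trials"], key=int)
        for k in keys:
            trials.append({region: h5["trials"][k][region][()] for region in h5["trials"][k]})
    return RegionTrialSet(
        participant_id=sidecar["participant_id"],
        trials=trials,
        fs=sidecar["fs"],
        labels=sidecar["labels"],
        conditions=sidecar["conditions"],
        region_order=tuple(sidecar["region_order"]),
    )
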