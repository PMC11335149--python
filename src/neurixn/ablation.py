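"""Ablation retests of trained decoders — no retraining involved.

Two families of ablation are supported:

* kernel knockouts: zeroing spatial-filter columns for all pairs touching a
  bilateral region, a hemisphere, or the significant interactions of a
  cluster centroid, then re-decoding the test windows;
* input-band manipulations: zero-phase band-stop (remove one canonical band
  from test inputs) or band-pass (keep only one band), applied to test
  windows of an unchanged model.

Both quantify how much of the decoder's accuracy rests on a region, a
hemisphere, an interaction set, or a frequency band.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .data_model import LEFT_REGIONS, LOBES, RIGHT_REGIONS, PairIndex, WindowSample
from .gedb import InvalidBandError
from .interpret import significant_interactions
from .model import InteractionDecoder
from .training import BASELINE_BANDS, BaselineModel, evaluate_accuracy

#: Frequency bands used for input-side ablations (the four canonical bands).
ABLATION_BANDS: dict[str, tuple[float, float]] = {
    code: (lo, hi) for code, lo, hi in BASELINE_BANDS
}

KERNEL_KINDS = ("region", "hemisphere", "cluster")
INPUT_KINDS = ("band_stop", "band_pass")


class WrongMaskKindError(TypeError):
    """An input-kind mask was passed where a kernel-kind mask is needed (or
    vice versa)."""


@dataclass(frozen=True)
class AblationMask:
    kind: str
    zeroed_pair_indices: frozenset = field(default_factory=frozenset)
    band: tuple[float, float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind in KERNEL_KINDS:
            if self.band is not None:
                raise WrongMaskKindError("kernel-kind masks specify pair indices only")
        elif self.kind in INPUT_KINDS:
            if self.zeroed_pair_indices:
                raise WrongMaskKindError("input-kind masks specify a band only")
        else:
            raise ValueError(f"unknown mask kind {self.kind!r}")


def region_mask(region_name: str, pair_index: PairIndex) -> AblationMask:
    """Zero all pairs touching the left or right instance of a lobe.

    Each lobe appears in 9 + 9 - 1 = 17 of the 45 pairs (the bilateral pair
    is shared).
    """
    if region_name not in LOBES:
        raise ValueError(f"unknown region {region_name!r}; choose from {sorted(LOBES)}")
    left, right = LOBES[region_name]
    idx = set(pair_index.pairs_touching(left)) | set(pair_index.pairs_touching(right))
    return AblationMask(kind="region", zeroed_pair_indices=frozenset(idx), name=region_name)


def hemisphere_mask(side: str, pair_index: PairIndex) -> AblationMask:
    """Zero all pairs touching any region of one hemisphere (35 of 45)."""
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    regions = LEFT_REGIONS if side == "left" else RIGHT_REGIONS
    idx: set[int] = set()
    for r in regions:
        idx.update(pair_index.pairs_touching(r))
    return AblationMask(kind="hemisphere", zeroed_pair_indices=frozenset(idx), name=side)


def cluster_mask(centroid: np.ndarray, p_threshold: float = 0.05, name: str = "") -> AblationMask:
    """Zero the significant interactions of a cluster centroid."""
    sig = significant_interactions(centroid, p_threshold=p_threshold)
    return AblationMask(
        kind="cluster", zeroed_pair_indices=frozenset(sig.indices.tolist()), name=name
    )


def apply_kernel_mask(model: InteractionDecoder, mask: AblationMask) -> InteractionDecoder:
    """Copy of the model with the masked spatial-filter columns zeroed.

    All 4 filters lose the same columns; the original model is untouched.
    """
    if mask.kind not in KERNEL_KINDS:
        raise WrongMaskKindError(f"{mask.kind!r} is not a kernel-kind mask")
    ablated = model.copy()
    idx = sorted(mask.zeroed_pair_indices)
    ablated.params["W4"][:, idx] = 0.0
    return ablated


def band_filter_inputs(
    windows: list[WindowSample],
    band: tuple[float, float] | str,
    mode: str = "stop",
    fs: float = 64.0,
    dc_block_hz: float = 0.5,
) -> list[WindowSample]:
    """Band-stop or band-pass test windows (zero-phase, per channel).

    ``mode="stop"`` removes the band with an order-4 Butterworth band-stop;
    ``mode="pass"`` keeps only the band (with a small DC block on the low
    edge to avoid offset artifacts).  Shapes and metadata are preserved.
    """
    if isinstance(band, str):
        band = ABLATION_BANDS[band]
    lo, hi = band
    if not 0 < lo < hi <= fs / 2:
        raise InvalidBandError(f"band ({lo}, {hi}) Hz invalid at fs={fs}")
    hi = min(hi, 0.998 * fs / 2)  # a band may touch Nyquist (beta at 64 Hz)
    if mode == "stop":
        sos = scipy.signal.butter(4, [lo, hi], btype="bandstop", fs=fs, output="sos")
    elif mode == "pass":
        sos = scipy.signal.butter(4, [max(lo, dc_block_hz), hi], btype="bandpass", fs=fs, output="sos")
    else:
        raise ValueError(f"mode must be 'stop' or 'pass', got {mode!r}")
    out = []
    for w in windows:
        out.append(
            WindowSample(
                data=scipy.signal.sosfiltfilt(sos, w.data, axis=-1),
                label=w.label,
                trial_id=w.trial_id,
                block_id=w.block_id,
                participant_id=w.participant_id,
                condition=w.condition,
            )
        )
    return out


def ablation_report(
    model: InteractionDecoder,
    conditions: list[tuple[str, AblationMask | None]],
    test_windows: list[WindowSample],
    fs: float = 64.0,
) -> pd.DataFrame:
    """Accuracy per ablation condition against the unablated model.

    ``conditions`` maps names to masks (kernel or input kind; ``None`` means
    unablated).  Returns a table of (condition, accuracy, delta_accuracy)
    where delta is relative to the unablated model.
    """
    base_acc = evaluate_accuracy(model, test_windows)
    rows = [{"condition": "original", "accuracy": base_acc, "delta_accuracy": 0.0}]
    for name, mask in conditions:
        if mask is None:
            continue
        if mask.kind in KERNEL_KINDS:
            acc = evaluate_accuracy(apply_kernel_mask(model, mask), test_windows)
        else:
            mode = "stop" if mask.kind == "band_stop" else "pass"
            acc = evaluate_accuracy(
                model, band_filter_inputs(test_windows, mask.band, mode=mode, fs=fs)
            )
        rows.append({"condition": name, "accuracy": acc, "delta_accuracy": acc - base_acc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Baseline-model mirror: zero logistic weights by region or band
# ---------------------------------------------------------------------------

def ablate_baseline(
    baseline: BaselineModel, region: str | None = None, band: str | None = None
) -> BaselineModel:
    """Copy of the baseline with the region's (2 x 4 entries, both
    hemispheres) or band's (10 entries) weights zeroed."""
    if (region is None) == (band is None):
        raise ValueError("specify exactly one of region or band")
    out = copy.deepcopy(baseline)
    n_bands = len(BASELINE_BANDS)
    if region is not None:
        if region not in LOBES:
            raise ValueError(f"unknown region {region!r}")
        from .data_model import REGION_ORDER

        for code in LOBES[region]:
            r = REGION_ORDER.index(code)
            out.weights[r * n_bands : (r + 1) * n_bands] = 0.0
    else:
        codes = [c for c, _, _ in BASELINE_BANDS]
        if band not in codes:
            raise ValueError(f"unknown band {band!r}")
        b = codes.index(band)
        out.weights[b::n_bands] = 0.0
    return out
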