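"""Synthetic region-level EEG generator with planted, class-dependent
band-specific structure.

The generator emulates the structure of a source-space auditory attention
dataset — 10 regions of interest with a few source time courses each, 50-s
trials at 64 Hz, two balanced attention classes (left/right), three
condition tags — while planting two kinds of recoverable ground truth:

* lateralization: a band's oscillation power in a set of regions differs
  between classes (attend-left raises the *right*-hemisphere members by
  ``power_ratio``, attend-right the left-hemisphere members), emulating the
  hemispheric alpha-power asymmetry that tracks attended direction;
* pairwise coupling: for each planted pair, the two regions' band
  oscillations share a slow (< 1 Hz) amplitude envelope in one class
  ("left") and are independent in the other, with modulation depth
  ``coupling_strength``.  The shared envelope is RMS-normalized so coupling
  changes co-modulation, not average band power.

Oscillations are band-filtered white noise (not sinusoids), so covariances
are well-conditioned; backgrounds are 1/f (pink) noise per source.
Condition tags carry no signal — they exist to exercise stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .data_model import (
    CLASSES,
    LEFT_REGIONS,
    REGION_ORDER,
    RIGHT_REGIONS,
    InvalidRegionError,
    RegionTrialSet,
)
from .gedb import CANONICAL_BANDS, GedBandSpec, bandpass

#: The class in which planted pair couplings are active.
COUPLED_CLASS = "left"


@dataclass
class GeneratorSpec:
    """Study conditions of the synthetic cohort (defaults emulate the real
    dataset's geometry: 18 participants, 60 trials of 50 s at 64 Hz)."""

    n_participants: int = 18
    n_trials: int = 60
    trial_seconds: float = 50.0
    fs: float = 64.0
    n_sources_per_roi: int = 3
    planted_pairs: tuple[tuple[str, str, str, float], ...] = (("RP", "LP", "alpha", 1.0),)
    lateralization: tuple[tuple[str, ...], str, float] = (("LP", "RP"), "alpha", 2.0)
    noise_sd: float = 1.0
    condition_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b, band, strength in self.planted_pairs:
            if a not in REGION_ORDER or b not in REGION_ORDER:
                raise InvalidRegionError(f"planted pair ({a}, {b}) has unknown region")
            if band not in {bs.band_code for bs in CANONICAL_BANDS}:
                raise ValueError(f"unknown band code {band!r}")
            if strength < 0:
                raise ValueError("coupling_strength must be >= 0")
        regions, band, ratio = self.lateralization
        for r in regions:
            if r not in REGION_ORDER:
                raise InvalidRegionError(f"lateralization region {r!r} unknown")
        if ratio <= 0:
            raise ValueError("power_ratio must be > 0")


@dataclass
class GroundTruth:
    planted_pairs: tuple[tuple[str, str, str, float], ...]
    lateralization: tuple[tuple[str, ...], str, float]
    labels: dict[str, list[str]] = field(default_factory=dict)  # participant -> per-trial class


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    spec = rng.normal(size=n // 2 + 1) + 1j * rng.normal(size=n // 2 + 1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    x = np.fft.irfft(spec / np.sqrt(f), n=n)
    return (x - x.mean()) / x.std()


def _band_osc(rng: np.random.Generator, n: int, band: GedBandSpec, fs: float) -> np.ndarray:
    """Unit-variance band-limited oscillation (filtered white noise)."""
    x = bandpass(rng.normal(size=n + 256), band.low_hz, band.high_hz, fs)[128:-128]
    return (x - x.mean()) / x.std()


def _slow_envelope(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float = 0.5) -> np.ndarray:
    """Standardized slow modulator (< 1 Hz)."""
    sos = scipy.signal.butter(4, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    m = scipy.signal.sosfiltfilt(sos, rng.normal(size=n + 512))[256:-256]
    return (m - m.mean()) / m.std()


def generate(spec: GeneratorSpec) -> tuple[list[RegionTrialSet], GroundTruth]:
    """Synthesize one :class:`RegionTrialSet` per participant plus ground truth.

    Deterministic for a fixed ``spec.seed``; participants draw from
    independent substreams of that seed.
    """
    bands = {b.band_code: b for b in CANONICAL_BANDS}
    lat_regions, lat_band, lat_ratio = spec.lateralization
    T = int(round(spec.trial_seconds * spec.fs))
    n = spec.n_trials
    truth = GroundTruth(planted_pairs=spec.planted_pairs, lateralization=spec.lateralization)
    participants = []
    master = np.random.default_rng(spec.seed)
    for pi in range(spec.n_participants):
        rng = np.random.default_rng(master.integers(2**31))
        pid = f"P{pi:02d}"
        labels = [CLASSES[0]] * (n // 2) + [CLASSES[1]] * (n - n // 2)
        rng.shuffle(labels)
        conditions = [f"cond{i % spec.condition_count}" for i in range(n)]
        # fixed per-participant source loadings, one spatial pattern per
        # (region, band): distinct oscillatory generators within a lobe give
        # the per-band eigendecomposition something to separate; patterns are
        # orthonormal within a region so the generators are identifiable
        loadings = {}
        for r in REGION_ORDER:
            gauss = rng.normal(size=(spec.n_sources_per_roi, len(bands)))
            q, _ = np.linalg.qr(gauss)
            for j, bc in enumerate(bands):
                loadings[(r, bc)] = q[:, j]
        trials = []
        for t in range(n):
            label = labels[t]
            osc = {
                (r, bc): _band_osc(rng, T, bands[bc], spec.fs)
                for r in REGION_ORDER
                for bc in bands
            }
            amp = {(r, bc): 1.0 for r in REGION_ORDER for bc in bands}
            boost = {"left": RIGHT_REGIONS, "right": LEFT_REGIONS}[label]
            for r in lat_regions:
                if r in boost:
                    amp[(r, lat_band)] *= np.sqrt(lat_ratio)
            for a, b, bc, strength in spec.planted_pairs:
                if strength > 0 and label == COUPLED_CLASS:
                    mod = np.exp(strength * _slow_envelope(rng, T, spec.fs))
                    mod /= np.sqrt(np.mean(mod**2))
                    osc[(a, bc)] = osc[(a, bc)] * mod
                    osc[(b, bc)] = osc[(b, bc)] * mod
            trial = {}
            for r in REGION_ORDER:
                src = sum(
                    np.outer(loadings[(r, bc)], amp[(r, bc)] * osc[(r, bc)]) for bc in bands
                )
                src += spec.noise_sd * np.stack(
                    [_pink_noise(rng, T) for _ in range(spec.n_sources_per_roi)]
                )
                trial[r] = src
            trials.append(trial)
        participants.append(
            RegionTrialSet(
                participant_id=pid,
                trials=trials,
                fs=spec.fs,
                labels=labels,
                conditions=conditions,
            )
        )
        truth.labels[pid] = labels
    return participants, truth


def summarize(
    trial_set: RegionTrialSet,
    bands: tuple[GedBandSpec, ...] = CANONICAL_BANDS,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diagnostic tables: per-region band powers and pairwise envelope
    correlations.

    Region summaries are projection-free (a fixed linear combination of
    sources could cancel a signed generator pattern): band power is the
    variance of the band-filtered signal averaged across the region's
    sources, and the region's band envelope is the source-average of the
    per-source Hilbert envelopes.  Returns ``(power_df, envcorr_df)`` per
    trial/region/band and per trial/pair/band (all 45 pairs by default).
    """
    from .data_model import make_pair_index

    if pairs is None:
        pairs = list(make_pair_index(trial_set.region_order).pairs)
    power_rows, corr_rows = [], []
    for t, trial in enumerate(trial_set.trials):
        label = trial_set.labels[t]
        env: dict[tuple[str, str], np.ndarray] = {}
        for r in trial_set.region_order:
            srcs = np.asarray(trial[r])
            for band in bands:
                filt = bandpass(srcs, band.low_hz, band.high_hz, trial_set.fs)
                power_rows.append(
                    {
                        "trial": t,
                        "label": label,
                        "region": r,
                        "band": band.band_code,
                        "power": float(np.var(filt, axis=1).mean()),
                    }
                )
                env[(r, band.band_code)] = np.abs(scipy.signal.hilbert(filt, axis=1)).mean(axis=0)
        for a, b in pairs:
            for band in bands:
                ea, eb = env[(a, band.band_code)], env[(b, band.band_code)]
                corr_rows.append(
                    {
                        "trial": t,
                        "label": label,
                        "region_i": a,
                        "region_j": b,
                        "band": band.band_code,
                        "env_corr": float(np.corrcoef(ea, eb)[0, 1]),
                    }
                )
    return pd.DataFrame(power_rows), pd.DataFrame(corr_rows)
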