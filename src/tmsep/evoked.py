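"""Baseline-normalized PSTHs, empirical significance bands, and phasic-event
detection for stimulus-evoked multiunit firing.

Each trial spans -500 ms to +1000 ms around a stimulus.  Spike counts per
half-open bin are converted to instantaneous firing rate and, trial by
trial, the mean baseline (-500 to 0 ms) rate is subtracted from every bin,
so the baseline mean of every trial is exactly zero by construction.
Trial-averaged trains are smoothed with a Gaussian kernel (sigma = 2 ms)
and compared against an empirical null band: the 2.5th and 97.5th
percentiles (linear-interpolation quantiles) of the averaged train's own
baseline bins, which controls the per-bin type-I error at 5%.

A significant phasic event is a maximal run of bins beyond one threshold
lasting more than 10 ms, where sub-threshold gaps of up to 10 ms between
runs of the same polarity are merged first (to accommodate jitter) and the
duration criterion is applied to the merged extent.  Events are then
labeled as the canonical response phases: short-latency (peak in 1-6 ms),
intermediate excitation (first excitation peaking after 6 ms), inhibition
(first suppression after it), and rebound excitation (first excitation
after the inhibition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .sigio import SpikeTrain, StimulusLog

__all__ = [
    "BinnedTrials",
    "SignificanceBand",
    "PhasicEvent",
    "bin_and_normalize",
    "average_trials",
    "significance_band",
    "smooth",
    "detect_phasic",
    "classify_phases",
    "extract_phase_fr",
    "significant_bin_times",
]

PHASE_LABELS = (
    "short_latency",
    "intermediate_excitation",
    "inhibition",
    "rebound_excitation",
    "unclassified",
)


@dataclass
class BinnedTrials:
    """Trial x bin matrix of baseline-normalized firing rate (events/s)."""

    matrix: np.ndarray
    bin_size_ms: float
    window_ms: Tuple[float, float]
    baseline_window_ms: Tuple[float, float]
    trial_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_baseline_bins(self) -> int:
        b0, b1 = self.baseline_window_ms
        return int(round((b1 - b0) / self.bin_size_ms))

    def bin_starts_ms(self) -> np.ndarray:
        return self.window_ms[0] + self.bin_size_ms * np.arange(self.n_bins)

    def bin_centers_ms(self) -> np.ndarray:
        return self.bin_starts_ms() + self.bin_size_ms / 2.0

    def baseline_bin_mask(self) -> np.ndarray:
        starts = self.bin_starts_ms()
        b0, b1 = self.baseline_window_ms
        return (starts >= b0) & (starts + self.bin_size_ms <= b1)

    def post_bin_mask(self) -> np.ndarray:
        return self.bin_starts_ms() >= 0.0


@dataclass
class SignificanceBand:
    """Empirical percentile band around the (zero) baseline mean."""

    lower: float
    upper: float
    n_baseline_samples: int
    alpha: float = 0.05


@dataclass
class PhasicEvent:
    """A significant excitation or inhibition epoch, half-open [onset, offset)."""

    polarity: str  # 'excitation' | 'inhibition'
    onset_ms: float
    offset_ms: float
    peak_normalized_fr: float
    peak_time_ms: float
    label: str = "unclassified"

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def bin_and_normalize(spikes: SpikeTrain, stim: StimulusLog,
                      bin_size_ms: float = 1.0,
                      window_ms: Tuple[float, float] = (-500.0, 1000.0),
                      baseline_window_ms: Tuple[float, float] = (-500.0, 0.0),
                      t_max: Optional[float] = None) -> BinnedTrials:
    """Bin spikes per trial and subtract each trial's mean baseline rate.

    Counts per half-open bin [edge_i, edge_{i+1}) are divided by the bin
    width to give instantaneous firing rate, then the trial's mean rate
    over the baseline bins is subtracted from every bin of that trial
    (baseline bins included), so each trial's baseline mean is exactly 0.

    Trials whose window overruns the recording (``t_max``, seconds, if
    given) are dropped with a warning.
    """
    n_bins_f = (window_ms[1] - window_ms[0]) / bin_size_ms
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9:
        raise ValueError("window length must be an integer number of bins")
    edges_ms = window_ms[0] + bin_size_ms * np.arange(n_bins + 1)
    bin_s = bin_size_ms / 1000.0

    onsets = stim.onsets
    keep = np.ones(len(onsets), dtype=bool)
    if t_max is not None:
        keep = (onsets + window_ms[0] / 1000.0 >= 0.0) & (onsets + window_ms[1] / 1000.0 <= t_max)
        if not keep.all():
            warnings.warn(
                f"dropped {int((~keep).sum())} trial(s) whose window overruns the recording",
                stacklevel=2,
            )
    ts = spikes.timestamps
    rows = []
    for onset in onsets[keep]:
        counts = np.diff(np.searchsorted(ts, onset + edges_ms / 1000.0))
        rows.append(counts / bin_s)
    matrix = np.asarray(rows, dtype=float).reshape(-1, n_bins)

    starts = edges_ms[:-1]
    b0, b1 = baseline_window_ms
    base_mask = (starts >= b0) & (starts + bin_size_ms <= b1)
    if base_mask.sum() == 0:
        raise ValueError("no baseline bins inside the window")
    matrix -= matrix[:, base_mask].mean(axis=1, keepdims=True)

    meta = pd.DataFrame({
        "trial": np.arange(len(onsets))[keep],
        "onset_s": onsets[keep],
        "intensity": stim.intensity_pct_mt[keep],
        "orientation": stim.orientation,
        "animal": stim.animal_id,
    })
    return BinnedTrials(matrix=matrix, bin_size_ms=bin_size_ms, window_ms=tuple(window_ms),
                        baseline_window_ms=tuple(baseline_window_ms), trial_meta=meta)


def average_trials(bt: BinnedTrials, group_by: Sequence[str] = ()) -> pd.DataFrame:
    """Average normalized-FR trains across trials, optionally per condition.

    Returns a DataFrame with one row per group: the grouping columns, the
    number of trials, and the averaged train (``train`` column).  When
    trials from several animals are pooled and ``'animal'`` is not a
    grouping key, animals are weighted equally (mean of per-animal means),
    the convention used for population averages; otherwise the plain
    arithmetic mean across trials is taken.
    """
    meta = bt.trial_meta.reset_index(drop=True)
    group_by = list(group_by)
    multi_animal = "animal" in meta.columns and meta["animal"].nunique() > 1
    inner = group_by + (["animal"] if multi_animal and "animal" not in group_by else [])

    def _mean_rows(idx):
        return bt.matrix[np.asarray(idx, dtype=int)].mean(axis=0)

    if inner:
        per_inner = []
        for key, sub in meta.groupby(inner, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            per_inner.append(dict(zip(inner, key), n_trials=len(sub), train=_mean_rows(sub.index)))
        inner_df = pd.DataFrame(per_inner)
        if inner == group_by:
            return inner_df
        # average the per-animal means with equal weight
        out = []
        grouped = inner_df.groupby(group_by, sort=True) if group_by else [((), inner_df)]
        for key, sub in grouped:
            key = key if isinstance(key, tuple) else (key,)
            train = np.mean(np.stack(sub["train"].to_numpy()), axis=0)
            out.append(dict(zip(group_by, key), n_trials=int(sub["n_trials"].sum()), train=train))
        return pd.DataFrame(out)
    return pd.DataFrame([{"n_trials": bt.n_trials, "train": bt.matrix.mean(axis=0)}])


def significance_band(train: np.ndarray, n_baseline_bins: int,
                      alpha: float = 0.05) -> SignificanceBand:
    """Percentile band from the averaged train's own baseline bins.

    ``lower``/``upper`` are the 100*alpha/2 and 100*(1-alpha/2) percentiles
    (2.5 / 97.5 by default) of the leading ``n_baseline_bins`` values.

    Quantiles use the Weibull (type-6) plotting-position convention,
    interpolating order statistics at ``p * (n + 1)``: for continuous
    i.i.d. samples the probability that a new value falls beyond the
    estimated quantile is then exactly ``alpha/2`` per tail, which is the
    nominal per-bin type-I error the band is meant to control.
    """
    if n_baseline_bins <= 0:
        raise ValueError("no baseline bins available for the significance band")
    if n_baseline_bins < 40:
        warnings.warn(
            f"only {n_baseline_bins} baseline bins: tail percentiles are unstable",
            stacklevel=2,
        )
    base = np.asarray(train, dtype=float)[:n_baseline_bins]
    lo, hi = np.percentile(base, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)],
                           method="weibull")
    return SignificanceBand(lower=float(lo), upper=float(hi),
                            n_baseline_samples=n_baseline_bins, alpha=alpha)


def smooth(train: np.ndarray, sigma_ms: float = 2.0, bin_size_ms: float = 1.0) -> np.ndarray:
    """Gaussian smoothing (kernel truncated at +/-4 sigma, unit sum, reflective
    boundary).  ``sigma_ms = 0`` returns the train unchanged."""
    if sigma_ms < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_ms == 0:
        return np.asarray(train, dtype=float).copy()
    return gaussian_filter1d(np.asarray(train, dtype=float),
                             sigma=sigma_ms / bin_size_ms, mode="reflect", truncate=4.0)


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def detect_phasic(train: np.ndarray, band: SignificanceBand, bin_size_ms: float = 1.0,
                  window_ms: Tuple[float, float] = (-500.0, 1000.0),
                  min_dur_ms: float = 10.0, max_gap_ms: float = 10.0,
                  search_window_ms: Optional[Tuple[float, float]] = None,
                  ) -> List[PhasicEvent]:
    """Detect significant phasic excitation/inhibition events.

    Per polarity independently: find maximal runs of bins beyond the
    threshold inside the search window (post-stimulus by default), merge
    consecutive runs separated by sub-threshold gaps <= ``max_gap_ms``,
    and keep merged runs whose total extent is strictly greater than
    ``min_dur_ms``.  Onset/offset are the outer edges of the first/last
    bin of the merged run.
    """
    if min_dur_ms <= 0:
        raise ValueError("min_dur_ms must be positive")
    train = np.asarray(train, dtype=float)
    starts = window_ms[0] + bin_size_ms * np.arange(len(train))
    if search_window_ms is None:
        search_window_ms = (0.0, window_ms[1])
    s0, s1 = search_window_ms
    in_search = (starts >= s0) & (starts + bin_size_ms <= s1)

    events: List[PhasicEvent] = []
    for polarity, beyond in (
        ("excitation", train > band.upper),
        ("inhibition", train < band.lower),
    ):
        runs = _runs(beyond & in_search)
        merged: List[Tuple[int, int]] = []
        for (a, b) in runs:
            if merged and (a - merged[-1][1] - 1) * bin_size_ms <= max_gap_ms:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        for (a, b) in merged:
            extent = (b + 1 - a) * bin_size_ms
            if extent > min_dur_ms:
                seg = train[a:b + 1]
                k = int(np.argmax(seg)) if polarity == "excitation" else int(np.argmin(seg))
                events.append(PhasicEvent(
                    polarity=polarity,
                    onset_ms=float(starts[a]),
                    offset_ms=float(starts[b] + bin_size_ms),
                    peak_normalized_fr=float(seg[k]),
                    peak_time_ms=float(starts[a + k] + bin_size_ms / 2.0),
                ))
    events.sort(key=lambda e: e.onset_ms)
    return events


def classify_phases(events: Sequence[PhasicEvent],
                    short_latency_window_ms: Tuple[float, float] = (1.0, 6.0),
                    ) -> List[PhasicEvent]:
    """Label events as the canonical response phases.

    Excitations peaking inside the short-latency window -> ``short_latency``;
    the first excitation peaking after that window -> ``intermediate_excitation``;
    the first inhibition starting after it -> ``inhibition``; the first
    excitation after that inhibition -> ``rebound_excitation``; anything
    else stays ``unclassified``.  Input order is preserved; labels are set
    on (shallow copies of) the events.
    """
    from copy import copy

    out = [copy(e) for e in sorted(events, key=lambda e: e.onset_ms)]
    w0, w1 = short_latency_window_ms
    intermediate = None
    inhibition = None
    rebound = None
    for e in out:
        if e.polarity == "excitation" and w0 <= e.peak_time_ms <= w1:
            e.label = "short_latency"
        elif e.polarity == "excitation" and e.peak_time_ms > w1 and intermediate is None:
            e.label = "intermediate_excitation"
            intermediate = e
        elif (e.polarity == "inhibition" and intermediate is not None
              and inhibition is None and e.onset_ms >= intermediate.onset_ms):
            e.label = "inhibition"
            inhibition = e
        elif (e.polarity == "excitation" and inhibition is not None
              and rebound is None and e.onset_ms >= inhibition.offset_ms):
            e.label = "rebound_excitation"
            rebound = e
    return out


def extract_phase_fr(bt: BinnedTrials, events: Sequence[PhasicEvent]) -> pd.DataFrame:
    """Per-trial mean normalized FR over each labeled phase's [onset, offset).

    Returns a tidy table keyed by (animal, trial, intensity, orientation,
    phase); unclassified events are skipped.
    """
    starts = bt.bin_starts_ms()
    rows = []
    for e in events:
        if e.label == "unclassified":
            continue
        mask = (starts >= e.onset_ms) & (starts + bt.bin_size_ms <= e.offset_ms)
        if not mask.any():
            continue
        vals = bt.matrix[:, mask].mean(axis=1)
        for i, v in enumerate(vals):
            m = bt.trial_meta.iloc[i]
            rows.append({
                "animal": m.get("animal", ""),
                "trial": m.get("trial", i),
                "intensity": m.get("intensity", np.nan),
                "orientation": m.get("orientation", ""),
                "phase": e.label,
                "mean_fr": float(v),
            })
    return pd.DataFrame(rows, columns=["animal", "trial", "intensity", "orientation", "phase", "mean_fr"])


def significant_bin_times(train: np.ndarray, band: SignificanceBand,
                          bin_size_ms: float, window_ms: Tuple[float, float],
                          search_window_ms: Tuple[float, float],
                          polarity: str = "excitation") -> np.ndarray:
    """Centers (ms) of bins beyond the band within a search window.

    The bin-level view used for the short-latency (1-6 ms, 0.5 ms bins)
    analysis, where phasic events are narrower than any duration criterion.
    """
    train = np.asarray(train, dtype=float)
    starts = window_ms[0] + bin_size_ms * np.arange(len(train))
    s0, s1 = search_window_ms
    in_search = (starts >= s0) & (starts + bin_size_ms <= s1)
    beyond = train > band.upper if polarity == "excitation" else train < band.lower
    return starts[in_search & beyond] + bin_size_ms / 2.0
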