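"""Synthetic TMS-evoked session generator.

Emulates the point-process statistics of multiunit firing in motor-cortex
layer V around a single TMS pulse: a homogeneous baseline, a multiphasic
evoked profile (intermediate excitation peaking near 20 ms, a long
inhibition, a rebound excitation ending near 300 ms), orientation-dependent
short-latency bursts (present under posterior-anterior induced current,
absent under medial-lateral), unilateral motor-unit potentials in EMG at
~11 ms, and linear voltage ramps on a low-gain monitoring channel driven by
a known injected current.  It also renders continuous 40 kHz voltage traces
with an amplifier blanking window (-0.2 to +0.8 ms around each pulse)
during which samples are grounded to zero.

Spike trains are drawn from an inhomogeneous Poisson process by
Lewis-Shedler thinning, which is exact for the piecewise-constant rate
profiles used here.  Everything is reproducible bit-for-bit given a seed.

Absolute rates are package constants (documented below); the quantity the
downstream analysis works with is baseline-normalized firing rate, so only
the *shape* and the intensity scaling of the profiles matter for fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .sigio import ContinuousRecording, Session, SpikeTrain, StimulusLog

__all__ = [
    "TRIAL_WINDOW_MS",
    "RateProfile",
    "SynthSessionConfig",
    "default_spike_waveform",
    "default_muap_template",
    "generate_spike_train",
    "preset_profiles",
    "generate_session_events",
    "render_continuous",
    "simulate_session",
    "generate_lgm_trace",
    "generate_emg",
]

#: Peri-stimulus trial window in ms (baseline 500 ms, response 1000 ms).
TRIAL_WINDOW_MS: Tuple[float, float] = (-500.0, 1000.0)

#: Multiunit baseline firing rate (events/s) used by the presets.  The
#: source figures report baseline-normalized rates only, so the absolute
#: level is a package choice typical of ketamine-anesthetized layer V
#: multiunit activity.
PRESET_BASELINE_RATE = 15.0

#: Default amplifier blanking window, ms relative to stimulus onset.
DEFAULT_BLANKING_MS: Tuple[float, float] = (-0.2, 0.8)


@dataclass(frozen=True)
class RateProfile:
    """Piecewise-constant peri-stimulus intensity function.

    ``rate(t) = max(0, baseline_rate + sum of components active at t)``;
    components are ``(t_start_ms, t_end_ms, additive_rate)`` boxes, additive
    rate may be negative to model suppression (the floor at zero models
    complete silencing rather than rejecting the profile).
    """

    baseline_rate: float
    components: Tuple[Tuple[float, float, float], ...] = ()

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValueError(f"baseline rate must be >= 0, got {self.baseline_rate}")
        object.__setattr__(self, "components", tuple(tuple(map(float, c)) for c in self.components))
        for (a, b, _r) in self.components:
            if not a < b:
                raise ValueError(f"component ({a}, {b}) has non-positive extent")
            if a < TRIAL_WINDOW_MS[0] or b > TRIAL_WINDOW_MS[1]:
                raise ValueError(f"component ({a}, {b}) outside the trial window {TRIAL_WINDOW_MS}")

    def rate(self, t_ms) -> np.ndarray:
        """Effective rate lambda(t) in events/s at peri-stimulus times ``t_ms``."""
        t = np.asarray(t_ms, dtype=float)
        lam = np.full(t.shape, self.baseline_rate)
        for (a, b, r) in self.components:
            lam += np.where((t >= a) & (t < b), r, 0.0)
        return np.maximum(lam, 0.0)

    def max_rate(self) -> float:
        """Exact maximum of lambda(t) (evaluated between component breakpoints)."""
        breaks = sorted({TRIAL_WINDOW_MS[0], TRIAL_WINDOW_MS[1]}
                        | {c[0] for c in self.components} | {c[1] for c in self.components})
        mids = [(a + b) / 2.0 for a, b in zip(breaks[:-1], breaks[1:])]
        return float(np.max(self.rate(np.array(mids)))) if mids else self.baseline_rate


def default_spike_waveform(fs: float = 40000.0, amplitude_uv: float = 80.0,
                           duration_ms: float = 1.0) -> np.ndarray:
    """Biphasic extracellular spike template, negative leading phase.

    Over ``duration_ms`` (default 1 ms): trough of ``-amplitude_uv`` at a
    quarter of the duration, positive overshoot of half that at three
    quarters.
    """
    n = max(int(round(duration_ms * 1e-3 * fs)), 2)
    t = np.arange(n) / n  # 0..1 over the 1 ms template
    w = -np.sin(2 * np.pi * t)
    w[t >= 0.5] *= 0.5
    return amplitude_uv * w


def default_muap_template(fs: float = 40000.0, amplitude_uv: float = 300.0) -> np.ndarray:
    """Biphasic 4 ms motor-unit action potential (two 2 ms half-sine lobes)."""
    n = max(int(round(4e-3 * fs)), 4)
    t = np.arange(n) / n * 4.0  # ms
    w = np.where(t < 2.0, np.sin(np.pi * t / 2.0), -0.6 * np.sin(np.pi * (t - 2.0) / 2.0))
    return amplitude_uv * w


@dataclass
class SynthSessionConfig:
    """Everything needed to generate one synthetic stimulation session.

    ``intensities`` gives the %MT value of each block of ``n_trials``
    stimuli; a single-condition session passes one value.  The
    inter-stimulus interval must exceed the trial window length (1.5 s).
    """

    n_trials: int = 60
    intensities: Tuple[float, ...] = (120.0,)
    orientation: str = "ML"
    animal_id: str = "synthetic"
    noise_sd: float = 8.0  # µV, white noise on the rendered trace
    fs: float = 40000.0
    blanking_ms: Tuple[float, float] = DEFAULT_BLANKING_MS
    isi_s: float = 2.0
    first_onset_s: float = 0.6
    seed: int = 0
    spike_waveform: Optional[np.ndarray] = None

    def __post_init__(self):
        window_len = (TRIAL_WINDOW_MS[1] - TRIAL_WINDOW_MS[0]) / 1000.0
        if not self.isi_s > window_len:
            raise ValueError(
                f"inter-stimulus interval {self.isi_s}s must exceed the trial window {window_len}s"
            )
        if self.first_onset_s < -TRIAL_WINDOW_MS[0] / 1000.0:
            raise ValueError("first onset leaves no room for the baseline window")
        if self.spike_waveform is None:
            self.spike_waveform = default_spike_waveform(self.fs)

    def profile_for(self, intensity: float) -> RateProfile:
        return preset_profiles(self.orientation, intensity)


def generate_spike_train(profile: RateProfile, window_ms: Tuple[float, float] = TRIAL_WINDOW_MS,
                         seed=None) -> SpikeTrain:
    """Draw one trial's spikes from an inhomogeneous Poisson process.

    Uses Lewis-Shedler thinning against the exact rate maximum.  Returned
    timestamps are in seconds relative to stimulus onset, sorted ascending.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times_ms = _draw_times_ms(profile, window_ms, rng)
    return SpikeTrain(timestamps=times_ms / 1000.0, source_channel="synthetic")


def _draw_times_ms(profile: RateProfile, window_ms, rng: np.random.Generator) -> np.ndarray:
    lam_max = profile.max_rate()
    t0, t1 = float(window_ms[0]), float(window_ms[1])
    dur_s = (t1 - t0) / 1000.0
    if lam_max <= 0 or dur_s <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * dur_s)
    cand = np.sort(rng.uniform(t0, t1, size=n))
    keep = rng.uniform(0.0, lam_max, size=n) < profile.rate(cand)
    return cand[keep]


# --- preset evoked profiles --------------------------------------------------

def _intensity_scale(intensity_pct_mt: float) -> float:
    """Monotone amplitude scaling of evoked components with stimulus intensity.

    Zero at and below 80 %MT (sham / far-subthreshold), 1 at 120 %MT.
    Linear in between, so excitations grow and the suppression deepens with
    intensity, mirroring the reported positive/positive/negative intensity
    modulation of the three long-latency phases.
    """
    return max(0.0, (float(intensity_pct_mt) - 80.0) / 40.0)


def preset_profiles(orientation: str, intensity: float) -> RateProfile:
    """Calibrated peri-stimulus rate profile for a given orientation/intensity.

    Both orientations share the long-latency structure: an excitation
    plateau around 20 ms, a suppression epoch from 40-150 ms (complete
    silencing at 120 %MT), and a rebound excitation ending by ~280 ms.
    PA stimulation additionally carries two narrow short-latency bursts at
    1-1.5 ms and 2.5-4.5 ms; ML carries none, leaving the 1-6 ms window at
    baseline rate.  Amplitudes (events/s, at 120 %MT) are package constants.
    """
    if orientation not in ("ML", "PA"):
        raise ValueError(f"unknown orientation {orientation!r} (expected 'ML' or 'PA')")
    s = _intensity_scale(intensity)
    lam0 = PRESET_BASELINE_RATE
    comps = []
    if s > 0:
        comps += [
            (8.0, 32.0, 25.0 * s),    # intermediate excitation, outer step
            (16.0, 24.0, 45.0 * s),   # intermediate excitation, peak plateau at ~20 ms
            (40.0, 150.0, -15.0 * s),  # long inhibition (floors at zero rate)
            (170.0, 280.0, 25.0 * s),  # rebound excitation
        ]
        if orientation == "PA":
            comps += [
                (1.0, 1.5, 400.0 * s),   # early short-latency burst
                (2.5, 4.5, 250.0 * s),   # late short-latency burst
            ]
    return RateProfile(baseline_rate=lam0, components=tuple(comps))


# --- session assembly --------------------------------------------------------

def generate_session_events(cfg: SynthSessionConfig) -> Tuple[SpikeTrain, StimulusLog]:
    """Generate the spike train and stimulus log of a full session.

    Each intensity in ``cfg.intensities`` contributes ``cfg.n_trials``
    stimuli (blocked, in the given order).  Evoked structure is drawn
    per-trial from the preset profile inside the trial window; the gaps
    between windows carry homogeneous baseline firing so the record is a
    plausible continuous recording.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_trials * len(cfg.intensities)
    onsets = cfg.first_onset_s + cfg.isi_s * np.arange(n_total)
    intensity = np.repeat(np.asarray(cfg.intensities, dtype=float), cfg.n_trials)

    all_times = []
    w0_s, w1_s = TRIAL_WINDOW_MS[0] / 1000.0, TRIAL_WINDOW_MS[1] / 1000.0
    # baseline firing in the gaps between trial windows (and before/after)
    gap_edges = [(0.0, onsets[0] + w0_s)]
    for i in range(n_total - 1):
        gap_edges.append((onsets[i] + w1_s, onsets[i + 1] + w0_s))
    gap_edges.append((onsets[-1] + w1_s, onsets[-1] + w1_s + 0.1))
    lam0 = cfg.profile_for(intensity[0]).baseline_rate
    for (a, b) in gap_edges:
        if b > a and lam0 > 0:
            n = rng.poisson(lam0 * (b - a))
            all_times.append(rng.uniform(a, b, size=n))
    # evoked structure inside each trial window
    for onset, inten in zip(onsets, intensity):
        prof = cfg.profile_for(inten)
        all_times.append(onset + _draw_times_ms(prof, TRIAL_WINDOW_MS, rng) / 1000.0)

    spikes = SpikeTrain(timestamps=np.concatenate(all_times) if all_times else np.empty(0),
                        source_channel="synthetic")
    stimlog = StimulusLog(onsets=onsets, intensity_pct_mt=intensity,
                          orientation=cfg.orientation, animal_id=cfg.animal_id)
    return spikes, stimlog


def render_continuous(trains: Sequence[SpikeTrain], cfg: SynthSessionConfig,
                      stimlog: Optional[StimulusLog] = None,
                      duration_s: Optional[float] = None) -> ContinuousRecording:
    """Render spike trains into a continuous voltage trace.

    The trace is the linear sum of waveform templates placed at spike times
    (overlaps sum), plus i.i.d. Gaussian noise of ``cfg.noise_sd``.  Samples
    inside the blanking interval around each stimulus onset are overwritten
    with 0, emulating the grounded amplifier input, and the intervals are
    recorded as ``excluded_intervals``.
    """
    if not cfg.fs > 0:
        raise ValueError(f"sampling rate must be positive, got {cfg.fs}")
    all_t = np.concatenate([tr.timestamps for tr in trains]) if trains else np.empty(0)
    wave = np.asarray(cfg.spike_waveform, dtype=float)
    if duration_s is None:
        t_last = all_t.max() if all_t.size else 0.0
        if stimlog is not None and stimlog.n_trials:
            t_last = max(t_last, stimlog.onsets[-1] + TRIAL_WINDOW_MS[1] / 1000.0)
        duration_s = t_last + len(wave) / cfg.fs + 0.05
    n = int(np.ceil(duration_s * cfg.fs))
    rng = np.random.default_rng(cfg.seed + 1)  # independent stream from the spike draw
    trace = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    for t in all_t:
        i0 = int(round(t * cfg.fs))
        i1 = min(i0 + len(wave), n)
        if 0 <= i0 < n:
            trace[i0:i1] += wave[: i1 - i0]

    excluded = []
    if stimlog is not None:
        b0, b1 = cfg.blanking_ms
        for onset in stimlog.onsets:
            a, b = onset + b0 / 1000.0, onset + b1 / 1000.0
            i0, i1 = max(int(np.ceil(a * cfg.fs)), 0), min(int(np.ceil(b * cfg.fs)), n)
            trace[i0:i1] = 0.0
            excluded.append((a, b))
    return ContinuousRecording(samples=trace, fs=cfg.fs, channel_id="synthetic",
                               excluded_intervals=excluded)


def simulate_session(cfg: SynthSessionConfig, with_emg: bool = False,
                     ground_truth: bool = False):
    """Full session simulation: spikes, stimulus log, rendered trace, optional EMG.

    Returns a :class:`~tmsep.sigio.Session`; with ``ground_truth=True`` also
    returns the planted spike train (for detector recovery tests) as a
    second element.
    """
    spikes, stimlog = generate_session_events(cfg)
    rec = render_continuous([spikes], cfg, stimlog=stimlog)
    session = Session(recording=rec, stimlog=stimlog)
    if with_emg:
        contra, ipsi = generate_emg(
            latency_ms=11.0, fs=cfg.fs, stim_onsets_s=stimlog.onsets,
            duration_s=rec.duration, noise_sd=5.0, seed=cfg.seed + 2,
        )
        session.emg_contra, session.emg_ipsi = contra, ipsi
    if ground_truth:
        return session, spikes
    return session


# --- auxiliary channel generators -------------------------------------------

def generate_lgm_trace(current: np.ndarray, c_in: float, fs: float,
                       noise_sd: float = 0.0, seed=None) -> np.ndarray:
    """Low-gain monitor voltage for a known injected current.

    ``V(t) = (1/C_in) * integral of I dt`` (cumulative trapezoid), the exact
    inverse of :func:`tmsep.chargemon.current_from_lgm` at zero noise.
    Units: current in A, ``c_in`` in F, output in V.
    """
    if not c_in > 0:
        raise ValueError(f"input capacitance must be positive, got {c_in}")
    from scipy.integrate import cumulative_trapezoid

    current = np.asarray(current, dtype=float)
    v = cumulative_trapezoid(current, dx=1.0 / fs, initial=0.0) / c_in
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, size=v.shape)
    return v


def generate_emg(latency_ms: float, fs: float, stim_onsets_s: np.ndarray,
                 duration_s: float, muap_template: Optional[np.ndarray] = None,
                 noise_sd: float = 5.0, seed=None,
                 ) -> Tuple[ContinuousRecording, ContinuousRecording]:
    """Paired intramuscular EMG traces with a unilateral evoked response.

    The contralateral trace contains the MUAP template starting
    ``latency_ms`` after every stimulus onset plus noise; the ipsilateral
    trace is noise only.
    """
    if latency_ms < 0:
        raise ValueError(f"latency must be >= 0, got {latency_ms}")
    if muap_template is None:
        muap_template = default_muap_template(fs)
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration_s * fs))
    contra = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    ipsi = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    for onset in np.atleast_1d(stim_onsets_s):
        i0 = int(round((onset + latency_ms / 1000.0) * fs))
        i1 = min(i0 + len(muap_template), n)
        if 0 <= i0 < n:
            contra[i0:i1] += muap_template[: i1 - i0]
    rec_c = ContinuousRecording(contra, fs=fs, channel_id="emg_contra")
    rec_i = ContinuousRecording(ipsi, fs=fs, channel_id="emg_ipsi")
    return rec_c, rec_i
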