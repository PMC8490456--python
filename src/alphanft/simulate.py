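"""Synthetic multi-session alpha-neurofeedback cohorts with known ground truth.

The generator emulates the study design: per subject one 2-min eyes-closed
resting (ECRS) recording, then 12 daily sessions each consisting of a 2-min
baseline and six 6-min training trials, recorded from three bipolar channels
at 500 Hz.  Each subject carries a latent alpha trait (the true ECRS alpha
amplitude), a learning gain g constructed so that corr(ECRS alpha, g)
approaches a configurable rho, and a per-session mean-relative-alpha-amplitude
(MRAA) trajectory normalised to run from 1 at session 1 to 1+g at the last
session (linear or sigmoid shape).

Two generation paths exist:

* fast path — per-trial band-amplitude tables sampled directly from the
  generative means with lognormal day/trial noise (plus 1-30 Hz mean bin
  spectra for the first and last sessions);
* slow path — full multi-channel time series (alpha sinusoid at the subject's
  peak frequency under a slowly varying Ornstein-Uhlenbeck envelope,
  band-limited delta/theta/beta noise, a 1/f broadband floor, and optional
  transient motion-like artifact bursts), whose band amplitudes are
  recoverable by the spectral stage.

Randomness is hierarchical: every subject/session/trial derives its own
substream from the root seed, so enlarging the cohort never reshuffles
existing subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .spectral import (
    BAND_ORDER,
    DEFAULT_BANDS,
    BandDefinition,
    MultiChannelSignal,
    amplitude_spectrum,
    band_amplitude,
)

__all__ = [
    "SimulationConfig",
    "SubjectGroundTruth",
    "CohortDataset",
    "sample_subject_params",
    "mraa_trajectory",
    "synth_trial_signal",
    "inject_artifacts",
    "generate_cohort",
]

CHANNEL_LABELS = ("C3a-C3p", "Cza-Czp", "C4a-C4p")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Band levels are the between-subject lognormal distribution of per-bin band
    amplitudes (microvolts): ``band_level_means_uv`` / ``band_level_sds_uv``
    are the arithmetic mean and SD of the amplitude itself.
    ``ecrs_learning_correlation`` is the target Pearson rho between the true
    ECRS alpha amplitude and the learning gain.
    """

    n_subjects: int = 46
    n_sessions: int = 12
    trials_per_session: int = 6
    trial_duration_s: float = 360.0
    baseline_duration_s: float = 120.0
    ecrs_duration_s: float = 120.0
    sampling_rate_hz: float = 500.0
    n_channels: int = 3
    band_level_means_uv: dict[str, float] = field(
        default_factory=lambda: {"delta": 6.0, "theta": 5.0, "alpha": 10.0,
                                 "beta": 2.5})
    band_level_sds_uv: dict[str, float] = field(
        default_factory=lambda: {"delta": 1.8, "theta": 1.5, "alpha": 4.0,
                                 "beta": 0.8})
    ecrs_learning_correlation: float = 0.7
    gain_mean: float = 0.35
    gain_sd: float = 0.43
    trajectory_shape: str = "sigmoid"
    sigmoid_midpoint_session: float = 6.0
    sigmoid_width: float = 1.5
    artifact_rate_per_min: float = 0.5
    artifact_amplitude_factor: float = 8.0
    alpha_peak_mean_hz: float = 10.0
    alpha_peak_sd_hz: float = 0.8
    # measurement-noise scales of the fast path (lognormal CVs)
    baseline_day_cv: float = 0.10
    trial_noise_cv: float = 0.05
    ecrs_noise_cv: float = 0.05
    spectrum_bin_cv: float = 0.08
    broadband_floor_uv: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.trial_duration_s, self.baseline_duration_s,
               self.ecrs_duration_s) <= 0:
            raise ValueError("all durations must be positive")
        if self.n_sessions < 2:
            raise ValueError("n_sessions must be at least 2")
        if abs(self.ecrs_learning_correlation) > 1:
            raise ValueError("|ecrs_learning_correlation| must be <= 1")
        if self.trajectory_shape not in ("linear", "sigmoid"):
            raise ValueError("trajectory_shape must be 'linear' or 'sigmoid'")
        if self.trajectory_shape == "sigmoid" and self.sigmoid_width <= 0:
            raise ValueError("sigmoid_width must be positive")
        if self.artifact_rate_per_min < 0:
            raise ValueError("artifact_rate_per_min must be >= 0")
        # Nyquist: highest synthesised frequency is the beta band top (30 Hz)
        if self.sampling_rate_hz < 2 * 30:
            raise ValueError("sampling_rate_hz below Nyquist for 30 Hz content")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class SubjectGroundTruth:
    """Latent generative parameters of one synthetic subject."""

    subject_id: str
    true_ecrs_band_amplitudes_uv: dict[str, float]
    learning_gain: float
    trajectory_params: tuple  # (shape, midpoint, width)
    true_mraa: np.ndarray
    alpha_peak_hz: float
    artifact_truth: list = field(default_factory=list)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["true_mraa"] = [float(v) for v in self.true_mraa]
        d["trajectory_params"] = list(self.trajectory_params)
        return d


@dataclass
class CohortDataset:
    """A generated cohort: tables (fast path) and/or signals (slow path)."""

    config: SimulationConfig
    ground_truth: list[SubjectGroundTruth]
    ecrs_table: pd.DataFrame | None = None       # subject, band, amplitude_uv
    baseline_table: pd.DataFrame | None = None   # subject, session, band, amplitude_uv
    trial_table: pd.DataFrame | None = None      # subject, session, trial, band, amplitude_uv
    spectra_table: pd.DataFrame | None = None    # subject, session, bin_hz, amplitude_uv
    signals: dict | None = None                  # slow path, keyed by subject_id

    @property
    def subject_ids(self) -> list[str]:
        return [gt.subject_id for gt in self.ground_truth]

    def write(self, outdir) -> None:
        """Persist the fast-path tables as tidy CSV plus a JSON ground-truth sidecar."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("ecrs_table", "baseline_table", "trial_table",
                     "spectra_table"):
            tab = getattr(self, name)
            if tab is not None:
                # %.17g keeps float64 round-trips lossless
                tab.to_csv(out / f"{name}.csv", index=False,
                           float_format="%.17g")
        sidecar = {
            "config": self.config.to_dict(),
            "ground_truth": [gt.to_jsonable() for gt in self.ground_truth],
        }
        (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, outdir) -> "CohortDataset":
        from pathlib import Path
        out = Path(outdir)
        sidecar = json.loads((out / "ground_truth.json").read_text())
        cfg = SimulationConfig.from_dict(sidecar["config"])
        gts = []
        for d in sidecar["ground_truth"]:
            d["true_mraa"] = np.asarray(d["true_mraa"], dtype=float)
            d["trajectory_params"] = tuple(d["trajectory_params"])
            gts.append(SubjectGroundTruth(**d))
        kw = {}
        for name in ("ecrs_table", "baseline_table", "trial_table",
                     "spectra_table"):
            p = out / f"{name}.csv"
            if p.exists():
                kw[name] = pd.read_csv(p, float_precision="round_trip")
        return cls(config=cfg, ground_truth=gts, **kw)


# ---------------------------------------------------------------------------
# random substreams
# ---------------------------------------------------------------------------

def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    """Deterministic substream for a (subject, session, trial, ...) key."""
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *key])
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log for a lognormal with given arithmetic mean/SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if sd <= 0:
        return np.log(mean), 0.0
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


# ---------------------------------------------------------------------------
# subject-level ground truth
# ---------------------------------------------------------------------------

def sample_subject_params(
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str = "S00",
) -> SubjectGroundTruth:
    """Draw one subject's latent parameters.

    The learning gain is built from the z-score of the subject's true ECRS
    alpha amplitude within its generating lognormal distribution:

        g = gain_mean + gain_sd * (rho * z + sqrt(1 - rho^2) * eps)

    with eps standard normal, so the population corr(ECRS alpha, g) is rho.
    """
    config.validate()
    bands = {}
    for name in BAND_ORDER:
        mu, sig = _lognormal_params(config.band_level_means_uv[name],
                                    config.band_level_sds_uv[name])
        bands[name] = float(rng.lognormal(mu, sig))
    mean_a = config.band_level_means_uv["alpha"]
    sd_a = config.band_level_sds_uv["alpha"]
    z = (bands["alpha"] - mean_a) / sd_a if sd_a > 0 else 0.0
    rho = config.ecrs_learning_correlation
    eps = rng.standard_normal()
    g = config.gain_mean + config.gain_sd * (
        rho * z + np.sqrt(max(0.0, 1.0 - rho ** 2)) * eps
    )
    peak = float(np.clip(
        rng.normal(config.alpha_peak_mean_hz, config.alpha_peak_sd_hz),
        8.0, 12.0,
    ))
    gt = SubjectGroundTruth(
        subject_id=subject_id,
        true_ecrs_band_amplitudes_uv=bands,
        learning_gain=float(g),
        trajectory_params=(config.trajectory_shape,
                           config.sigmoid_midpoint_session,
                           config.sigmoid_width),
        true_mraa=np.array([]),
        alpha_peak_hz=peak,
    )
    gt.true_mraa = mraa_trajectory(gt, config)
    return gt


def mraa_trajectory(gt: SubjectGroundTruth, config: SimulationConfig) -> np.ndarray:
    """True per-session MRAA, normalised so m(1) = 1 and m(last) = 1 + g.

    linear:  m(s) = 1 + g * (s-1) / (k-1)
    sigmoid: m(s) = 1 + g * (sig(s) - sig(1)) / (sig(k) - sig(1)),
             sig(s) = 1 / (1 + exp(-(s - midpoint) / width))
    """
    shape, midpoint, width = gt.trajectory_params
    k = config.n_sessions
    s = np.arange(1, k + 1, dtype=float)
    g = gt.learning_gain
    if shape == "linear":
        return 1.0 + g * (s - 1.0) / (k - 1.0)
    if shape == "sigmoid":
        if width <= 0:
            raise ValueError("sigmoid_width must be positive")
        sig = 1.0 / (1.0 + np.exp(-(s - midpoint) / width))
        return 1.0 + g * (sig - sig[0]) / (sig[-1] - sig[0])
    raise ValueError(f"unknown trajectory shape {shape!r}")


# ---------------------------------------------------------------------------
# slow path: time-series synthesis
# ---------------------------------------------------------------------------

def _ou_envelope(n: int, fs: float, rng: np.random.Generator,
                 cv: float = 0.25, tau_s: float = 2.0) -> np.ndarray:
    """Slowly varying positive envelope with mean 1 (OU-smoothed, clipped)."""
    dt = 1.0 / fs
    coef = np.exp(-dt / tau_s)
    # stationary AR(1) discretisation of an OU process around 1, SD = cv
    sd_step = cv * np.sqrt(1.0 - coef ** 2)
    noise = rng.standard_normal(n)
    dev = sps.lfilter([sd_step], [1.0, -coef], noise)
    x = np.clip(1.0 + dev, 0.05, None)
    return x / x.mean()


def _sinusoid_band_gain(freq_hz: float, fs: float, band: BandDefinition,
                        epoch_s: float = 1.0) -> float:
    """Band amplitude the spectral stage reports per unit sinusoid peak.

    Used to calibrate the alpha component so a requested band amplitude is
    recoverable downstream (Hamming leakage spreads a sinusoid over ~3 bins,
    so the 5-bin alpha mean of a unit sinusoid is well below 1).
    """
    n = int(round(epoch_s * fs))
    t = np.arange(n) / fs
    bins, amp = amplitude_spectrum(np.sin(2 * np.pi * freq_hz * t), fs)
    return band_amplitude(bins, amp, band)


def _band_noise(n: int, fs: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [lo, hi] Hz."""
    b, a = sps.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    x = sps.filtfilt(b, a, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude broadband noise, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _measured_band(sig: np.ndarray, fs: float, band: BandDefinition) -> float:
    """Mean band amplitude of a 1-channel signal over its 1-s epochs."""
    n_per = int(round(fs))
    n_ep = len(sig) // n_per
    vals = []
    for i in range(n_ep):
        bins, amp = amplitude_spectrum(sig[i * n_per:(i + 1) * n_per], fs)
        vals.append(band_amplitude(bins, amp, band))
    return float(np.mean(vals))


def synth_recording(
    gt: SubjectGroundTruth,
    config: SimulationConfig,
    band_targets_uv: dict[str, float],
    duration_s: float,
    rng: np.random.Generator,
    segment_kind: str = "trial",
) -> MultiChannelSignal:
    """Synthesise one multi-channel recording hitting the given band targets.

    The alpha component is a shared sinusoid at the subject's peak frequency
    under an OU envelope (identical across channels); delta/theta/beta are
    independent band-limited noise per channel; a small 1/f floor is added.
    Each component is rescaled so that the spectral stage recovers the target
    band amplitude on this realisation (up to envelope variability).
    """
    fs = config.sampling_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    band_by_name = {b.name: b for b in DEFAULT_BANDS}

    alpha_target = band_targets_uv.get("alpha", 0.0)
    chans = np.zeros((n, config.n_channels))
    if alpha_target > 0:
        gain = _sinusoid_band_gain(gt.alpha_peak_hz, fs,
                                   band_by_name["alpha"])
        env = _ou_envelope(n, fs, rng)
        phase = rng.uniform(0, 2 * np.pi)
        alpha_src = (alpha_target / gain) * env * np.sin(
            2 * np.pi * gt.alpha_peak_hz * t + phase)
        chans += alpha_src[:, None]

    for name, (lo, hi) in (("delta", (1.0, 3.0)), ("theta", (4.0, 8.0)),
                           ("beta", (13.0, 30.0))):
        target = band_targets_uv.get(name, 0.0)
        if target <= 0:
            continue
        for c in range(config.n_channels):
            x = _band_noise(n, fs, lo, hi, rng)
            meas = _measured_band(x, fs, band_by_name[name])
            if meas > 0:
                chans[:, c] += x * (target / meas)

    if config.broadband_floor_uv > 0 and any(
            v > 0 for v in band_targets_uv.values()):
        for c in range(config.n_channels):
            x = _pink_noise(n, rng)
            # scale so the 10-Hz bin amplitude ~ broadband_floor_uv
            bins, amp = amplitude_spectrum(x[: int(fs)], fs)
            ref = amp[np.argmin(np.abs(bins - 10.0))]
            if ref > 0:
                chans[:, c] += x * (config.broadband_floor_uv / ref)

    labels = CHANNEL_LABELS[: config.n_channels] if config.n_channels <= 3 \
        else tuple(f"ch{i}" for i in range(config.n_channels))
    return MultiChannelSignal(chans, fs, labels, segment_kind)


def synth_trial_signal(
    gt: SubjectGroundTruth,
    session: int,
    trial: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    baseline_alpha_uv: float | None = None,
) -> MultiChannelSignal:
    """One training-trial recording; alpha level = baseline level x true MRAA."""
    if not (1 <= session <= config.n_sessions):
        raise ValueError("session out of range")
    base_alpha = (baseline_alpha_uv if baseline_alpha_uv is not None
                  else gt.true_ecrs_band_amplitudes_uv["alpha"])
    targets = dict(gt.true_ecrs_band_amplitudes_uv)
    targets["alpha"] = base_alpha * float(gt.true_mraa[session - 1])
    return synth_recording(gt, config, targets, config.trial_duration_s, rng,
                           segment_kind="trial")


def inject_artifacts(
    signal: MultiChannelSignal,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[MultiChannelSignal, np.ndarray]:
    """Add transient motion-like bursts; return (signal, per-epoch truth mask).

    Burst onsets follow a Poisson process at ``artifact_rate_per_min``;
    durations are uniform on [0.2, 1.0] s.  Each burst is low-frequency
    (<= 30 Hz) noise plus a monophasic offset under a Tukey (tapered-cosine)
    envelope, peak absolute amplitude ``artifact_amplitude_factor`` times the
    background SD, applied identically to every channel (motion is largely
    common-mode across a bipolar montage).

    The truth mask marks 1-s epochs that contain at least 0.15 s (or the
    whole plateau, if shorter) of the burst's full-amplitude plateau — the
    central half of its duration.  Epochs touched only by the low-amplitude
    envelope tapers carry negligible artifact energy, are indistinguishable
    from clean epochs by any amplitude statistic, and do not corrupt the
    epoch's band amplitudes, so they are not ground-truth contaminated.
    """
    fs = signal.sampling_rate_hz
    dur = signal.duration_s
    n_epochs = int(dur)  # 1-s epochs
    mask = np.zeros(n_epochs, dtype=bool)
    n_bursts = rng.poisson(config.artifact_rate_per_min * dur / 60.0)
    if n_bursts == 0 or config.artifact_rate_per_min == 0:
        return signal, mask
    out = signal.samples.copy()
    sd = float(signal.samples.std())
    b_lp, a_lp = sps.butter(4, min(30.0 / (fs / 2), 0.99), btype="low")
    events = []
    for _ in range(n_bursts):
        onset = rng.uniform(0.0, max(dur - 1.0, 0.0))
        blen = rng.uniform(0.2, 1.0)
        i0 = int(onset * fs)
        i1 = min(int((onset + blen) * fs), signal.n_samples)
        m = i1 - i0
        if m < 8:
            continue
        env = sps.windows.tukey(m, 0.5)
        noise = sps.filtfilt(b_lp, a_lp, rng.standard_normal(m + 200))[100:100 + m]
        noise /= max(np.abs(noise).max(), 1e-12)
        shape = env * (0.6 * noise + 0.7 * rng.choice([-1.0, 1.0]))
        shape *= config.artifact_amplitude_factor * sd / np.abs(shape).max()
        out[i0:i1] += shape[:, None]
        events.append((float(onset), float(blen)))
        p0, p1 = onset + 0.25 * blen, onset + 0.75 * blen  # envelope plateau
        need = min(0.15, p1 - p0) - 1e-9
        for e in range(int(np.floor(p0)), min(int(np.ceil(p1)), n_epochs)):
            if min(e + 1, p1) - max(e, p0) >= need:
                mask[e] = True
    new = MultiChannelSignal(out, fs, signal.channel_labels,
                             signal.segment_kind)
    new._artifact_events = events  # bookkeeping for ground truth
    return new, mask


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _fast_path_tables(config: SimulationConfig,
                      gts: list[SubjectGroundTruth]) -> dict[str, pd.DataFrame]:
    ecrs_rows, base_rows, trial_rows, spec_rows = [], [], [], []
    bin_band = {}
    for f in range(1, 31):
        if f <= 3:
            bin_band[f] = "delta"
        elif f <= 7:
            bin_band[f] = "theta"
        elif f <= 12:
            bin_band[f] = "alpha"
        else:
            bin_band[f] = "beta"

    for si, gt in enumerate(gts):
        rng = _rng(config, si, 1)  # measurement-noise stream of subject si
        for band in BAND_ORDER:
            true = gt.true_ecrs_band_amplitudes_uv[band]
            noise = rng.lognormal(*_lognormal_params(1.0, config.ecrs_noise_cv)) \
                if config.ecrs_noise_cv > 0 else 1.0
            ecrs_rows.append((gt.subject_id, band, true * noise))
        for s in range(1, config.n_sessions + 1):
            day = {
                band: rng.lognormal(*_lognormal_params(1.0, config.baseline_day_cv))
                if config.baseline_day_cv > 0 else 1.0
                for band in BAND_ORDER
            }
            base_alpha = gt.true_ecrs_band_amplitudes_uv["alpha"] * day["alpha"]
            for band in BAND_ORDER:
                base_rows.append((gt.subject_id, s, band,
                                  gt.true_ecrs_band_amplitudes_uv[band] * day[band]))
            for tr in range(1, config.trials_per_session + 1):
                for band in BAND_ORDER:
                    level = gt.true_ecrs_band_amplitudes_uv[band] * day[band]
                    if band == "alpha":
                        level = base_alpha * float(gt.true_mraa[s - 1])
                    tn = rng.lognormal(*_lognormal_params(1.0, config.trial_noise_cv)) \
                        if config.trial_noise_cv > 0 else 1.0
                    trial_rows.append((gt.subject_id, s, tr, band, level * tn))
            if s in (1, config.n_sessions):
                for f in range(1, 31):
                    level = gt.true_ecrs_band_amplitudes_uv[bin_band[f]]
                    if 8 <= f <= 12:
                        level = (gt.true_ecrs_band_amplitudes_uv["alpha"]
                                 * float(gt.true_mraa[s - 1]))
                    bn = rng.lognormal(*_lognormal_params(1.0, config.spectrum_bin_cv)) \
                        if config.spectrum_bin_cv > 0 else 1.0
                    spec_rows.append((gt.subject_id, s, f, level * bn))
    return {
        "ecrs_table": pd.DataFrame(
            ecrs_rows, columns=["subject", "band", "amplitude_uv"]),
        "baseline_table": pd.DataFrame(
            base_rows, columns=["subject", "session", "band", "amplitude_uv"]),
        "trial_table": pd.DataFrame(
            trial_rows,
            columns=["subject", "session", "trial", "band", "amplitude_uv"]),
        "spectra_table": pd.DataFrame(
            spec_rows, columns=["subject", "session", "bin_hz", "amplitude_uv"]),
    }


def _slow_path_signals(config: SimulationConfig,
                       gts: list[SubjectGroundTruth]) -> dict:
    signals: dict[str, dict] = {}
    for si, gt in enumerate(gts):
        day_rng = _rng(config, si, 1)
        ecrs = synth_recording(
            gt, config, gt.true_ecrs_band_amplitudes_uv,
            config.ecrs_duration_s, _rng(config, si, 2),
            segment_kind="ecrs")
        sessions = []
        for s in range(1, config.n_sessions + 1):
            day = day_rng.lognormal(
                *_lognormal_params(1.0, config.baseline_day_cv)) \
                if config.baseline_day_cv > 0 else 1.0
            base_targets = dict(gt.true_ecrs_band_amplitudes_uv)
            base_targets["alpha"] *= day
            baseline = synth_recording(
                gt, config, base_targets, config.baseline_duration_s,
                _rng(config, si, 3, s), segment_kind="baseline")
            trials = []
            for tr in range(1, config.trials_per_session + 1):
                sig = synth_trial_signal(
                    gt, s, tr, config, _rng(config, si, 4, s, tr),
                    baseline_alpha_uv=base_targets["alpha"])
                if config.artifact_rate_per_min > 0:
                    sig, truth = inject_artifacts(
                        sig, config, _rng(config, si, 5, s, tr))
                    gt.artifact_truth.append(
                        {"session": s, "trial": tr,
                         "events": getattr(sig, "_artifact_events", [])})
                trials.append(sig)
            sessions.append({"baseline": baseline, "trials": trials})
        signals[gt.subject_id] = {"ecrs": ecrs, "sessions": sessions}
    return signals


def generate_cohort(config: SimulationConfig, path: str = "fast") -> CohortDataset:
    """Generate a full synthetic cohort.

    ``path="fast"`` samples band-amplitude tables directly from the generative
    means (seconds for the default 46-subject design); ``path="slow"``
    synthesises the full time series (use small configs).  Both paths are
    deterministic in (config, seed) and attach the ground truth.
    """
    config.validate()
    gts = [
        sample_subject_params(config, _rng(config, si, 0), f"S{si:03d}")
        for si in range(config.n_subjects)
    ]
    ds = CohortDataset(config=replace(config), ground_truth=gts)
    if path == "fast":
        tables = _fast_path_tables(config, gts)
        ds.ecrs_table = tables["ecrs_table"]
        ds.baseline_table = tables["baseline_table"]
        ds.trial_table = tables["trial_table"]
        ds.spectra_table = tables["spectra_table"]
    elif path == "slow":
        ds.signals = _slow_path_signals(config, gts)
    else:
        raise ValueError("path must be 'fast' or 'slow'")
    return ds
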