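"""Per-call acoustic measurements: f0 contour, duration, HNR, formants, ΔF.

Fourteen parameters are measured per call, mirroring a standard bioacoustic
source-filter workup: call duration; mean/SD/min/max/range/start/end of the
fundamental frequency; mean harmonics-to-noise ratio; the first four mean
formants; and the formant dispersion ΔF.

The f0 tracker is a frame-local normalized cross-correlation method
(time step 0.01 s, pitch window 75-1200 Hz, parabolic peak interpolation,
voicing decided by the peak correlation) without a global path finder — the
calls this targets are weakly frequency-modulated, so frame-local candidates
suffice.  HNR uses the same correlation machinery: per frame
10·log10(r/(1-r)) from the normalized autocorrelation peak r, averaging over
frames above a silence threshold.  Formants come from per-frame Burg LPC
(order 2 × max formant count) after resampling to twice the formant ceiling
and pre-emphasis; candidates are LPC-root angles filtered by frequency range
and bandwidth, assigned lowest-four-by-frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly
from statsmodels.regression.linear_model import burg as _burg

from .synth import CallRecording, read_wav

#: the 14 measured parameters, in report order
PARAMETERS = [
    "duration", "mean_f0", "sd_f0", "max_f0", "min_f0", "range_f0",
    "start_f0", "end_f0", "hnr", "F1", "F2", "F3", "F4", "delta_f",
]

FEATURE_CSV_COLUMNS = ["call_id", "individual_id"] + PARAMETERS


class ExtractionError(RuntimeError):
    """A call could not be measured (no pitch, no formants, all silent...)."""


@dataclass
class PitchConfig:
    time_step: float = 0.01
    pitch_floor: float = 75.0
    pitch_ceiling: float = 1200.0
    voicing_threshold: float = 0.45

    def __post_init__(self):
        if not 0 < self.pitch_floor < self.pitch_ceiling:
            raise ValueError("need 0 < pitch_floor < pitch_ceiling")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")


@dataclass
class FormantConfig:
    time_step: float = 0.01
    max_n_formants: int = 5
    max_formant: float = 8000.0
    window_length: float = 0.05
    pre_emphasis_from: float = 50.0
    bandwidth_cutoff: float = 400.0

    def __post_init__(self):
        if self.max_n_formants < 4:
            raise ValueError("max_n_formants must be >= 4 (F1-F4 are reported)")


@dataclass
class HnrConfig:
    time_step: float = 0.01
    minimum_pitch: float = 75.0
    silence_threshold: float = 0.1
    periods_per_window: float = 1.0

    def __post_init__(self):
        if self.minimum_pitch <= 0:
            raise ValueError("minimum_pitch must be positive")


@dataclass
class PitchContour:
    """Frame times, per-frame f0 (NaN when unvoiced) and the voicing mask."""

    frame_times: np.ndarray
    f0: np.ndarray
    voiced_mask: np.ndarray
    time_step: float

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced_mask]

    @property
    def voiced_times(self) -> np.ndarray:
        return self.frame_times[self.voiced_mask]


@dataclass
class AcousticFeatures:
    """The 14-parameter record for one call."""

    duration: float
    mean_f0: float
    sd_f0: float
    max_f0: float
    min_f0: float
    range_f0: float
    start_f0: float
    end_f0: float
    hnr: float
    F1: float
    F2: float
    F3: float
    F4: float
    delta_f: float

    def as_dict(self) -> dict:
        return asdict(self)


def _frame_peak_correlation(seg: np.ndarray, w: int, lag_min: int, lag_max: int):
    """Best normalized cross-correlation peak of one analysis segment.

    ``seg`` holds w + lag_max samples; the leading window of length w is
    correlated against itself shifted by each admissible lag.  Returns the
    interpolated peak correlation and lag (parabolic refinement), or
    (0, nan) when no interior peak exists.
    """
    seg = seg - seg.mean()
    a = seg[:w]
    ea = float(np.dot(a, a))
    if ea <= 0:
        return 0.0, np.nan
    # cross term for every lag in [lag_min, lag_max] at once
    cross = np.correlate(seg[lag_min : lag_max + w], a, mode="valid")
    energy = np.cumsum(seg * seg)
    # energy of seg[lag : lag+w] for lag in [lag_min, lag_max]
    lags = np.arange(lag_min, lag_max + 1)
    e_hi = energy[lags + w - 1]
    e_lo = np.where(lags > 0, energy[lags - 1], 0.0)
    eb = e_hi - e_lo
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cross / np.sqrt(ea * np.maximum(eb, 1e-300))
    r = np.nan_to_num(r, nan=0.0)
    if r.size < 3:
        return 0.0, np.nan
    # interior local maxima; prefer the shortest lag among near-best peaks to
    # suppress sub-octave (period-doubling) errors on periodic frames
    interior = np.flatnonzero((r[1:-1] >= r[:-2]) & (r[1:-1] >= r[2:])) + 1
    if interior.size == 0:
        return float(r.max()), np.nan
    r_best = float(r[interior].max())
    cand = interior[r[interior] >= r_best - 0.04]
    i = int(cand[0])
    rm, r0, rp = r[i - 1], r[i], r[i + 1]
    denom = rm - 2 * r0 + rp
    delta = 0.5 * (rm - rp) / denom if abs(denom) > 1e-12 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    lag = lags[i] + delta
    r_peak = float(r0 - 0.25 * (rm - rp) * delta)
    return min(r_peak, 1.0), lag


def _frames(n_samples: int, rate: float, step: float, seg_len: int) -> np.ndarray:
    """Start indices of analysis segments placed every `step` seconds."""
    hop = max(1, int(round(step * rate)))
    last = n_samples - seg_len
    if last < 0:
        return np.array([], dtype=int)
    return np.arange(0, last + 1, hop)


def extract_pitch(recording: CallRecording, cfg: PitchConfig | None = None) -> PitchContour:
    """Track f0 by frame-wise normalized cross-correlation.

    Frames whose peak correlation falls below the voicing threshold, or whose
    interpolated lag leaves the configured pitch window, are marked unvoiced.
    """
    cfg = cfg or PitchConfig()
    x, rate = recording.samples, recording.rate
    w = int(round(rate / cfg.pitch_floor))
    lag_max = w
    lag_min = max(2, int(np.floor(rate / cfg.pitch_ceiling)))
    seg_len = w + lag_max
    if x.size <= seg_len:
        raise ExtractionError(
            f"{recording.call_id}: recording too short for pitch analysis "
            f"(need > {seg_len / rate:.3f} s at floor {cfg.pitch_floor} Hz)"
        )
    starts = _frames(x.size, rate, cfg.time_step, seg_len)
    f0 = np.full(starts.size, np.nan)
    voiced = np.zeros(starts.size, dtype=bool)
    for k, s in enumerate(starts):
        r, lag = _frame_peak_correlation(x[s : s + seg_len], w, lag_min, lag_max)
        if r >= cfg.voicing_threshold and np.isfinite(lag) and lag > 0:
            freq = rate / lag
            if cfg.pitch_floor <= freq <= cfg.pitch_ceiling:
                f0[k] = freq
                voiced[k] = True
    if not voiced.any():
        raise ExtractionError(f"{recording.call_id}: no voiced frames found")
    times = (starts + seg_len / 2.0) / rate
    return PitchContour(frame_times=times, f0=f0, voiced_mask=voiced,
                        time_step=cfg.time_step)


def summarize_f0(contour: PitchContour) -> dict:
    """Mean/SD/min/max/range/start/end f0 over the voiced frames only."""
    v = contour.voiced_f0
    if v.size < 2:
        raise ExtractionError("need >= 2 voiced frames for f0 statistics")
    stats = {
        "mean_f0": float(np.mean(v)),
        "sd_f0": float(np.std(v, ddof=1)),
        "max_f0": float(np.max(v)),
        "min_f0": float(np.min(v)),
        "start_f0": float(v[0]),
        "end_f0": float(v[-1]),
    }
    stats["range_f0"] = stats["max_f0"] - stats["min_f0"]
    return stats


def measure_duration(contour: PitchContour) -> float:
    """Voiced-span duration: last minus first voiced frame time plus one step."""
    t = contour.voiced_times
    if t.size == 0:
        raise ExtractionError("no voiced frames; cannot measure duration")
    return float(t[-1] - t[0] + contour.time_step)


def _lpc_formant_candidates(frame: np.ndarray, order: int, rate: float,
                            cfg: FormantConfig) -> np.ndarray:
    """Formant candidates from the Burg LPC polynomial roots of one frame."""
    rho, _ = _burg(frame, order=order)
    roots = np.roots(np.concatenate(([1.0], -rho)))
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * rate / (2.0 * np.pi)
    bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * rate / np.pi
    keep = (freqs > 50.0) & (freqs < cfg.max_formant - 50.0) & (bws < cfg.bandwidth_cutoff)
    return np.sort(freqs[keep])


def extract_formants(
    recording: CallRecording, cfg: FormantConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean F1-F4 plus the per-frame track.

    The signal is resampled to 2 × max_formant, pre-emphasized above
    ``pre_emphasis_from``, and analyzed frame-by-frame (Gaussian-tapered
    windows) with Burg LPC of order 2 × max_n_formants.  Frames below a tenth
    of the peak frame RMS are treated as silence and skipped.
    """
    cfg = cfg or FormantConfig()
    target_rate = 2.0 * cfg.max_formant
    x, rate = recording.samples, recording.rate
    if target_rate > rate:
        raise ValueError("max_formant above the recording's Nyquist frequency")
    # rational resampling to the analysis rate
    from fractions import Fraction

    frac = Fraction(int(target_rate), int(rate)).limit_denominator(1000)
    y = resample_poly(x, frac.numerator, frac.denominator)
    fs = rate * frac.numerator / frac.denominator
    alpha = np.exp(-2.0 * np.pi * cfg.pre_emphasis_from / fs)
    y = np.append(y[0], y[1:] - alpha * y[:-1])

    wlen = int(round(cfg.window_length * fs))
    order = 2 * cfg.max_n_formants
    if y.size <= wlen or wlen <= order + 2:
        raise ExtractionError(f"{recording.call_id}: too short for formant analysis")
    starts = _frames(y.size, fs, cfg.time_step, wlen)
    window = np.exp(-0.5 * ((np.arange(wlen) - (wlen - 1) / 2) / (0.4 * wlen / 2)) ** 2)

    frames = np.stack([y[s : s + wlen] for s in starts])
    rms = np.sqrt(np.mean(frames**2, axis=1))
    active = rms >= 0.1 * rms.max()

    track = np.full((starts.size, 4), np.nan)
    n_ok = 0
    for k in np.flatnonzero(active):
        cand = _lpc_formant_candidates(frames[k] * window, order, fs, cfg)
        m = min(4, cand.size)
        track[k, :m] = cand[:m]
        if cand.size >= 4:
            n_ok += 1
    n_active = int(active.sum())
    if n_active == 0 or n_ok <= n_active / 2:
        raise ExtractionError(
            f"{recording.call_id}: fewer than four formants recoverable in more "
            f"than half of the {n_active} active frames"
        )
    means = np.nanmean(track, axis=0)
    if np.any(~np.isfinite(means)):
        raise ExtractionError(f"{recording.call_id}: a formant was never observed")
    return means, track


def estimate_delta_f(formants: np.ndarray) -> float:
    """Formant dispersion from the uniform-tube (closed-open) regression.

    ΔF is the zero-intercept least-squares slope of F_k on (2k-1)/2: under
    the tube model F_k = (2k-1)·ΔF/2, so ΔF = Σ F_k x_k / Σ x_k².
    """
    F = np.asarray(formants, dtype=float)
    if F.size != 4 or np.any(np.diff(F) <= 0):
        raise ValueError(f"need four strictly increasing formants, got {F}")
    x = np.array([0.5, 1.5, 2.5, 3.5])
    return float(np.dot(F, x) / np.dot(x, x))


def compute_hnr(recording: CallRecording, cfg: HnrConfig | None = None) -> float:
    """Mean harmonics-to-noise ratio in dB.

    Per frame, r is the normalized cross-correlation peak over the lag window
    of the minimum pitch and the frame HNR is 10·log10(r/(1-r)); frames whose
    peak amplitude is below silence_threshold × the global peak are skipped.
    r is clipped to [1e-6, 1-1e-6], bounding frame HNR to ±60 dB.
    """
    cfg = cfg or HnrConfig()
    x, rate = recording.samples, recording.rate
    w = int(round(cfg.periods_per_window * rate / cfg.minimum_pitch))
    lag_max = int(round(rate / cfg.minimum_pitch))
    lag_min = 2
    seg_len = w + lag_max
    if x.size <= seg_len:
        raise ExtractionError(f"{recording.call_id}: too short for HNR analysis")
    starts = _frames(x.size, rate, cfg.time_step, seg_len)
    global_peak = float(np.max(np.abs(x)))
    vals = []
    for s in starts:
        seg = x[s : s + seg_len]
        if np.max(np.abs(seg)) < cfg.silence_threshold * global_peak:
            continue
        r, _ = _frame_peak_correlation(seg, w, lag_min, lag_max)
        r = float(np.clip(r, 1e-6, 1.0 - 1e-6))
        vals.append(10.0 * np.log10(r / (1.0 - r)))
    if not vals:
        raise ExtractionError(f"{recording.call_id}: all frames silent")
    return float(np.mean(vals))


def extract_features(
    recording: CallRecording,
    pitch_cfg: PitchConfig | None = None,
    formant_cfg: FormantConfig | None = None,
    hnr_cfg: HnrConfig | None = None,
) -> AcousticFeatures:
    """Measure all 14 parameters of one call."""
    try:
        contour = extract_pitch(recording, pitch_cfg)
        f0_stats = summarize_f0(contour)
        duration = measure_duration(contour)
        hnr = compute_hnr(recording, hnr_cfg)
        formants, _ = extract_formants(recording, formant_cfg)
        delta_f = estimate_delta_f(formants)
    except (ExtractionError, ValueError) as e:
        raise ExtractionError(f"{recording.call_id}: {e}") from e
    return AcousticFeatures(
        duration=duration,
        hnr=hnr,
        F1=float(formants[0]),
        F2=float(formants[1]),
        F3=float(formants[2]),
        F4=float(formants[3]),
        delta_f=delta_f,
        **f0_stats,
    )


def features_from_recordings(
    recordings,
    pitch_cfg: PitchConfig | None = None,
    formant_cfg: FormantConfig | None = None,
    hnr_cfg: HnrConfig | None = None,
    on_error: str = "raise",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Build the calls × parameters feature table from an iterable of calls.

    ``on_error='exclude'`` drops failing calls and returns them with their
    failure reasons (the screening/exclusion report); 'raise' propagates.
    """
    rows, excluded = [], []
    for rec in recordings:
        try:
            feats = extract_features(rec, pitch_cfg, formant_cfg, hnr_cfg)
        except ExtractionError as e:
            if on_error == "exclude":
                excluded.append((rec.call_id, str(e)))
                continue
            raise
        rows.append({"call_id": rec.call_id, "individual_id": rec.individual_id,
                     **feats.as_dict()})
    return pd.DataFrame(rows, columns=FEATURE_CSV_COLUMNS), excluded


def features_from_manifest(
    manifest_path: str | Path,
    pitch_cfg: PitchConfig | None = None,
    formant_cfg: FormantConfig | None = None,
    hnr_cfg: HnrConfig | None = None,
    on_error: str = "raise",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Extract features for every WAV listed in a manifest CSV."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent

    def recordings():
        for _, row in manifest.iterrows():
            samples, rate = read_wav(base / row["file"])
            yield CallRecording(
                samples=samples, rate=rate,
                individual_id=str(row["individual_id"]),
                call_id=str(row["call_id"]),
            )

    return features_from_recordings(
        recordings(), pitch_cfg, formant_cfg, hnr_cfg, on_error=on_error
    )
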