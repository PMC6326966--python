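"""Source-filter synthesis of labelled coo-like calls.

Generates harmonic-rich, weakly frequency-modulated calls for a population of
virtual callers, with explicit control over within- versus between-individual
variation.  The production model is the classic source-filter decomposition:
a glottal source with a -12 dB/octave spectral tilt sets the fundamental
frequency contour, and a cascade of second-order resonators imposes formants
at the closed-open uniform-tube positions F_k = (2k-1)·ΔF/2 plus
per-individual offsets, with ΔF = c/(2L) for vocal-tract length L and
c = 350 m/s.  Aspiration noise is shaped by the same resonator cascade so the
harmonics-to-noise ratio is controlled by a single gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import lfilter

SPEED_OF_SOUND = 350.0  # m/s, warm humid vocal tract
PITCH_FLOOR = 75.0      # Hz, analysis window bounds every contour must respect
PITCH_CEILING = 1200.0
PEAK_AMPLITUDE = 0.9    # all calls are peak-normalized to this level

CONTOUR_SHAPES = ("flat", "fall", "rise", "arc")

#: manifest column order written by generate_dataset
MANIFEST_COLUMNS = [
    "file", "individual_id", "call_id", "seed",
    "true_mean_f0", "true_F1", "true_F2", "true_F3", "true_F4",
    "true_deltaF", "true_duration", "noise_gain",
]


class PopulationError(ValueError):
    """Invalid population specification."""


@dataclass
class IndividualProfile:
    """Distribution parameters for one virtual caller.

    ``mean_f0``/``f0_within_sd`` give the caller's average fundamental and its
    call-to-call SD; ``vocal_tract_length`` (cm) sets the formant dispersion
    through ΔF = c/(2L); ``formant_shape_offsets`` perturb the uniform-tube
    formant positions; ``noise_gain`` is the linear RMS ratio of aspiration
    noise to the harmonic source and hence controls HNR.
    """

    individual_id: str
    mean_f0: float
    f0_within_sd: float
    f0_contour_shape: str = "flat"
    modulation_depth: float = 0.05
    vocal_tract_length: float = 14.0
    formant_shape_offsets: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    mean_duration: float = 0.6
    duration_within_cv: float = 0.08
    noise_gain: float = 0.05
    n_calls: int = 12

    def __post_init__(self) -> None:
        if not (PITCH_FLOOR <= self.mean_f0 <= PITCH_CEILING):
            raise PopulationError(
                f"mean_f0={self.mean_f0} outside the analysis pitch window "
                f"[{PITCH_FLOOR}, {PITCH_CEILING}] Hz"
            )
        if self.vocal_tract_length <= 0:
            raise PopulationError("vocal_tract_length must be positive")
        if self.n_calls < 2:
            raise PopulationError("n_calls must be >= 2 (CV needs an SD)")
        if self.duration_within_cv < 0:
            raise PopulationError("duration_within_cv must be >= 0")
        if self.noise_gain < 0:
            raise PopulationError("noise_gain must be >= 0")
        if self.f0_contour_shape not in CONTOUR_SHAPES:
            raise PopulationError(
                f"unknown contour shape {self.f0_contour_shape!r}; "
                f"expected one of {CONTOUR_SHAPES}"
            )
        self.formant_shape_offsets = tuple(float(x) for x in self.formant_shape_offsets)
        if len(self.formant_shape_offsets) != 4:
            raise PopulationError("formant_shape_offsets must have 4 entries")

    @property
    def delta_f(self) -> float:
        """Uniform-tube formant dispersion c/(2L) in Hz."""
        return SPEED_OF_SOUND / (2.0 * self.vocal_tract_length * 0.01)

    @property
    def formants(self) -> np.ndarray:
        """Target formant frequencies F1..F4 in Hz (tube positions + offsets)."""
        k = np.arange(1, 5)
        return (2 * k - 1) * self.delta_f / 2.0 + np.asarray(self.formant_shape_offsets)


@dataclass
class PopulationConfig:
    """A full synthetic-population specification: who calls, how, and where."""

    profiles: list[IndividualProfile]
    sample_rate: int = 44100
    bit_depth: int = 16
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        ids = [p.individual_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise PopulationError(f"individual_id values not unique: {ids}")
        if self.profiles:
            fmax = max(float(np.max(p.formants)) for p in self.profiles)
            if self.sample_rate < 2 * fmax:
                raise PopulationError(
                    f"sample_rate {self.sample_rate} below Nyquist for the "
                    f"highest synthesized formant ({fmax:.0f} Hz)"
                )

    @property
    def total_calls(self) -> int:
        return sum(p.n_calls for p in self.profiles)


@dataclass
class CallRecording:
    """One mono call: samples in [-1, 1], its rate, and its provenance."""

    samples: np.ndarray
    rate: int
    individual_id: str
    call_id: str
    seed: int = 0
    true_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence (mono)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise ValueError("samples must lie in [-1, 1]")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


# call-count pattern of the seven-male reference study (per-caller totals)
REFERENCE_CALL_COUNTS = (12, 16, 33, 23, 40, 24, 14)

# population-level baselines; between-individual SDs scale with `separation`,
# within-individual SDs with `within_scale`.  The f0 register and tract length
# are chosen jointly so the fundamental stays well below F1 and the fourth
# formant stays well inside the 8 kHz analysis band.
_BASE = {
    "mean_f0": 340.0,          # Hz, harmonic coo register of a large-bodied male
    "f0_between_sd": 40.0,     # Hz per unit separation
    "f0_within_sd": 12.0,      # Hz per unit within_scale
    "vtl": 9.6,                # cm -> ΔF ≈ 1823 Hz, F4 ≈ 6.38 kHz
    "vtl_between_sd": 0.3,     # cm per unit separation
    "formant_offset_sd": 45.0, # Hz per unit separation, per formant
    "duration": 0.55,          # s
    "duration_between_sd": 0.07,
    "duration_within_cv": 0.08,
    "noise_gain": 0.06,
    "noise_between_logsd": 0.35,  # log-scale SD per unit separation
}

# bounds keeping every sampled profile in the regime where the stated
# analysis settings (pitch 75-1200 Hz, 5 formants below 8 kHz) are valid
_F0_BOUNDS = (240.0, 460.0)
_VTL_BOUNDS = (9.3, 9.9)


def make_population(
    k: int,
    separation: float,
    within_scale: float,
    seed: int,
    n_calls: tuple[int, ...] | None = None,
    sample_rate: int = 44100,
) -> PopulationConfig:
    """Draw ``k`` caller profiles with controllable individuality structure.

    ``separation`` scales every between-individual SD (0 gives a null
    population of identical profiles); ``within_scale`` scales the
    within-individual call-to-call SDs.  Deterministic given ``seed``.
    Call counts default to the unbalanced reference pattern for k = 7 and to
    draws from [12, 40] otherwise.
    """
    if k < 2:
        raise PopulationError("a population needs at least k=2 individuals")
    if separation < 0:
        raise PopulationError("separation must be >= 0")
    if within_scale <= 0:
        raise PopulationError("within_scale must be > 0")

    rng = np.random.default_rng(seed)
    if n_calls is None:
        if k == len(REFERENCE_CALL_COUNTS):
            n_calls = REFERENCE_CALL_COUNTS
        else:
            n_calls = tuple(int(x) for x in rng.integers(12, 41, size=k))
    elif len(n_calls) != k:
        raise PopulationError("n_calls must have one entry per individual")

    profiles = []
    for i in range(k):
        mean_f0 = _BASE["mean_f0"] + separation * _BASE["f0_between_sd"] * rng.standard_normal()
        mean_f0 = float(np.clip(mean_f0, *_F0_BOUNDS))
        vtl = _BASE["vtl"] + separation * _BASE["vtl_between_sd"] * rng.standard_normal()
        vtl = float(np.clip(vtl, *_VTL_BOUNDS))
        offsets = np.clip(
            separation * _BASE["formant_offset_sd"] * rng.standard_normal(4),
            -90.0, 90.0,
        )
        duration = _BASE["duration"] + separation * _BASE["duration_between_sd"] * rng.standard_normal()
        duration = float(np.clip(duration, 0.25, 1.2))
        noise_gain = _BASE["noise_gain"] * float(
            np.exp(separation * _BASE["noise_between_logsd"] * rng.standard_normal())
        )
        shape = CONTOUR_SHAPES[int(rng.integers(len(CONTOUR_SHAPES)))] if separation > 0 else "arc"
        profiles.append(
            IndividualProfile(
                individual_id=f"M{i + 1:02d}",
                mean_f0=mean_f0,
                f0_within_sd=within_scale * _BASE["f0_within_sd"],
                f0_contour_shape=shape,
                modulation_depth=0.05,
                vocal_tract_length=vtl,
                formant_shape_offsets=tuple(offsets),
                mean_duration=duration,
                duration_within_cv=within_scale * _BASE["duration_within_cv"],
                noise_gain=noise_gain,
                n_calls=int(n_calls[i]),
            )
        )
    return PopulationConfig(profiles=profiles, sample_rate=sample_rate, master_seed=seed)


def _f0_contour(profile: IndividualProfile, call_mean_f0: float, n: int) -> np.ndarray:
    """Per-sample f0 track for one call, clipped into the analysis window."""
    t = np.linspace(0.0, 1.0, n)
    depth = profile.modulation_depth * call_mean_f0
    shape = profile.f0_contour_shape
    if shape == "flat":
        contour = np.full(n, call_mean_f0)
    elif shape == "fall":
        contour = call_mean_f0 + depth * (0.5 - t)
    elif shape == "rise":
        contour = call_mean_f0 + depth * (t - 0.5)
    else:  # arc
        contour = call_mean_f0 + depth * (np.sin(np.pi * t) - 2.0 / np.pi)
    lo, hi = PITCH_FLOOR + 5.0, PITCH_CEILING - 5.0
    if contour.min() < lo or contour.max() > hi:
        warnings.warn(
            f"f0 contour of {profile.individual_id} exits [{lo:.0f}, {hi:.0f}] Hz; "
            "clipping to keep pitch-analysis settings valid",
            stacklevel=2,
        )
        contour = np.clip(contour, lo, hi)
    return contour


def _resonator_coeffs(freq: float, bandwidth: float, rate: float):
    """Two-pole resonator (unit DC-ish gain numerator) at `freq` Hz."""
    r = np.exp(-np.pi * bandwidth / rate)
    theta = 2.0 * np.pi * freq / rate
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    b = [1.0 - r]  # keeps gains across formants comparable
    return b, a


def _formant_bandwidths(formants: np.ndarray) -> np.ndarray:
    """Bandwidths growing mildly with frequency, well under the 400 Hz cutoff."""
    return np.clip(80.0 + 0.03 * formants, 80.0, 200.0)


def _tract_resonances(profile: IndividualProfile) -> np.ndarray:
    """All tube resonances to synthesize: F1-F4 (with the profile's offsets)
    plus the unperturbed 5th and 6th resonances, so the spectrum above F4 is
    filled the way a real tract fills it."""
    k = np.arange(5, 7)
    upper = (2 * k - 1) * profile.delta_f / 2.0
    return np.concatenate([profile.formants, upper])


def _apply_tract(x: np.ndarray, formants: np.ndarray, rate: float) -> np.ndarray:
    y = x
    for f, bw in zip(formants, _formant_bandwidths(formants)):
        b, a = _resonator_coeffs(f, bw, rate)
        y = lfilter(b, a, y)
    return y


def synthesize_call(
    profile: IndividualProfile, call_seed: int, rate: int = 44100
) -> CallRecording:
    """Render one call from a profile: harmonic source, tract filter, noise.

    The glottal source is built additively as harmonics of the f0 contour with
    1/h² amplitudes (a -12 dB/octave tilt, band-limited below Nyquist, hence
    alias-free).  Aspiration noise passes through the same resonator cascade
    and is mixed at ``noise_gain`` relative to the harmonic RMS.
    """
    formants = profile.formants
    if rate < 2 * float(np.max(formants)):
        raise PopulationError(
            f"rate {rate} below Nyquist for highest formant {np.max(formants):.0f} Hz"
        )
    rng = np.random.default_rng(call_seed)
    duration = profile.mean_duration * (
        1.0 + profile.duration_within_cv * rng.standard_normal()
    )
    duration = float(np.clip(duration, 0.15, 2.0))
    call_mean_f0 = profile.mean_f0 + profile.f0_within_sd * rng.standard_normal()
    call_mean_f0 = float(np.clip(call_mean_f0, PITCH_FLOOR + 10, PITCH_CEILING - 10))

    n = int(round(duration * rate))
    contour = _f0_contour(profile, call_mean_f0, n)
    phase = 2.0 * np.pi * np.cumsum(contour) / rate

    # band-limited additive pulse train with -12 dB/oct tilt; the first
    # difference adds the +6 dB/oct lip-radiation characteristic
    n_harm = max(1, int(np.floor(0.95 * (rate / 2.0) / contour.max())))
    source = np.zeros(n)
    for h in range(1, n_harm + 1):
        source += np.cos(h * phase) / h**2
    source = np.diff(source, prepend=source[0])

    resonances = _tract_resonances(profile)
    resonances = resonances[resonances < 0.475 * rate]
    harmonic = _apply_tract(source, resonances, rate)
    h_rms = float(np.sqrt(np.mean(harmonic**2)))
    if profile.noise_gain > 0:
        noise = _apply_tract(rng.standard_normal(n), resonances, rate)
        noise *= profile.noise_gain * h_rms / float(np.sqrt(np.mean(noise**2)))
        signal = harmonic + noise
    else:
        signal = harmonic

    # soft raised-cosine onset/offset (25 ms or 10% of the call, whichever is less)
    ramp = min(int(0.025 * rate), n // 10)
    if ramp > 1:
        env = np.ones(n)
        win = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = win
        env[-ramp:] = win[::-1]
        signal = signal * env

    signal = PEAK_AMPLITUDE * signal / float(np.max(np.abs(signal)))

    x = np.array([0.5, 1.5, 2.5, 3.5])
    true_delta_f = float(np.dot(formants, x) / np.dot(x, x))
    return CallRecording(
        samples=signal,
        rate=rate,
        individual_id=profile.individual_id,
        call_id=f"{profile.individual_id}_s{call_seed}",
        seed=call_seed,
        true_params={
            "true_mean_f0": float(np.mean(contour)),
            "true_F1": float(formants[0]),
            "true_F2": float(formants[1]),
            "true_F3": float(formants[2]),
            "true_F4": float(formants[3]),
            "true_deltaF": true_delta_f,
            "true_duration": duration,
            "noise_gain": float(profile.noise_gain),
        },
    )


def iter_population_calls(config: PopulationConfig):
    """Yield every call of the population, deterministically seeded.

    Per-call seeds are drawn once from the master seed so that any ordering
    or subset of the population reproduces bit-identical audio.
    """
    if not config.profiles:
        raise PopulationError("population has no profiles")
    seed_rng = np.random.default_rng(config.master_seed)
    for profile in config.profiles:
        call_seeds = seed_rng.integers(0, 2**31 - 1, size=profile.n_calls)
        for j, cs in enumerate(call_seeds):
            rec = synthesize_call(profile, int(cs), config.sample_rate)
            rec.call_id = f"{profile.individual_id}_{j + 1:03d}"
            yield rec


def write_wav(path: str | Path, recording: CallRecording, bit_depth: int = 16) -> None:
    """Write a mono RIFF PCM WAV (16-bit by default)."""
    if bit_depth != 16:
        raise ValueError("only 16-bit PCM output is supported")
    scaled = np.round(recording.samples * 32767.0).astype(np.int16)
    wavfile.write(str(path), recording.rate, scaled)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono RIFF PCM WAV into float samples in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: stereo/multichannel WAV not supported, need mono")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return samples, int(rate)


def generate_dataset(
    config: PopulationConfig,
    output_dir: str | Path | None = None,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write one WAV per call plus a manifest CSV; return the manifest.

    The manifest records file, labels, per-call seed and the generating truth
    (f0, formants, ΔF, duration, noise gain) for recovery tests.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace it"
        )
    rows = []
    for rec in iter_population_calls(config):
        fname = f"{rec.call_id}.wav"
        write_wav(out / fname, rec, config.bit_depth)
        rows.append(
            {
                "file": fname,
                "individual_id": rec.individual_id,
                "call_id": rec.call_id,
                "seed": rec.seed,
                **rec.true_params,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def profile_to_dict(profile: IndividualProfile) -> dict:
    d = asdict(profile)
    d["formant_shape_offsets"] = list(profile.formant_shape_offsets)
    return d


def population_from_dict(d: dict) -> PopulationConfig:
    """Build a PopulationConfig from a plain dict (YAML config file contents)."""
    profiles = [
        IndividualProfile(
            **{**p, "formant_shape_offsets": tuple(p.get("formant_shape_offsets", (0, 0, 0, 0)))}
        )
        for p in d["profiles"]
    ]
    return PopulationConfig(
        profiles=profiles,
        sample_rate=int(d.get("sample_rate", 44100)),
        bit_depth=int(d.get("bit_depth", 16)),
        master_seed=int(d.get("master_seed", 0)),
        output_dir=d.get("output_dir"),
    )
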