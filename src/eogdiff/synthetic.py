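"""Synthetic saccadic electrooculogram generator.

Records are built velocity-first: for each stimulus transition a
single-signed velocity pulse is placed ``latency`` seconds later, the
pulses are concatenated into the exact velocity profile (EVP), and the
EVP is integrated to the noise-free position signal. Ground truth
(the EVP and the events annotated on it) is therefore known exactly,
which is what makes differentiator benchmarking possible at all.

The emulated protocol is horizontal saccadic stimulation: a target
alternating between two fixation points separated by the stimulation
angle (20, 30 or 60 degrees), so each saccade's amplitude equals the
stimulation angle with alternating sign. Two subject classes are
modelled through their main-sequence and latency parameters: healthy
controls and SCA2 patients, whose saccades are slower (longer durations,
hence lower peak velocities) with longer, more variable latencies.

Noise is added at the generation rate (1000 Hz) — 60 Hz mains
interference, white Gaussian noise, and 3-7 Hz band-limited "colored"
noise seen in patient recordings — and the record is then decimated to
200 Hz through an 8th-order Chebyshev type-I antialiasing filter, the
rate at which the whole benchmark operates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from .detection import DetectionConfig, SaccadeEvent, annotate_exact_events

__all__ = [
    "ClassParameters",
    "SaccadeParameters",
    "NoiseConfig",
    "SyntheticRecord",
    "DatasetConfig",
    "DatasetManifest",
    "DEFAULT_CLASS_PARAMS",
    "default_noise",
    "sample_parameters",
    "saccade_velocity_pulse",
    "build_record",
    "add_noise",
    "decimate_record",
    "generate_dataset",
]

GENERATOR_VERSION = "1.0"

CLASSES = ("healthy", "sca2")
ANGLES = (20, 30, 60)


@dataclass(frozen=True)
class ClassParameters:
    """Main-sequence and latency model of one subject class.

    Saccade duration follows the linear main sequence
    ``D(A) = d0 + d1 * |A|`` (seconds, A in degrees) with multiplicative
    lognormal jitter; latency is Gaussian truncated from below.
    Peak velocity is not drawn — it follows from the pulse shape,
    ``Vp = 2|A| / D`` for the sin^2 pulse.
    """

    d0: float
    d1: float
    duration_jitter_sigma: float
    latency_mean: float
    latency_sd: float
    latency_min: float = 0.10

    def mean_duration(self, amplitude_deg: float) -> float:
        return self.d0 + self.d1 * abs(amplitude_deg)


#: Healthy saccades at 20 deg last ~75 ms (Vp ~533 deg/s); SCA2 saccades
#: are markedly slowed (~180 ms, Vp ~222 deg/s at 20 deg) with longer,
#: more variable latencies — the class contrast the benchmark relies on.
DEFAULT_CLASS_PARAMS: dict[str, ClassParameters] = {
    "healthy": ClassParameters(
        d0=0.025, d1=0.0025, duration_jitter_sigma=0.08,
        latency_mean=0.20, latency_sd=0.03,
    ),
    "sca2": ClassParameters(
        d0=0.060, d1=0.006, duration_jitter_sigma=0.08,
        latency_mean=0.28, latency_sd=0.06,
    ),
}


@dataclass(frozen=True)
class SaccadeParameters:
    """Characteristic parameters of one generated saccade."""

    amplitude: float  # degrees, signed
    duration: float  # seconds
    peak_velocity: float  # deg/s
    latency: float  # seconds from stimulus transition to onset
    onset_time: float = 0.0  # absolute onset, seconds

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.amplitude == 0:
            raise ValueError("amplitude must be nonzero")
        if self.latency <= 0:
            raise ValueError("latency must be positive")
        if self.peak_velocity * self.duration < abs(self.amplitude) * (1 - 1e-9):
            raise ValueError(
                "peak_velocity * duration cannot be below |amplitude| "
                "(a pulse cannot integrate to more than its height x width)"
            )


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise model (all amplitudes in degrees of position).

    mains_amplitude : amplitude of the power-line sinusoid (default 60 Hz).
    white_sigma : standard deviation of white Gaussian noise.
    colored_sigma : standard deviation of band-limited (3-7 Hz) noise.
    """

    mains_amplitude: float = 0.3
    mains_freq: float = 60.0
    white_sigma: float = 0.1
    colored_sigma: float = 0.05
    colored_band: tuple[float, float] = (3.0, 7.0)

    def __post_init__(self) -> None:
        if min(self.mains_amplitude, self.white_sigma, self.colored_sigma) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        lo, hi = self.colored_band
        if not (0 < lo < hi):
            raise ValueError(f"invalid colored band {self.colored_band}")

    def to_dict(self) -> dict:
        return {
            "mains_amplitude": self.mains_amplitude,
            "mains_freq": self.mains_freq,
            "white_sigma": self.white_sigma,
            "colored_sigma": self.colored_sigma,
            "colored_band": list(self.colored_band),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseConfig":
        d = dict(d)
        d["colored_band"] = tuple(d.get("colored_band", (3.0, 7.0)))
        return cls(**d)


def default_noise(subject_class: str) -> NoiseConfig:
    """Per-class noise defaults; SCA2 recordings carry twice the 3-7 Hz noise.

    The colored amplitudes (0.05 deg healthy, 0.10 deg SCA2) keep the
    post-differentiation fixation velocity noise of well-behaved filters
    a few deg/s RMS, so the occurrence threshold sits many sigma above
    it — the regime in which velocity-threshold identification is known
    to operate cleanly. See docs/methods.md for the calibration.
    """
    _check_class(subject_class)
    return NoiseConfig(colored_sigma=0.10 if subject_class == "sca2" else 0.05)


@dataclass(eq=False)
class SyntheticRecord:
    """One synthetic record: position, exact velocity, and annotations."""

    fs: float
    position: np.ndarray  # degrees
    evp: np.ndarray  # exact velocity profile, deg/s
    stimulus_transitions: np.ndarray  # seconds
    exact_events: tuple[SaccadeEvent, ...]
    subject_class: str
    stimulation_angle: float
    seed: int | None = None
    noise: NoiseConfig | None = None
    parameters: tuple[SaccadeParameters, ...] = ()

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.evp = np.asarray(self.evp, dtype=float)
        self.stimulus_transitions = np.asarray(self.stimulus_transitions, dtype=float)
        if self.position.shape != self.evp.shape:
            raise ValueError("position and EVP must have equal length")
        for a, b in zip(self.exact_events, self.exact_events[1:]):
            if b.onset_index <= a.offset_index:
                raise ValueError("exact events must be disjoint and ordered")

    @property
    def n_samples(self) -> int:
        return self.position.size

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def _check_class(subject_class: str) -> None:
    if subject_class not in CLASSES:
        raise ValueError(f"unknown subject class {subject_class!r}; use {CLASSES}")


def _check_angle(angle_deg: float) -> None:
    if angle_deg not in ANGLES:
        raise ValueError(f"stimulation angle must be one of {ANGLES}, got {angle_deg}")


def sample_parameters(
    subject_class: str,
    angle_deg: float,
    rng: np.random.Generator,
    class_params: dict[str, ClassParameters] | None = None,
    jitter: bool = True,
    sign: float = 1.0,
) -> SaccadeParameters:
    """Draw the characteristic parameters of one saccade.

    Duration comes from the class main sequence with lognormal jitter
    (disabled with ``jitter=False`` for deterministic checks), latency
    from a truncated Gaussian, and peak velocity from the sin^2 pulse
    shape factor ``Vp = 2 |A| / D``.
    """
    _check_class(subject_class)
    _check_angle(angle_deg)
    p = (class_params or DEFAULT_CLASS_PARAMS)[subject_class]

    duration = p.mean_duration(angle_deg)
    if jitter:
        duration *= float(np.exp(rng.normal(0.0, p.duration_jitter_sigma)))

    if jitter:
        latency = float(rng.normal(p.latency_mean, p.latency_sd))
        while latency < p.latency_min:
            latency = float(rng.normal(p.latency_mean, p.latency_sd))
    else:
        latency = p.latency_mean

    amplitude = sign * angle_deg
    return SaccadeParameters(
        amplitude=amplitude,
        duration=duration,
        peak_velocity=2.0 * abs(amplitude) / duration,
        latency=latency,
    )


def saccade_velocity_pulse(params: SaccadeParameters, fs: float) -> np.ndarray:
    """Sampled sin^2 velocity pulse of one saccade.

    ``v(t) = Vp * sin^2(pi t / D) * sign(A)`` on [0, D], with
    ``Vp = 2|A|/D`` so the pulse integrates exactly to the amplitude.
    """
    if fs * params.duration < 4:
        raise ValueError(
            f"duration {params.duration}s too short for fs={fs} (needs >= 4 samples)"
        )
    n = int(np.floor(params.duration * fs)) + 1
    t = np.arange(n) / fs
    vp = 2.0 * abs(params.amplitude) / params.duration
    return np.sign(params.amplitude) * vp * np.sin(np.pi * t / params.duration) ** 2


def build_record(
    n_saccades: int,
    subject_class: str,
    angle_deg: float,
    fs: float = 1000.0,
    rng: np.random.Generator | None = None,
    class_params: dict[str, ClassParameters] | None = None,
    detection_cfg: DetectionConfig | None = None,
    fixation_range: tuple[float, float] = (1.5, 3.0),
    seed: int | None = None,
) -> SyntheticRecord:
    """Build one noise-free record of ``n_saccades`` alternating saccades.

    The stimulus steps between ``-angle/2`` and ``+angle/2`` at intervals
    drawn uniformly from ``fixation_range``; each transition elicits one
    saccade ``latency`` seconds later. Parameters whose pulse would
    collide with the next transition are redrawn (bounded retries).
    Exact events are annotated by the detector on the EVP.
    """
    if n_saccades < 1:
        raise ValueError("n_saccades must be >= 1")
    _check_class(subject_class)
    _check_angle(angle_deg)
    if rng is None:
        rng = np.random.default_rng(seed)

    gaps = rng.uniform(*fixation_range, size=n_saccades + 1)
    transitions = np.cumsum(gaps[:-1])
    total = float(np.sum(gaps))
    n = int(np.round(total * fs)) + 1

    evp = np.zeros(n)
    params_out = []
    guard = 0.05  # s of margin before the next transition
    for i, t0 in enumerate(transitions):
        deadline = (transitions[i + 1] if i + 1 < n_saccades else total) - guard
        sign = 1.0 if i % 2 == 0 else -1.0
        for attempt in range(20):
            p = sample_parameters(
                subject_class, angle_deg, rng, class_params, sign=sign
            )
            if t0 + p.latency + p.duration <= deadline:
                break
        else:
            raise RuntimeError(
                f"could not place saccade {i}: latency+duration keeps "
                "exceeding the fixation interval"
            )
        onset = t0 + p.latency
        p = dataclasses.replace(p, onset_time=onset)
        pulse = saccade_velocity_pulse(p, fs)
        start = int(np.round(onset * fs))
        evp[start : start + pulse.size] += pulse
        params_out.append(p)

    position = -angle_deg / 2.0 + cumulative_trapezoid(evp, dx=1.0 / fs, initial=0.0)

    record = SyntheticRecord(
        fs=fs,
        position=position,
        evp=evp,
        stimulus_transitions=transitions,
        exact_events=(),
        subject_class=subject_class,
        stimulation_angle=angle_deg,
        seed=seed,
        parameters=tuple(params_out),
    )
    record.exact_events = tuple(annotate_exact_events(record, detection_cfg))
    return record


def add_noise(
    record: SyntheticRecord, cfg: NoiseConfig, rng: np.random.Generator
) -> SyntheticRecord:
    """Contaminate the position signal; the EVP ground truth is untouched."""
    pos = record.position.copy()
    t = record.times
    if cfg.mains_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        pos += cfg.mains_amplitude * np.sin(2.0 * np.pi * cfg.mains_freq * t + phase)
    if cfg.white_sigma > 0:
        pos += rng.normal(0.0, cfg.white_sigma, size=pos.size)
    if cfg.colored_sigma > 0:
        lo, hi = cfg.colored_band
        if hi >= record.fs / 2:
            raise ValueError("colored band must lie below Nyquist")
        # The narrow bandpass rings for seconds; shape a longer white
        # stream and keep the settled middle, otherwise the noise starts
        # with a several-sigma startup transient at the record edge.
        margin = int(round(4.0 * record.fs / min(lo, 1.0)))
        raw = rng.standard_normal(pos.size + 2 * margin)
        b, a = signal.butter(4, [lo, hi], btype="band", fs=record.fs)
        shaped = signal.filtfilt(b, a, raw)[margin:-margin]
        sd = shaped.std()
        if sd > 0:
            pos += shaped * (cfg.colored_sigma / sd)
    return dataclasses.replace(record, position=pos, noise=cfg)


def decimate_record(
    record: SyntheticRecord,
    target_fs: float = 200.0,
    detection_cfg: DetectionConfig | None = None,
) -> SyntheticRecord:
    """Resample 1000 Hz -> 200 Hz with the standard decimation operator.

    Position and EVP go through the same 8th-order Chebyshev type-I
    antialiasing low-pass (zero-phase) and 1-in-q downsampling. Stimulus
    times are unchanged (seconds); exact events are re-annotated on the
    decimated EVP, since they are defined by thresholding the EVP at
    whichever rate the experiment runs at.
    """
    q = record.fs / target_fs
    if abs(q - round(q)) > 1e-9 or q < 1:
        raise ValueError(
            f"fs={record.fs} is not an integer multiple of target_fs={target_fs}"
        )
    q = int(round(q))
    # The zero-phase antialiasing filter has a startup transient at the
    # signal boundary (noticeable on the mains component) that would
    # differentiate into spurious velocity spikes in the edge fixations.
    # Edge-pad before filtering and crop after; alignment is preserved
    # because the pad length is a multiple of q.
    margin = 100 * q
    pos, evp = (
        signal.decimate(np.pad(x, margin, mode="edge"), q)[
            margin // q : -(margin // q)
        ]
        for x in (record.position, record.evp)
    )
    out = dataclasses.replace(
        record, fs=target_fs, position=pos, evp=evp, exact_events=()
    )
    out.exact_events = tuple(annotate_exact_events(out, detection_cfg))
    return out


@dataclass(frozen=True)
class DatasetConfig:
    """The dataset grid and generation conditions."""

    records_per_cell: int = 20
    n_saccades: int = 20
    classes: tuple[str, ...] = CLASSES
    angles: tuple[float, ...] = ANGLES
    fs: float = 1000.0
    target_fs: float = 200.0
    noise: dict[str, NoiseConfig] | None = None  # per class; None = defaults
    class_params: dict[str, ClassParameters] | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    noiseless: bool = False

    def noise_for(self, subject_class: str) -> NoiseConfig:
        if self.noiseless:
            return NoiseConfig(mains_amplitude=0.0, white_sigma=0.0, colored_sigma=0.0)
        if self.noise is not None:
            return self.noise[subject_class]
        return default_noise(subject_class)


@dataclass
class ManifestEntry:
    record_id: str
    subject_class: str
    angle: float
    seed: int
    path: str | None = None


@dataclass
class DatasetManifest:
    """Index of a generated dataset, optionally with in-memory records."""

    entries: list[ManifestEntry]
    records: list[SyntheticRecord] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[tuple[str, float], int]:
        out: dict[tuple[str, float], int] = {}
        for e in self.entries:
            key = (e.subject_class, e.angle)
            out[key] = out.get(key, 0) + 1
        return out

    def total_exact_saccades(self) -> int:
        if self.records is None:
            raise ValueError("manifest has no in-memory records")
        return sum(len(r.exact_events) for r in self.records)


def generate_dataset(
    config: DatasetConfig | None = None,
    master_seed: int = 0,
    out_dir=None,
) -> DatasetManifest:
    """Generate the full dataset grid (classes x angles x records-per-cell).

    Each record gets the derived seed ``master_seed + index`` so the whole
    dataset is a pure function of (config, master_seed). With ``out_dir``
    set, records are written as CSV + JSON sidecars and a manifest CSV.
    """
    config = config or DatasetConfig()
    entries: list[ManifestEntry] = []
    records: list[SyntheticRecord] = []
    idx = 0
    for subject_class in config.classes:
        for angle in config.angles:
            noise_cfg = config.noise_for(subject_class)
            for i in range(config.records_per_cell):
                seed = master_seed + idx
                rng = np.random.default_rng(seed)
                rec = build_record(
                    config.n_saccades, subject_class, angle,
                    fs=config.fs, rng=rng,
                    class_params=config.class_params,
                    detection_cfg=config.detection,
                    seed=seed,
                )
                rec = add_noise(rec, noise_cfg, rng)
                rec = decimate_record(rec, config.target_fs, config.detection)
                rid = f"{subject_class}_{int(angle):02d}_{i:02d}"
                entries.append(ManifestEntry(rid, subject_class, angle, seed))
                records.append(rec)
                idx += 1

    manifest = DatasetManifest(entries=entries, records=records)
    if out_dir is not None:
        from . import io as _io  # deferred: io imports this module

        _io.write_dataset(manifest, out_dir)
    return manifest
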