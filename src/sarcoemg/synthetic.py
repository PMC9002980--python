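"""Synthetic cohort generator.

No public sEMG sarcopenia dataset exists, so the pipeline is exercised on a
simulated cohort that reproduces the statistical structure the analysis
relies on:

* interference-pattern sEMG modelled as band-limited Gaussian noise,
  amplitude-modulated by a task activation profile — the standard surrogate
  when individual motor-unit physiology is not the question;
* the clinical labelling rule (SARC-F >= 4, EWGSOP2 grip cut-offs of
  27 kg / 16 kg, gait speed < 0.8 m/s) mapping screening data to three
  ordinal "confidence levels";
* a class effect encoded in BOTH the activation amplitude (strength loss)
  and the spectral centre frequency (slowing of the interference pattern),
  ordered level 1 > level 2 > level 3, so amplitude features (IEMG, RMS) and
  the averaged instantaneous frequency are genuinely informative;
* the published cohort imbalance: 3 / 22 / 7 subjects in levels 1 / 2 / 3.

Every subject gets the full acquisition protocol: a 5 s rest baseline, 5 s
MVC contractions of each muscle, a sit-to-stand burst (the feature source)
and a gait segment (generated for completeness, unused by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_io import (CHANNEL_NAMES, ClinicalAssessment, Recording,
                      ValidationError, logger)

#: EWGSOP2 weak-grip cut-offs, kg.
GRIP_CUTOFF_KG = {"male": 27.0, "female": 16.0}
#: EWGSOP2 slow-gait cut-off, m/s.
GAIT_CUTOFF_MS = 0.8
#: SARC-F screening threshold.
SARCF_THRESHOLD = 4

#: Mean rectified value of a unit-RMS Gaussian process, E|X| = sqrt(2/pi).
RECTIFIED_GAUSSIAN_MEAN = float(np.sqrt(2.0 / np.pi))


class BelowScreeningThreshold(ValueError):
    """SARC-F < 4: the subject is below the screening threshold, no level."""


def assign_confidence_level(a: ClinicalAssessment) -> int:
    """Grade an assessment into sarcopenia confidence level 1, 2 or 3.

    The criteria are nested: level 1 needs SARC-F >= 4; level 2 additionally
    weak grip (below the sex-specific EWGSOP2 cut-off); level 3 additionally
    slow gait (< 0.8 m/s).  The deepest satisfied level is returned.

    Raises
    ------
    BelowScreeningThreshold
        If SARC-F < 4; the caller decides whether to exclude the subject.
    """
    if a.sarcf < SARCF_THRESHOLD:
        raise BelowScreeningThreshold(
            f"subject {a.subject_id}: SARC-F {a.sarcf} below screening threshold "
            f"{SARCF_THRESHOLD}")
    level = 1
    if a.grip_kg < GRIP_CUTOFF_KG[a.sex]:
        level = 2
        if a.gait_speed < GAIT_CUTOFF_MS:
            level = 3
    return level


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelSignalParams:
    """Per-level sEMG effect parameters.

    peak_frac is the sit-to-stand activation peak as a fraction of MVC;
    center_hz / bandwidth_hz shape the interference-pattern spectrum;
    burst_s is the duration of the sit-to-stand burst.
    """

    peak_frac: float
    center_hz: float
    bandwidth_hz: float = 60.0
    burst_s: float = 2.0


#: Default effects: healthier level-1 subjects are stronger (higher MVC
#: fraction) and faster (higher spectral centre) than level-3 subjects.
DEFAULT_LEVEL_PARAMS = {
    1: LevelSignalParams(peak_frac=0.80, center_hz=120.0),
    2: LevelSignalParams(peak_frac=0.55, center_hz=95.0),
    3: LevelSignalParams(peak_frac=0.35, center_hz=70.0),
}

#: Protocol segment order and durations (seconds).
PROTOCOL = (
    ("baseline", 5.0),
    ("mvc_gl", 5.0),
    ("mvc_ta", 5.0),
    ("sit_to_stand", 4.0),
    ("gait", 5.0),
)


@dataclass
class CohortSpec:
    """Stated world of the synthetic cohort.

    Defaults mirror the published study: 3/22/7 subjects per level, MVC-scale
    signals around 1 mV with a 0.01 mV RMS noise floor, 1 kHz sampling.
    """

    counts: tuple[int, int, int] = (3, 22, 7)
    level_params: dict[int, LevelSignalParams] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_PARAMS))
    noise_floor_mv: float = 0.01
    mvc_peak_mv: float = 1.0
    sampling_rate: float = 1000.0
    #: multiplicative subject-to-subject jitter half-width on amplitudes
    jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValidationError("counts must be >= 0")
        for lvl in (1, 2, 3):
            if lvl not in self.level_params:
                raise ValidationError(f"level_params missing level {lvl}")
        p1, p2, p3 = (self.level_params[k] for k in (1, 2, 3))
        if not (p1.peak_frac > p2.peak_frac > p3.peak_frac):
            raise ValidationError("peak_frac must be strictly ordered level 1 > 2 > 3")
        if not (p1.center_hz > p2.center_hz > p3.center_hz):
            raise ValidationError("center_hz must be strictly ordered level 1 > 2 > 3")
        for lvl, p in self.level_params.items():
            lo = p.center_hz - p.bandwidth_hz / 2
            hi = p.center_hz + p.bandwidth_hz / 2
            if not (20.0 < lo and hi < 450.0):
                raise ValidationError(
                    f"level {lvl} band [{lo}, {hi}] Hz must lie inside (20, 450) Hz "
                    "to survive the analysis band-pass")
        if self.noise_floor_mv < 0 or self.mvc_peak_mv <= 0:
            raise ValidationError("noise_floor_mv >= 0 and mvc_peak_mv > 0 required")


@dataclass
class SyntheticSubject:
    """A generated recording, its clinical assessment and the true level.

    ``programmed`` records ground-truth quantities of the generator (per
    channel MVC envelope amplitude in mV) for cross-checking calibration.
    """

    recording: Recording
    assessment: ClinicalAssessment
    level: int
    programmed: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def generate_semg_channel(duration_s: float, fs: float,
                          activation_profile: np.ndarray,
                          center_f: float, bandwidth: float,
                          peak_mv: float, noise_floor: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Synthesise one sEMG channel.

    Band-limited Gaussian noise (4th-order Butterworth band-pass around
    ``center_f`` +/- ``bandwidth``/2, rescaled to unit RMS) is amplitude
    modulated by ``peak_mv * activation_profile`` and summed with a white
    noise floor of the given RMS.  Deterministic for a given ``rng`` state.
    """
    n = int(round(duration_s * fs))
    if activation_profile.shape != (n,):
        raise ValidationError(
            f"activation_profile must have {n} samples, got {activation_profile.shape}")
    lo, hi = center_f - bandwidth / 2, center_f + bandwidth / 2
    if not (0 < lo < hi < fs / 2):
        raise ValidationError(
            f"band [{lo}, {hi}] Hz must lie inside (0, Nyquist={fs / 2}) Hz")
    white = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(shaped ** 2))
    if rms > 0:
        shaped = shaped / rms
    x = peak_mv * activation_profile * shaped
    if noise_floor > 0:
        x = x + noise_floor * rng.standard_normal(n)
    return x


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth unimodal burst on [0, 1]: 0.5*(1 - cos(2*pi*t))."""
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def _protocol_layout(fs: float) -> tuple[dict[str, tuple[int, int]], int]:
    segments: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, dur in PROTOCOL:
        n = int(round(dur * fs))
        segments[name] = (pos, pos + n)
        pos += n
    return segments, pos


def _activation_profile(segments: dict[str, tuple[int, int]], n_total: int,
                        fs: float, muscle: str, params: LevelSignalParams,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude activation envelope across the whole protocol.

    The channel's own MVC segment is a sustained contraction at 1.0; the
    sit-to-stand is a raised-cosine burst at ``peak_frac``; gait is two
    modest bursts; baseline and the other muscle's MVC are rest.
    """
    profile = np.zeros(n_total)
    mvc_seg = "mvc_gl" if muscle == "GL" else "mvc_ta"
    start, end = segments[mvc_seg]
    profile[start:end] = 1.0

    start, end = segments["sit_to_stand"]
    burst_n = int(round(params.burst_s * fs))
    burst_n = min(burst_n, end - start)
    offset = (end - start - burst_n) // 2
    profile[start + offset:start + offset + burst_n] = (
        params.peak_frac * _raised_cosine(burst_n))

    start, end = segments["gait"]
    step_n = int(round(0.8 * fs))
    for k in (0, 2):  # two stance bursts
        s = start + k * step_n
        e = min(s + step_n, end)
        if e > s:
            profile[s:e] = 0.35 * params.peak_frac * _raised_cosine(e - s)
    return profile


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

def _sample_assessment(subject_id: str, level: int,
                       rng: np.random.Generator) -> ClinicalAssessment:
    """Draw screening values uniformly within level-consistent ranges."""
    sex = "male" if rng.random() < 0.5 else "female"
    cutoff = GRIP_CUTOFF_KG[sex]
    sarcf = int(rng.integers(SARCF_THRESHOLD, 11))
    if level == 1:
        grip = float(rng.uniform(cutoff + 1.0, cutoff + 15.0))
        gait = float(rng.uniform(0.8, 1.4))
    elif level == 2:
        grip = float(rng.uniform(max(cutoff - 12.0, 1.0), cutoff - 1.0))
        gait = float(rng.uniform(0.8, 1.3))
    elif level == 3:
        grip = float(rng.uniform(max(cutoff - 12.0, 1.0), cutoff - 1.0))
        gait = float(rng.uniform(0.3, 0.75))
    else:
        raise ValidationError(f"level must be 1, 2 or 3, got {level}")
    a = ClinicalAssessment(subject_id=subject_id, sarcf=sarcf, grip_kg=grip,
                           gait_speed=gait, sex=sex)
    assert assign_confidence_level(a) == level
    return a


def generate_subject(level: int, spec: CohortSpec, rng: np.random.Generator,
                     subject_id: str = "S000") -> SyntheticSubject:
    """Generate one subject: full-protocol recording plus consistent assessment."""
    params = spec.level_params[level]
    fs = spec.sampling_rate
    segments, n_total = _protocol_layout(fs)
    assessment = _sample_assessment(subject_id, level, rng)

    channels: dict[str, np.ndarray] = {}
    programmed_mvc: dict[str, float] = {}
    for name in CHANNEL_NAMES:
        muscle = "GL" if name.startswith("GL") else "TA"
        # subject/channel-level MVC scale jitter; normalisation removes it
        amp = spec.mvc_peak_mv * float(rng.uniform(1 - spec.jitter, 1 + spec.jitter))
        profile = _activation_profile(segments, n_total, fs, muscle, params, rng)
        channels[name] = generate_semg_channel(
            n_total / fs, fs, profile, params.center_hz, params.bandwidth_hz,
            amp, spec.noise_floor_mv, rng)
        # expected mean rectified amplitude during the MVC contraction
        programmed_mvc[name] = amp * RECTIFIED_GAUSSIAN_MEAN

    rec = Recording(subject_id=subject_id, sampling_rate=fs, channels=channels,
                    segments=segments, sex=assessment.sex)
    return SyntheticSubject(recording=rec, assessment=assessment, level=level,
                            programmed={"mvc_envelope_mv": programmed_mvc})


def generate_cohort(spec: CohortSpec | None = None) -> list[SyntheticSubject]:
    """Generate the full cohort in randomised order, deterministic under seed."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    order = [lvl for lvl, count in zip((1, 2, 3), spec.counts) for _ in range(count)]
    order = [order[i] for i in rng.permutation(len(order))]
    subjects = [
        generate_subject(lvl, spec, rng, subject_id=f"S{i:03d}")
        for i, lvl in enumerate(order)
    ]
    got = {lvl: sum(s.level == lvl for s in subjects) for lvl in (1, 2, 3)}
    logger.info("generated cohort: %s", got)
    return subjects
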