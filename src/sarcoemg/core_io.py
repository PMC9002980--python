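"""Domain containers, file I/O and run configuration.

The pipeline works on four bipolar surface-EMG channels recorded from the
lower limbs (left/right Gastrocnemius Lateralis and Tibialis Anterior) while
a subject performs a clinical protocol: a 5 s rest baseline, two 5 s maximum
voluntary contraction (MVC) calibration trials, a sit-to-stand transfer and a
short walk.  Signals travel as plain CSV (one column per channel, mV) with a
separate annotation CSV giving the protocol segments in seconds; clinical
screening data (SARC-F, hand-grip strength, gait speed) live in their own
table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("sarcoemg")

#: Canonical channel order: muscle (GL then TA), left before right.
CHANNEL_NAMES = ("GL_left", "GL_right", "TA_left", "TA_right")

#: Protocol segments.  ``mvc_gl``/``mvc_ta`` are the calibration contractions
#: of the respective muscle; features are extracted from ``sit_to_stand``.
SEGMENT_NAMES = ("baseline", "mvc_gl", "mvc_ta", "sit_to_stand", "gait")

#: Segments that calibrate or reference the signal must span at least 5 s.
MIN_CALIBRATION_S = 5.0
CALIBRATION_SEGMENTS = ("baseline", "mvc_gl", "mvc_ta")

SEXES = ("male", "female")


class FormatError(ValueError):
    """A file does not have the expected layout (e.g. a channel is missing)."""


class ValidationError(ValueError):
    """Data violates a domain invariant."""


class ConfigError(ValueError):
    """Invalid run configuration."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A multi-channel sEMG record with protocol annotations.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    sampling_rate : float
        Sampling frequency in Hz.
    channels : dict
        Maps each of the four canonical channel names to a 1-D float array.
        Units are mV for raw/filtered signals; after MVC normalisation the
        values are dimensionless MVC fractions.
    segments : dict
        Maps segment names to half-open, 0-based sample intervals
        ``(start, end)``.
    sex : str
        ``"male"`` or ``"female"``.
    kind : str
        Processing state: ``"raw"``, ``"filtered"`` or ``"envelope"``.
    normalized : bool
        True once amplitudes have been divided by the MVC reference.
    """

    subject_id: str
    sampling_rate: float
    channels: dict[str, np.ndarray]
    segments: dict[str, tuple[int, int]]
    sex: str
    kind: str = "raw"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.channels:
            raise FormatError("recording has no channels")
        for name in CHANNEL_NAMES:
            if name not in self.channels:
                raise FormatError(f"channel {name} missing")
        # canonical order, contiguous float arrays
        self.channels = {
            name: np.ascontiguousarray(self.channels[name], dtype=float)
            for name in CHANNEL_NAMES
        }
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValidationError(f"channels have differing lengths: {sorted(lengths)}")
        n = lengths.pop()
        for seg, (start, end) in self.segments.items():
            if seg not in SEGMENT_NAMES:
                raise ValidationError(
                    f"unknown segment {seg!r}; expected one of {SEGMENT_NAMES}")
            if not (0 <= start < end <= n):
                raise ValidationError(
                    f"segment {seg} interval [{start}, {end}) outside signal [0, {n})")
        for seg in CALIBRATION_SEGMENTS:
            if seg in self.segments:
                start, end = self.segments[seg]
                if end - start < MIN_CALIBRATION_S * self.sampling_rate:
                    raise ValidationError(
                        f"segment {seg} spans {(end - start) / self.sampling_rate:.2f} s, "
                        f"needs >= {MIN_CALIBRATION_S} s")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def segment_slice(self, name: str) -> slice:
        if name not in self.segments:
            raise ValidationError(
                f"recording {self.subject_id} has no segment {name!r}")
        start, end = self.segments[name]
        return slice(start, end)

    def replace_channels(self, channels: Mapping[str, np.ndarray], *,
                         kind: str | None = None,
                         normalized: bool | None = None) -> "Recording":
        """Copy of this recording with new channel data, same annotations."""
        return Recording(
            subject_id=self.subject_id,
            sampling_rate=self.sampling_rate,
            channels=dict(channels),
            segments=dict(self.segments),
            sex=self.sex,
            kind=self.kind if kind is None else kind,
            normalized=self.normalized if normalized is None else normalized,
        )


@dataclass(frozen=True)
class ClinicalAssessment:
    """Screening measurements used to grade sarcopenia confidence.

    SARC-F is the 5-item questionnaire (each item 0-2, total 0-10); grip is
    the best hand-dynamometer reading in kg; gait speed in m/s over 5 m.
    """

    subject_id: str
    sarcf: int
    grip_kg: float
    gait_speed: float
    sex: str

    def __post_init__(self) -> None:
        if not (0 <= self.sarcf <= 10):
            raise ValidationError(f"SARC-F score must be in [0, 10], got {self.sarcf}")
        if self.grip_kg < 0:
            raise ValidationError("grip_kg must be >= 0")
        if self.gait_speed < 0:
            raise ValidationError("gait_speed must be >= 0")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")


#: Default 12-feature set, in canonical order.
DEFAULT_FEATURES = (
    "IEMG", "MAV", "MAV1", "MAV2", "RMS", "VAR",
    "AAC", "ZC", "SSI", "SSC", "WAMP", "AIF",
)


@dataclass
class PipelineConfig:
    """Effective parameters of a full pipeline run.

    Defaults are the published operating point: 20-450 Hz 4th-order
    Butterworth band-pass, 10 Hz envelope cut-off, 200 ms windows advanced by
    50 ms, count-feature threshold 0.1 mV and 10-fold cross-validation.
    """

    sampling_rate: float = 1000.0
    band_low: float = 20.0
    band_high: float = 450.0
    filter_order: int = 4
    filter_phase: str = "zero_phase"          # or "causal"
    envelope_cutoff: float = 10.0
    baseline_subtract: bool = True            # subtract rest baseline from MVC reference
    window_ms: float = 200.0
    step_ms: float = 50.0
    edge_trim_s: float = 0.25                 # trim filter transients at segment edges
    thr_mv: float = 0.1                       # ZC/SSC/WAMP amplitude guard, in mV
    features: tuple[str, ...] = DEFAULT_FEATURES
    feature_source: str = "filtered"          # or "envelope"
    aggregate: str = "per_subject_mean"       # or "per_window"
    smote_k: int = 5
    enn_k: int = 3
    smote_target: object = 50                 # per-class count, or "majority"
    selection: str = "fixed_paper_subset"     # "none" | "fixed_paper_subset" | "mbtga"
    cv_folds: int = 10
    paper_mode: bool = True                   # global balancing before CV
    seed: int = 0

    _ALIASES = {"band_pass": ("band_low", "band_high")}

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.band_low >= self.band_high:
            raise ConfigError("lower edge must be < upper edge")
        if self.band_low <= 0:
            raise ConfigError("band_low must be positive")
        if self.sampling_rate <= 2 * self.band_high:
            raise ConfigError(
                f"sampling_rate {self.sampling_rate} Hz cannot represent the "
                f"{self.band_high} Hz band edge (Nyquist)")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.filter_phase not in ("zero_phase", "causal"):
            raise ConfigError("filter_phase must be 'zero_phase' or 'causal'")
        if self.envelope_cutoff <= 0:
            raise ConfigError("envelope_cutoff must be positive")
        if self.window_ms <= 0 or not (0 < self.step_ms <= self.window_ms):
            raise ConfigError("need window_ms > 0 and 0 < step_ms <= window_ms")
        if self.thr_mv < 0:
            raise ConfigError("thr_mv must be >= 0")
        unknown = set(self.features) - set(DEFAULT_FEATURES)
        if unknown:
            raise ConfigError(f"unknown features: {sorted(unknown)}")
        if self.feature_source not in ("filtered", "envelope"):
            raise ConfigError("feature_source must be 'filtered' or 'envelope'")
        if self.aggregate not in ("per_subject_mean", "per_window"):
            raise ConfigError("aggregate must be 'per_subject_mean' or 'per_window'")
        if self.smote_k < 1 or self.enn_k < 1:
            raise ConfigError("neighbour counts must be >= 1")
        if self.smote_target != "majority" and (
                not isinstance(self.smote_target, int) or self.smote_target < 1):
            raise ConfigError("smote_target must be 'majority' or a positive int")
        if self.selection not in ("none", "fixed_paper_subset", "mbtga"):
            raise ConfigError("selection must be none|fixed_paper_subset|mbtga")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["features"] = list(self.features)
        return d


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> PipelineConfig:
    """Read a YAML key-value config; unspecified keys keep their defaults.

    ``band_pass: [low, high]`` is accepted as an alias for the two edge keys.
    Unknown keys raise :class:`ConfigError` listing the valid ones.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config must be a mapping, got {type(loaded).__name__}")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)

    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    kwargs: dict = {}
    for key, value in raw.items():
        if key == "band_pass":
            if (not isinstance(value, (list, tuple)) or len(value) != 2):
                raise ConfigError("band_pass must be a [low, high] pair")
            kwargs["band_low"], kwargs["band_high"] = float(value[0]), float(value[1])
            continue
        if key not in valid:
            raise ConfigError(
                f"unknown config key {key!r}; valid keys: {sorted(valid | {'band_pass'})}")
        kwargs[key] = value

    # numeric coercion with a clear parse error
    numeric = {"sampling_rate", "band_low", "band_high", "envelope_cutoff",
               "window_ms", "step_ms", "edge_trim_s", "thr_mv"}
    for key in list(kwargs):
        if key in numeric:
            try:
                kwargs[key] = float(kwargs[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"config key {key!r} must be numeric, "
                                  f"got {kwargs[key]!r}") from exc
        elif key in {"filter_order", "smote_k", "enn_k", "cv_folds", "seed"}:
            try:
                kwargs[key] = int(kwargs[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"config key {key!r} must be an integer, "
                                  f"got {kwargs[key]!r}") from exc
    if "features" in kwargs:
        kwargs["features"] = tuple(kwargs["features"])

    cfg = PipelineConfig(**kwargs)
    logger.info("effective config: %s", cfg.to_dict())
    return cfg


# ---------------------------------------------------------------------------
# signal / annotation files
# ---------------------------------------------------------------------------

_META_KEYS = ("subject_id", "sampling_rate_hz", "sex")


def write_recording(rec: Recording, signal_path: str | Path,
                    annotation_path: str | Path) -> tuple[Path, Path]:
    """Write a recording as a signal CSV plus an annotation CSV.

    The signal file carries ``# key: value`` metadata comment lines (subject
    id, sampling rate, sex) above a header row with the four channel names in
    canonical order.  Annotation times are written in seconds.  Amplitudes are
    serialised with enough digits that a round trip is exact to <1e-9 mV.
    """
    signal_path, annotation_path = Path(signal_path), Path(annotation_path)
    if not rec.segments:
        logger.warning("recording %s has no annotated segments", rec.subject_id)
    meta = (f"# subject_id: {rec.subject_id}\n"
            f"# sampling_rate_hz: {rec.sampling_rate!r}\n"
            f"# sex: {rec.sex}\n")
    frame = pd.DataFrame({name: rec.channels[name] for name in CHANNEL_NAMES})
    with open(signal_path, "w") as fh:
        fh.write(meta)
        frame.to_csv(fh, index=False, float_format="%.10e")
    rows = [
        {"segment": seg, "start_s": start / rec.sampling_rate,
         "end_s": end / rec.sampling_rate}
        for seg, (start, end) in rec.segments.items()
    ]
    pd.DataFrame(rows, columns=["segment", "start_s", "end_s"]).to_csv(
        annotation_path, index=False, float_format="%.9g")
    return signal_path, annotation_path


def _read_signal_metadata(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_recording(signal_path: str | Path, annotation_path: str | Path, *,
                   sampling_rate: float | None = None,
                   subject_id: str | None = None,
                   sex: str | None = None) -> Recording:
    """Read a signal CSV and its annotation sidecar into a :class:`Recording`.

    Metadata missing from the file's comment header can be supplied as
    keyword arguments (sampling rate falls back to 1000 Hz with a warning).
    Segment times in seconds are converted to 0-based half-open sample
    intervals.
    """
    signal_path, annotation_path = Path(signal_path), Path(annotation_path)
    meta = _read_signal_metadata(signal_path)
    frame = pd.read_csv(signal_path, comment="#")
    for name in CHANNEL_NAMES:
        if name not in frame.columns:
            raise FormatError(f"channel {name} missing")

    if sampling_rate is None:
        if "sampling_rate_hz" in meta:
            sampling_rate = float(meta["sampling_rate_hz"])
        else:
            sampling_rate = 1000.0
            logger.warning("%s: no sampling rate in header; assuming 1000 Hz",
                           signal_path)
    if subject_id is None:
        subject_id = meta.get("subject_id", signal_path.stem)
    if sex is None:
        sex = meta.get("sex", "male")

    ann = pd.read_csv(annotation_path)
    for col in ("segment", "start_s", "end_s"):
        if col not in ann.columns:
            raise FormatError(f"annotation file lacks column {col!r}")
    n = len(frame)
    segments: dict[str, tuple[int, int]] = {}
    for _, row in ann.iterrows():
        start = int(round(float(row["start_s"]) * sampling_rate))
        end = int(round(float(row["end_s"]) * sampling_rate))
        if not (0 <= start < end <= n):
            raise ValidationError(
                f"segment {row['segment']} [{row['start_s']}, {row['end_s']}) s "
                f"outside the {n / sampling_rate:.3f} s signal")
        segments[str(row["segment"])] = (start, end)
    # overlap check (sorted by start)
    ordered = sorted(segments.items(), key=lambda kv: kv[1][0])
    for (seg_a, (_, end_a)), (seg_b, (start_b, _)) in zip(ordered, ordered[1:]):
        if start_b < end_a:
            raise ValidationError(f"segments {seg_a} and {seg_b} overlap")

    return Recording(
        subject_id=subject_id, sampling_rate=sampling_rate,
        channels={name: frame[name].to_numpy(dtype=float) for name in CHANNEL_NAMES},
        segments=segments, sex=sex,
    )


def write_assessments(assessments: list[ClinicalAssessment], path: str | Path,
                      levels: list[int] | None = None) -> Path:
    """Write the cohort clinical table (one row per subject)."""
    rows = []
    for i, a in enumerate(assessments):
        row = {"subject_id": a.subject_id, "sarcf": a.sarcf, "grip_kg": a.grip_kg,
               "sex": a.sex, "gait_speed": a.gait_speed}
        if levels is not None:
            row["level"] = levels[i]
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_assessments(path: str | Path) -> tuple[list[ClinicalAssessment], list[int] | None]:
    frame = pd.read_csv(path)
    required = {"subject_id", "sarcf", "grip_kg", "sex", "gait_speed"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"assessment file lacks columns {sorted(missing)}")
    assessments = [
        ClinicalAssessment(subject_id=str(r.subject_id), sarcf=int(r.sarcf),
                           grip_kg=float(r.grip_kg), gait_speed=float(r.gait_speed),
                           sex=str(r.sex))
        for r in frame.itertuples()
    ]
    levels = [int(v) for v in frame["level"]] if "level" in frame.columns else None
    return assessments, levels
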