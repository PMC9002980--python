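"""Sliding-window feature extraction.

Twelve time and time-frequency domain features are computed per channel on
200 ms windows advanced by 50 ms over the sit-to-stand segment, giving a
48-dimensional vector per instance (12 features x 4 channels).

Amplitude/energy features: IEMG, MAV, MAV1, MAV2, RMS, VAR, AAC, SSI.
Threshold-guarded counts: ZC (zero crossings), SSC (slope-sign changes),
WAMP (Willison amplitude), all with amplitude guard ``thr`` (0.1 mV on raw
signals; divided by the MVC reference when the signal is normalised).
Spectral: AIF, the window mean of the instantaneous frequency obtained from
the unwrapped phase of the analytic (Hilbert) signal, in Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .core_io import (CHANNEL_NAMES, DEFAULT_FEATURES, Recording,
                      ValidationError, logger)

FEATURE_NAMES = DEFAULT_FEATURES


@dataclass(frozen=True)
class WindowPlan:
    """Window length/step in ms with derived sample counts at a given rate."""

    window_ms: float = 200.0
    step_ms: float = 50.0
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_samples <= 1:
            raise ValidationError("window must span more than one sample")
        if not (0 < self.step_samples <= self.n_samples):
            raise ValidationError("need 0 < step <= window length")

    @property
    def n_samples(self) -> int:
        return int(round(self.window_ms * self.sampling_rate / 1000.0))

    @property
    def step_samples(self) -> int:
        return int(round(self.step_ms * self.sampling_rate / 1000.0))


@dataclass(frozen=True)
class FeatureParams:
    """Threshold configuration for the count features.

    ``thr`` is in the units of the analysed signal.  When the signal has been
    MVC-normalised, pass ``channel_thr`` mapping each channel to
    0.1 mV / (that channel's MVC reference) so the printed mV threshold keeps
    its meaning.
    """

    thr: float = 0.1
    channel_thr: dict[str, float] | None = None

    def thr_for(self, channel: str) -> float:
        if self.channel_thr is not None:
            return self.channel_thr[channel]
        return self.thr


def segment_windows(series: np.ndarray, plan: WindowPlan) -> np.ndarray:
    """Slice a series into overlapping windows (trailing partial discarded).

    Returns an array of shape ``(count, N)`` with
    ``count = floor((L - N) / S) + 1``.
    """
    series = np.asarray(series, dtype=float)
    n, s = plan.n_samples, plan.step_samples
    if series.ndim != 1:
        raise ValidationError("series must be 1-D")
    if len(series) < n:
        raise ValidationError(
            f"series of {len(series)} samples shorter than one {n}-sample window")
    count = (len(series) - n) // s + 1
    idx = np.arange(n)[None, :] + s * np.arange(count)[:, None]
    return series[idx]


# ---------------------------------------------------------------------------
# per-window features
# ---------------------------------------------------------------------------

def feature_IEMG(x: np.ndarray, params: FeatureParams | None = None) -> float:
    return float(np.sum(np.abs(x)))


def feature_MAV(x: np.ndarray, params: FeatureParams | None = None) -> float:
    return float(np.mean(np.abs(x)))


def _mav1_weights(n: int) -> np.ndarray:
    # 1-based index i; full weight on the central half 0.25N <= i <= 0.75N
    i = np.arange(1, n + 1)
    return np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)


def _mav2_weights(n: int) -> np.ndarray:
    # ramp up 4i/N before the central half, ramp down 4(N-i)/N after it
    i = np.arange(1, n + 1)
    w = np.ones(n)
    w[i < 0.25 * n] = 4.0 * i[i < 0.25 * n] / n
    w[i > 0.75 * n] = 4.0 * (n - i[i > 0.75 * n]) / n
    return w


def feature_MAV1(x: np.ndarray, params: FeatureParams | None = None) -> float:
    return float(np.sum(_mav1_weights(len(x)) * np.abs(x)) / len(x))


def feature_MAV2(x: np.ndarray, params: FeatureParams | None = None) -> float:
    return float(np.sum(_mav2_weights(len(x)) * np.abs(x)) / len(x))


def feature_RMS(x: np.ndarray, params: FeatureParams | None = None) -> float:
    return float(np.sqrt(np.mean(x ** 2)))


def feature_VAR(x: np.ndarray, params: FeatureParams | None = None) -> float:
    return float(np.sum(x ** 2) / (len(x) - 1))


def feature_AAC(x: np.ndarray, params: FeatureParams | None = None) -> float:
    return float(np.sum(np.abs(np.diff(x))))


def feature_SSI(x: np.ndarray, params: FeatureParams | None = None) -> float:
    return float(np.sum(x ** 2))


def feature_ZC(x: np.ndarray, params: FeatureParams) -> float:
    """Sign changes whose amplitude gap clears the threshold guard."""
    thr = params.thr
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(x[:-1] - x[1:]) >= thr
    return float(np.count_nonzero(sign_change & big_enough))


def feature_SSC(x: np.ndarray, params: FeatureParams) -> float:
    """Slope-sign changes: (x_i - x_{i-1})(x_i - x_{i+1}) >= thr."""
    thr = params.thr
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return float(np.count_nonzero(prod >= thr))


def feature_WAMP(x: np.ndarray, params: FeatureParams) -> float:
    """Willison amplitude: consecutive differences of at least thr."""
    thr = params.thr
    return float(np.count_nonzero(np.abs(x[:-1] - x[1:]) >= thr))


def feature_AIF(x: np.ndarray, fs: float) -> float:
    """Averaged instantaneous frequency of the window, in Hz.

    The instantaneous frequency is the time derivative of the unwrapped
    analytic-signal phase over 2*pi; its window mean is clamped to
    [0, fs/2].  An all-zero window has undefined phase and yields 0.
    """
    if len(x) <= 4:
        raise ValidationError("AIF needs more than 4 samples")
    if not np.any(x):
        warnings.warn("AIF of an all-zero window is undefined; returning 0",
                      stacklevel=2)
        return 0.0
    phase = np.unwrap(np.angle(hilbert(x)))
    inst_f = np.diff(phase) * fs / (2.0 * np.pi)
    return float(np.clip(np.mean(inst_f), 0.0, fs / 2.0))


_AMPLITUDE_FEATURES: dict[str, Callable] = {
    "IEMG": feature_IEMG, "MAV": feature_MAV, "MAV1": feature_MAV1,
    "MAV2": feature_MAV2, "RMS": feature_RMS, "VAR": feature_VAR,
    "AAC": feature_AAC, "SSI": feature_SSI,
}
_COUNT_FEATURES: dict[str, Callable] = {
    "ZC": feature_ZC, "SSC": feature_SSC, "WAMP": feature_WAMP,
}


def compute_window_features(window: np.ndarray, fs: float, thr: float,
                            features: Sequence[str] = FEATURE_NAMES) -> dict[str, float]:
    """All requested features of one window (thr already in signal units)."""
    params = FeatureParams(thr=thr)
    out: dict[str, float] = {}
    for name in features:
        if name in _AMPLITUDE_FEATURES:
            out[name] = _AMPLITUDE_FEATURES[name](window)
        elif name in _COUNT_FEATURES:
            out[name] = _COUNT_FEATURES[name](window, params)
        elif name == "AIF":
            out[name] = feature_AIF(window, fs)
        else:
            raise ValidationError(f"unknown feature {name!r}")
    return out


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def column_name(channel: str, feature: str) -> str:
    return f"{channel}:{feature}"


@dataclass
class FeatureMatrix:
    """Instances x named feature columns, with an aligned label vector."""

    data: pd.DataFrame          # index: instance ids, columns "channel:feature"
    labels: pd.Series           # confidence level per instance

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.data.index)
        if self.labels.isna().any():
            raise ValidationError("labels missing for some instances")
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValidationError("feature matrix contains non-finite entries")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_instances(self) -> int:
        return len(self.data)

    def class_counts(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in self.labels.value_counts().sort_index().items()}

    def to_csv(self, path: str | Path) -> Path:
        frame = self.data.copy()
        frame.insert(0, "instance_id", self.data.index)
        frame["level"] = self.labels.to_numpy()
        frame.to_csv(path, index=False, float_format="%.10g")
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        if "instance_id" not in frame.columns or "level" not in frame.columns:
            raise ValidationError("feature CSV needs instance_id and level columns")
        frame = frame.set_index("instance_id")
        labels = frame.pop("level").astype(int)
        return cls(data=frame.astype(float), labels=labels)


def build_feature_matrix(recordings: Sequence[Recording],
                         labels: Sequence[int],
                         plan: WindowPlan | None = None,
                         params: FeatureParams | None = None,
                         features: Sequence[str] = FEATURE_NAMES,
                         segment: str = "sit_to_stand",
                         edge_trim_s: float = 0.25,
                         aggregate: str = "per_subject_mean") -> FeatureMatrix:
    """Extract the feature matrix from preprocessed recordings.

    Features are computed on the named segment only (default sit-to-stand,
    the task the study uses for classification), excluding ``edge_trim_s``
    at each end to avoid filter transients.  ``per_subject_mean`` averages
    each feature over the windows, one instance per subject; ``per_window``
    emits one instance per window.  Column order is deterministic: channels
    in canonical order, features in table order.
    """
    if len(recordings) != len(labels):
        raise ValidationError("recordings and labels length mismatch")
    if aggregate not in ("per_subject_mean", "per_window"):
        raise ValidationError("aggregate must be per_subject_mean or per_window")
    params = params or FeatureParams()

    columns = [column_name(ch, f) for ch in CHANNEL_NAMES for f in features]
    rows: list[np.ndarray] = []
    ids: list[str] = []
    out_labels: list[int] = []

    for rec, level in zip(recordings, labels):
        if segment not in rec.segments:
            raise ValidationError(
                f"recording {rec.subject_id} has no {segment!r} segment")
        plan_ = plan or WindowPlan(sampling_rate=rec.sampling_rate)
        start, end = rec.segments[segment]
        trim = int(round(edge_trim_s * rec.sampling_rate))
        start, end = start + trim, end - trim
        if end - start < plan_.n_samples:
            raise ValidationError(
                f"recording {rec.subject_id}: {segment} segment too short for one "
                f"window after edge trimming")

        per_channel: list[np.ndarray] = []  # (n_windows, n_features) per channel
        for ch in CHANNEL_NAMES:
            windows = segment_windows(rec.channels[ch][start:end], plan_)
            thr = params.thr_for(ch)
            vals = np.array([
                [compute_window_features(w, rec.sampling_rate, thr, features)[f]
                 for f in features]
                for w in windows
            ])
            per_channel.append(vals)
        block = np.hstack(per_channel)  # (n_windows, n_channels * n_features)

        if aggregate == "per_subject_mean":
            rows.append(block.mean(axis=0))
            ids.append(rec.subject_id)
            out_labels.append(int(level))
        else:
            for w_i, row in enumerate(block):
                rows.append(row)
                ids.append(f"{rec.subject_id}:w{w_i:03d}")
                out_labels.append(int(level))

    data = pd.DataFrame(np.array(rows), index=pd.Index(ids, name="instance_id"),
                        columns=columns)
    logger.info("feature matrix: %d instances x %d columns", *data.shape)
    return FeatureMatrix(data=data, labels=pd.Series(out_labels, index=data.index))
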