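"""Noise reduction, linear envelope and MVC normalisation.

The chain is: 4th-order Butterworth band-pass (20-450 Hz) to suppress
baseline drift and electrode-movement artefacts, full-wave rectification
followed by a 10 Hz low-pass for the linear envelope, and division by a
per-channel Maximum Voluntary Contraction reference so that amplitudes are
comparable across subjects.  Filtering is zero-phase (forward-backward) by
default, appropriate for offline analysis; causal filtering is available for
parity with a real-time system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import CHANNEL_NAMES, Recording, ValidationError, logger

#: Which MVC calibration segment references each channel.
MVC_SEGMENT_FOR_CHANNEL = {
    "GL_left": "mvc_gl", "GL_right": "mvc_gl",
    "TA_left": "mvc_ta", "TA_right": "mvc_ta",
}


def _apply_sos(sos: np.ndarray, x: np.ndarray, phase: str) -> np.ndarray:
    if phase == "zero_phase":
        return sps.sosfiltfilt(sos, x)
    if phase == "causal":
        return sps.sosfilt(sos, x)
    raise ValidationError(f"phase must be 'zero_phase' or 'causal', got {phase!r}")


def bandpass_filter(rec: Recording, low: float = 20.0, high: float = 450.0,
                    order: int = 4, phase: str = "zero_phase") -> Recording:
    """Band-pass every channel; returns a recording of kind ``"filtered"``."""
    if high >= rec.sampling_rate / 2:
        raise ValidationError(
            f"upper edge {high} Hz >= Nyquist {rec.sampling_rate / 2} Hz")
    if not (0 < low < high):
        raise ValidationError("need 0 < low < high")
    for name, x in rec.channels.items():
        if not np.all(np.isfinite(x)):
            raise ValidationError(f"channel {name} contains non-finite samples")
    sos = sps.butter(order, [low, high], btype="bandpass",
                     fs=rec.sampling_rate, output="sos")
    out = {name: _apply_sos(sos, x, phase) for name, x in rec.channels.items()}
    return rec.replace_channels(out, kind="filtered")


def compute_envelope(filt: Recording, cutoff: float = 10.0, order: int = 4,
                     phase: str = "zero_phase") -> Recording:
    """Linear envelope: full-wave rectification then low-pass Butterworth.

    Small negative residues of the zero-phase low-pass are clipped to 0.
    """
    if cutoff >= filt.sampling_rate / 2:
        raise ValidationError(f"cutoff {cutoff} Hz >= Nyquist")
    sos = sps.butter(order, cutoff, btype="lowpass",
                     fs=filt.sampling_rate, output="sos")
    out = {
        name: np.clip(_apply_sos(sos, np.abs(x), phase), 0.0, None)
        for name, x in filt.channels.items()
    }
    return filt.replace_channels(out, kind="envelope")


@dataclass(frozen=True)
class MvcReference:
    """Per-channel MVC amplitude reference in mV.

    The reference is the mean envelope over the channel's matching MVC
    calibration segment, optionally minus the rest-baseline mean (removing
    sensor offset).  Must be strictly positive for every channel.
    """

    refs_mv: dict[str, float]

    def __post_init__(self) -> None:
        for name in CHANNEL_NAMES:
            if name not in self.refs_mv:
                raise ValidationError(f"MVC reference missing channel {name}")
            if self.refs_mv[name] <= 0:
                raise ValidationError(
                    f"MVC reference for {name} is {self.refs_mv[name]:.4g} <= 0; "
                    "calibration unusable (MVC does not exceed baseline)")


def compute_mvc(env: Recording, baseline_subtract: bool = True) -> MvcReference:
    """Derive the per-channel MVC reference from an (un-normalised) envelope.

    GL channels are referenced to the ``mvc_gl`` segment, TA channels to
    ``mvc_ta``.  Requires the ``baseline`` segment when subtracting.
    """
    if env.normalized:
        raise ValidationError("envelope is already normalized")
    needed = {"mvc_gl", "mvc_ta"} | ({"baseline"} if baseline_subtract else set())
    missing = needed - set(env.segments)
    if missing:
        raise ValidationError(f"recording {env.subject_id} lacks segments "
                              f"{sorted(missing)} needed for MVC calibration")
    refs = {}
    for name, x in env.channels.items():
        mvc_mean = float(np.mean(x[env.segment_slice(MVC_SEGMENT_FOR_CHANNEL[name])]))
        base = (float(np.mean(x[env.segment_slice("baseline")]))
                if baseline_subtract else 0.0)
        refs[name] = mvc_mean - base
    return MvcReference(refs_mv=refs)


def normalize(env: Recording, mvc: MvcReference) -> Recording:
    """Divide each channel by its MVC reference; output is dimensionless."""
    out = {name: x / mvc.refs_mv[name] for name, x in env.channels.items()}
    return env.replace_channels(out, normalized=True)


def scale_by_mvc(filt: Recording, mvc: MvcReference) -> Recording:
    """MVC-scale a band-passed (signed) signal for spectral/count features."""
    out = {name: x / mvc.refs_mv[name] for name, x in filt.channels.items()}
    return filt.replace_channels(out, normalized=True)


def preprocess(rec: Recording, band_low: float = 20.0, band_high: float = 450.0,
               order: int = 4, envelope_cutoff: float = 10.0,
               phase: str = "zero_phase", baseline_subtract: bool = True,
               ) -> tuple[Recording, Recording, MvcReference]:
    """Full chain: band-pass -> envelope -> MVC calibration -> normalisation.

    Returns ``(filtered_scaled, envelope_normalized, mvc)`` where both signal
    products are in MVC-fraction units.
    """
    filt = bandpass_filter(rec, band_low, band_high, order, phase)
    env = compute_envelope(filt, envelope_cutoff, order, phase)
    mvc = compute_mvc(env, baseline_subtract=baseline_subtract)
    logger.debug("subject %s MVC refs: %s", rec.subject_id,
                 {k: round(v, 4) for k, v in mvc.refs_mv.items()})
    return scale_by_mvc(filt, mvc), normalize(env, mvc), mvc
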