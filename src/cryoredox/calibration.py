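"""Dark-current, flat-field and gain correction of raw fluorescence slice stacks.

Raw cryo-imager frames mix the tissue autofluorescence signal with an
additive sensor dark level, a multiplicative illumination (vignetting)
pattern, and a per-session gain that drifts day to day.  The correction
model applied per slice is

    corrected = clip0(raw - dark) / flat / gain

where ``flat`` is the illumination pattern normalized to unit mean and
``gain`` an explicit per-session scalar (default 1).  Negative values
after dark subtraction are clipped to zero: fluorescence counts are
physically nonnegative and downstream voxel ratios require it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Channel",
    "ImageStack",
    "CalibrationFrames",
    "CalibrationError",
    "normalize_flat",
    "calibrate_stack",
]

#: valid fluorescence channel names
CHANNELS = ("NADH", "FAD")
Channel = str


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs (shape/channel mismatch, bad flat)."""


@dataclass
class ImageStack:
    """One channel's ordered slice images plus acquisition geometry.

    Slices are stored as a single 3D float array with shape
    ``(n_slices, ny, nx)`` in acquisition (z) order.  Counts are
    nonnegative; pixel size and slice thickness are in micrometres.
    """

    channel: Channel
    data: np.ndarray
    pixel_size_um: float = 1.0
    slice_thickness_um: float = 100.0
    animal_id: str = ""
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack data must be 3D (n_slices, ny, nx), got ndim={self.data.ndim}"
            )
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if np.any(self.data < 0):
            raise ValueError("stack contains negative counts")
        if self.pixel_size_um <= 0 or self.slice_thickness_um <= 0:
            raise ValueError("pixel size and slice thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class CalibrationFrames:
    """Per-channel dark frames, normalized flat-field frames and session gains.

    ``dark[c]`` holds sensor counts with the lamp off; ``flat[c]`` the
    unit-mean illumination pattern; ``gain[c]`` a positive per-session
    intensity scalar.  Any channel may be omitted, in which case identity
    correction (dark 0, flat 1, gain 1) is used for it.
    """

    dark: dict[Channel, np.ndarray] = field(default_factory=dict)
    flat: dict[Channel, np.ndarray] = field(default_factory=dict)
    gain: dict[Channel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, g in self.gain.items():
            if g <= 0:
                raise CalibrationError(f"gain for channel {c} must be positive, got {g}")


def normalize_flat(raw_flat: np.ndarray) -> np.ndarray:
    """Normalize a dark-subtracted flat-field frame to unit mean.

    Parameters
    ----------
    raw_flat
        2D frame of the illumination pattern, already dark-subtracted.
        Every pixel must be strictly positive, otherwise the frame cannot
        act as a multiplicative correction.

    Returns
    -------
    2D array with mean exactly 1 (to floating point).
    """
    raw_flat = np.asarray(raw_flat, dtype=np.float64)
    if raw_flat.ndim != 2:
        raise CalibrationError("flat frame must be 2D")
    n_bad = int(np.count_nonzero(raw_flat <= 0))
    if n_bad:
        raise CalibrationError(
            f"flat frame has {n_bad} nonpositive pixel(s) after dark subtraction; "
            "cannot be used as a multiplicative correction"
        )
    return raw_flat / raw_flat.mean()


def identity_frames(frame_shape: tuple[int, int]) -> CalibrationFrames:
    """Calibration frames that leave a stack unchanged (dark 0, flat 1, gain 1)."""
    ones = np.ones(frame_shape)
    zeros = np.zeros(frame_shape)
    return CalibrationFrames(
        dark={c: zeros.copy() for c in CHANNELS},
        flat={c: ones.copy() for c in CHANNELS},
        gain={c: 1.0 for c in CHANNELS},
    )


def calibrate_stack(stack: ImageStack, frames: CalibrationFrames | None) -> ImageStack:
    """Apply dark / flat / gain correction to every slice of a raw stack.

    Each slice becomes ``clip0(raw - dark) / flat / gain`` for the stack's
    channel.  Metadata is preserved and the result is marked calibrated;
    calibrating an already-calibrated stack raises rather than silently
    correcting twice.  ``frames=None`` applies identity calibration with a
    warning, for deliberately uncorrected runs.
    """
    if stack.calibrated:
        raise CalibrationError(
            f"stack for animal {stack.animal_id!r} channel {stack.channel} "
            "is already calibrated; refusing to calibrate twice"
        )
    if frames is None:
        warnings.warn(
            "no calibration frames supplied; proceeding with identity calibration",
            stacklevel=2,
        )
        return replace(stack, data=stack.data.copy(), calibrated=True)

    c = stack.channel
    shape = stack.frame_shape
    dark = np.asarray(frames.dark.get(c, np.zeros(shape)), dtype=np.float64)
    flat = np.asarray(frames.flat.get(c, np.ones(shape)), dtype=np.float64)
    gain = float(frames.gain.get(c, 1.0))
    if dark.shape != shape or flat.shape != shape:
        raise CalibrationError(
            f"calibration frame shape {dark.shape if dark.shape != shape else flat.shape} "
            f"does not match stack frame shape {shape}"
        )
    if np.any(flat <= 0):
        raise CalibrationError("flat frame must be strictly positive")

    corrected = np.clip(stack.data - dark[None, :, :], 0.0, None)
    corrected /= flat[None, :, :]
    corrected /= gain
    return replace(stack, data=corrected, calibrated=True)
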