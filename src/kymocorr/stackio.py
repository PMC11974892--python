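"""Calibrated movie I/O and the intensity-preprocessing chain.

Movies are T x C x Y x X arrays with physical calibration (pixel size in
micrometres, frame interval in seconds).  On disk they are multi-page TIFFs
with channels interleaved per frame (page order: frame 0 channel 0, frame 0
channel 1, frame 1 channel 0, ...) and a JSON sidecar carrying the
calibration, so the format round-trips losslessly for 16-bit data.

The preprocessing chain runs in a fixed order:

1. ``subtract_background`` — per-frame, per-channel median of the cell-free
   region is removed (camera offset and stray light).
2. ``correct_bleaching`` — a single exponential is fitted to the frame-summed
   in-cell intensity of each channel and divided out.
3. ``normalize_total_fluorescence`` — each frame is scaled so the summed
   in-cell intensity of each channel is constant over time, compensating
   residual acquisition drift and focus changes.
4. ``match_channel_means`` — the dimmer channel is multiplied by one global
   scalar so both channels share the same in-cell mean, putting probe and
   reference intensities on a common scale before correlation.

Applying the chain a second time is a no-op to numerical tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "MovieStack",
    "CellMask",
    "read_movie",
    "write_movie",
    "subtract_background",
    "correct_bleaching",
    "normalize_total_fluorescence",
    "match_channel_means",
    "ratio_image",
    "preprocess",
]

RATIO_UNDEFINED = np.nan  # sentinel for pixels where the ratio is not defined


@dataclass
class MovieStack:
    """A calibrated fluorescence time-lapse movie.

    Attributes
    ----------
    intensities : ndarray, shape (T, C, Y, X)
        Non-negative intensities.
    pixel_size_um : float
    frame_interval_s : float
    channel_names : tuple of str
    """

    intensities: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: tuple = ("reference", "probe")

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"expected a T x C x Y x X array, got shape {arr.shape}")
        if arr.shape[1] < 1 or min(arr.shape) < 1:
            raise ValueError(f"all dimensions must be positive, got {arr.shape}")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")
        self.intensities = arr
        self.channel_names = tuple(self.channel_names)

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape(self):
        return self.intensities.shape

    def channel(self, name_or_index) -> np.ndarray:
        """Return the (T, Y, X) sub-stack for one channel."""
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return self.intensities[:, idx]

    def with_intensities(self, arr: np.ndarray) -> "MovieStack":
        return replace(self, intensities=arr)


@dataclass
class CellMask:
    """Per-frame binary masks marking the cell footprint."""

    masks: np.ndarray  # (T, Y, X) boolean
    method: str = "manual"
    blur_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim != 3:
            raise ValueError(f"expected (T, Y, X) masks, got shape {m.shape}")
        self.masks = m.astype(bool)

    @property
    def usable(self) -> np.ndarray:
        """Boolean per frame: mask has at least one foreground pixel."""
        return self.masks.any(axis=(1, 2))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_movie(stack: MovieStack, path) -> None:
    """Write a stack as multi-page TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    T, C, Y, X = stack.shape
    pages = stack.intensities.reshape(T * C, Y, X)
    if np.any(pages < 0) or np.any(pages > np.iinfo(np.uint16).max):
        raise ValueError("intensities out of range for 16-bit storage")
    tifffile.imwrite(path, np.round(pages).astype(np.uint16), photometric="minisblack")
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "channel_names": list(stack.channel_names),
        "n_frames": T,
        "n_channels": C,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_movie(path, pixel_size_um=None, frame_interval_s=None, channel_names=None) -> MovieStack:
    """Read a multi-page TIFF movie; calibration from sidecar or arguments."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar_path = path.with_suffix(".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    pixel_size_um = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    frame_interval_s = (
        frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    )
    channel_names = channel_names if channel_names is not None else meta.get("channel_names")
    for name, value in (
        ("pixel_size_um", pixel_size_um),
        ("frame_interval_s", frame_interval_s),
    ):
        if value is None:
            raise ValueError(
                f"missing calibration field {name!r}: provide it as an argument "
                f"or in the sidecar {sidecar_path.name}"
            )
    n_pages = pages.shape[0]
    C = len(channel_names) if channel_names else meta.get("n_channels", 1)
    if channel_names is None:
        channel_names = [f"channel_{i}" for i in range(C)]
    if n_pages % C != 0:
        raise ValueError(f"page count {n_pages} is not a multiple of {C} channels")
    T = n_pages // C
    data = pages.reshape(T, C, *pages.shape[1:]).astype(float)
    return MovieStack(data, float(pixel_size_um), float(frame_interval_s), tuple(channel_names))


# ---------------------------------------------------------------------------
# Preprocessing chain
# ---------------------------------------------------------------------------

def _check_mask(stack: MovieStack, mask: CellMask) -> np.ndarray:
    m = mask.masks
    if m.shape[0] != stack.n_frames or m.shape[1:] != stack.shape[2:]:
        raise ValueError(
            f"mask shape {m.shape} does not match stack frames {stack.shape}"
        )
    return m


def subtract_background(stack: MovieStack, mask: CellMask) -> MovieStack:
    """Subtract the per-frame, per-channel median of the cell-free region.

    The background region is the complement of the cell mask; the median is
    robust to debris and stray bright pixels.  Results are floored at zero.
    """
    m = _check_mask(stack, mask)
    out = stack.intensities.copy()
    for t in range(stack.n_frames):
        bg_region = ~m[t]
        if not bg_region.any():
            raise ValueError(f"frame {t}: no cell-free background region in mask")
        for c in range(stack.n_channels):
            out[t, c] -= np.median(out[t, c][bg_region])
    np.maximum(out, 0.0, out=out)
    return stack.with_intensities(out)


def correct_bleaching(stack: MovieStack, mask: CellMask | None = None):
    """Fit and divide out a mono-exponential photobleaching decay per channel.

    The model ``I_sum(t) = I0 * exp(-k t)`` is fitted by least squares on the
    log-transformed frame-summed in-cell intensity.  Each frame is divided by
    its fitted decay factor, so corrected frame sums carry no exponential
    trend.

    Returns ``(corrected_stack, rates_per_s)``.
    """
    if stack.n_frames < 5:
        raise ValueError("bleach correction needs at least 5 frames")
    if mask is not None:
        m = _check_mask(stack, mask)
    else:
        m = np.ones((stack.n_frames, *stack.shape[2:]), dtype=bool)
    t_s = np.arange(stack.n_frames) * stack.frame_interval_s
    out = stack.intensities.copy()
    rates = np.empty(stack.n_channels)
    for c in range(stack.n_channels):
        sums = np.array(
            [stack.intensities[t, c][m[t]].sum() for t in range(stack.n_frames)]
        )
        if np.any(sums <= 0):
            raise ValueError(f"channel {c}: non-positive in-cell frame sums")
        slope, intercept = np.polyfit(t_s, np.log(sums), 1)
        k = -slope
        rates[c] = k
        out[:, c] /= np.exp(-k * t_s)[:, None, None]
    return stack.with_intensities(out), rates


def normalize_total_fluorescence(stack: MovieStack, mask: CellMask) -> MovieStack:
    """Equalize the summed in-cell intensity of each channel across frames.

    Each frame of each channel is divided by that frame's in-cell total, then
    rescaled by the channel's time-averaged total so values stay
    intensity-like.  After this step the per-frame in-cell totals are equal
    over time for every channel.
    """
    m = _check_mask(stack, mask)
    if not m.any():
        raise ValueError("empty mask: no in-cell pixels")
    out = stack.intensities.copy()
    for c in range(stack.n_channels):
        totals = np.array(
            [stack.intensities[t, c][m[t]].sum() for t in range(stack.n_frames)]
        )
        if np.any(totals <= 0):
            raise ValueError(f"channel {c}: zero in-cell total fluorescence")
        out[:, c] *= (totals.mean() / totals)[:, None, None]
    return stack.with_intensities(out)


def match_channel_means(stack: MovieStack, mask: CellMask):
    """Scale the dimmer channel so both channels share the in-cell mean.

    One global scalar is applied over the whole movie; returns
    ``(matched_stack, factor)`` where ``factor`` is the multiplier applied to
    the lesser-mean channel.
    """
    if stack.n_channels != 2:
        raise ValueError("channel mean matching requires exactly 2 channels")
    m = _check_mask(stack, mask)
    means = np.array(
        [stack.intensities[:, c][m].mean() for c in range(2)]
    )
    if np.any(means <= 0):
        raise ValueError("zero in-cell mean intensity")
    out = stack.intensities.copy()
    dim = int(np.argmin(means))
    factor = means[1 - dim] / means[dim]
    out[:, dim] *= factor
    return stack.with_intensities(out), factor


def preprocess(stack: MovieStack, mask: CellMask):
    """Run the full chain: background -> bleach -> total-fluorescence -> mean-match.

    Returns ``(stack, info)`` with the fitted bleach rates and mean-match
    factor in ``info``.
    """
    out = subtract_background(stack, mask)
    out, rates = correct_bleaching(out, mask)
    out = normalize_total_fluorescence(out, mask)
    factor = 1.0
    if out.n_channels == 2:
        out, factor = match_channel_means(out, mask)
    return out, {"bleach_rates_per_s": rates, "mean_match_factor": factor}


# ---------------------------------------------------------------------------
# Ratio images
# ---------------------------------------------------------------------------

def ratio_image(
    probe_frame: np.ndarray,
    reference_frame: np.ndarray,
    mask: np.ndarray,
    floor: float | None = None,
) -> np.ndarray:
    """Pixelwise probe / reference ratio inside the mask.

    Pixels outside the mask, or whose reference intensity is at or below
    ``floor``, carry NaN rather than infinities.  ``floor`` defaults to the
    1st percentile of the in-mask reference intensity (but at least a small
    positive epsilon).
    """
    probe_frame = np.asarray(probe_frame, dtype=float)
    reference_frame = np.asarray(reference_frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if probe_frame.shape != reference_frame.shape or probe_frame.shape != mask.shape:
        raise ValueError("probe, reference and mask shapes must match")
    if floor is None:
        in_ref = reference_frame[mask]
        floor = max(np.percentile(in_ref, 1.0) if in_ref.size else 0.0, 1e-9)
    valid = mask & (reference_frame >= floor) & (reference_frame > 0)
    out = np.full(probe_frame.shape, RATIO_UNDEFINED)
    out[valid] = probe_frame[valid] / reference_frame[valid]
    return out
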