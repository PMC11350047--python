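"""Image-based division-ratio quantification for multi-channel droplet movies.

Each fluorescence channel labels one droplet component (A, B, C).  A frame is
binarized (automatic Otsu threshold by default, manual override available)
and the division ratio of a component pair is computed from the two masks::

    r_div = 1 - |X ∩ Y| / min(|X|, |Y|)

which is 0 when the two components perfectly colocalize (one mixed droplet)
and 1 when their masks are disjoint (fully divided droplets).  Per-frame
values assemble into a :class:`~dropdiv.division.DivisionTrace`, which feeds
the same division-time / pathway machinery as the simulated traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import tifffile
from skimage.filters import median as _median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import disk as _disk_footprint

from .division import DivisionTrace

__all__ = [
    "ImageStack",
    "DivisionRatioEstimate",
    "binarize",
    "division_ratio_frames",
    "trace_from_stack",
]


@dataclass
class ImageStack:
    """Time-ordered multi-channel image data.

    data            : array (n_frames, n_channels, height, width)
    channels        : component label per channel, e.g. ("A", "B")
    frame_interval  : time between frames (arbitrary unit, default 1 frame)
    pixel_size      : µm per pixel (metadata only)
    """

    data: np.ndarray
    channels: Tuple[str, ...]
    frame_interval: float = 1.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be (frames, channels, y, x)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel labels do not match data")
        if self.data.shape[0] < 1:
            raise ValueError("stack needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; have {self.channels}"
            ) from None
        return self.data[:, i]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def save_tiff(self, path: str) -> None:
        """Write as a multi-page TIFF, frame-major then channel."""
        tifffile.imwrite(path, self.data, metadata={"axes": "TCYX"})

    @classmethod
    def from_tiff(
        cls,
        path: str,
        channels: Sequence[str],
        frame_interval: float = 1.0,
        pixel_size: float = 1.0,
        layout: str = "TCYX",
    ) -> "ImageStack":
        arr = tifffile.imread(path)
        if arr.ndim == 3:  # single channel stored as (T, Y, X)
            arr = arr[:, None]
        if layout == "CTYX":
            arr = np.swapaxes(arr, 0, 1)
        elif layout != "TCYX":
            raise ValueError(f"unknown layout {layout!r}")
        return cls(arr, tuple(channels), frame_interval, pixel_size)


@dataclass
class DivisionRatioEstimate:
    """Per-frame division ratios plus the masks and thresholds used."""

    r_div: np.ndarray
    thresholds: Dict[str, np.ndarray]
    masks: Optional[Dict[str, np.ndarray]] = None


def binarize(
    frame: np.ndarray,
    method: str = "otsu",
    threshold: Optional[float] = None,
    median_radius: int = 0,
) -> np.ndarray:
    """Threshold a single-channel frame into a boolean foreground mask.

    ``method='otsu'`` picks an automatic global threshold (invariant to a
    constant intensity offset); ``method='manual'`` uses ``threshold``.
    ``median_radius > 0`` applies a median pre-filter of that pixel radius.
    A blank (constant) frame yields an empty mask with a warning.
    """
    img = np.asarray(frame)
    if img.ndim != 2:
        raise ValueError("binarize expects a single-channel 2-D frame")
    if median_radius > 0:
        img = _median_filter(img, footprint=_disk_footprint(median_radius))
    if method == "manual":
        if threshold is None:
            raise ValueError("manual method requires a threshold")
        thr = threshold
    elif method == "otsu":
        if img.max() == img.min():
            warnings.warn("blank frame: no foreground found", stacklevel=2)
            return np.zeros(img.shape, dtype=bool)
        thr = threshold_otsu(img)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return img > thr


def division_ratio_frames(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """Overlap-based division ratio of two component masks.

    ``1 - |X ∩ Y| / min(|X|, |Y|)``: 0 for identical masks, 1 for disjoint
    masks; symmetric in its arguments.  Raises when both masks are empty
    (no droplet visible — the ratio is undefined).
    """
    mx = np.asarray(mask_x, dtype=bool)
    my = np.asarray(mask_y, dtype=bool)
    if mx.shape != my.shape:
        raise ValueError("masks must share a shape")
    ax, ay = int(mx.sum()), int(my.sum())
    if ax == 0 and ay == 0:
        raise ValueError("both masks empty: division ratio undefined")
    smaller = min(a for a in (ax, ay) if a > 0)
    inter = int((mx & my).sum())
    return 1.0 - inter / smaller


def trace_from_stack(
    stack: ImageStack,
    pairing: Mapping[str, Tuple[str, str]] | Tuple[str, str] = ("A", "B"),
    method: str = "otsu",
    threshold: Optional[float] = None,
    median_radius: int = 0,
) -> Dict[str, DivisionTrace]:
    """Division-ratio traces from an image stack.

    ``pairing`` maps a component label to the two channels compared for it,
    e.g. ``{"B": ("A", "B"), "C": ("A", "C")}`` for a ternary droplet; a
    plain 2-tuple is shorthand for a single anonymous pair.  Frames where
    the ratio is undefined (both masks empty) propagate the previous value.
    """
    if isinstance(pairing, tuple):
        pairing = {pairing[1]: pairing}
    traces: Dict[str, DivisionTrace] = {}
    for component, (ca, cb) in pairing.items():
        fa = stack.channel(ca)
        fb = stack.channel(cb)
        vals = np.zeros(stack.n_frames)
        prev = 0.0
        for f in range(stack.n_frames):
            ma = binarize(fa[f], method, threshold, median_radius)
            mb = binarize(fb[f], method, threshold, median_radius)
            try:
                prev = division_ratio_frames(ma, mb)
            except ValueError:
                pass  # keep previous value for blank frames
            vals[f] = prev
        traces[component] = DivisionTrace(
            time=stack.times, r_div=np.clip(vals, 0.0, 1.0), component=component
        )
    return traces
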