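"""Morphological mask algebra separating membrane, cytoplasm and nucleus.

The object mask is an Otsu segmentation of the brightfield channel; the
cytoplasm is the object shrunk by *adaptive erosion* to a percentage of its
area (the percent-retained coefficient, default 70); the plasma-membrane ring
is the tight object minus the cytoplasm; the nucleus, when a nuclear channel
exists, is that channel's object eroded by a fixed number of pixels.
8-connected structuring elements and components are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .records import CellRecord

#: 3x3 square structuring element => 8-connected morphology.
_SELEM = np.ones((3, 3), dtype=bool)


class EmptyMaskError(ValueError):
    """Raised when an operation requires a nonempty mask but got none."""


@dataclass
class Mask:
    """A binary pixel mask with a provenance label."""

    pixels: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def __bool__(self) -> bool:
        return bool(self.pixels.any())


@dataclass
class MaskSet:
    """Named masks over one cell's pixel grid.

    Invariants: ``membrane = object_tight \\ cytoplasm`` exactly (so membrane
    and cytoplasm partition the tight object), and ``nucleus ⊆ object`` when
    present.
    """

    object: Mask
    object_tight: Mask
    cytoplasm: Mask
    membrane: Mask
    nucleus: Mask | None = None


def modal_background(image: np.ndarray, exclude: np.ndarray | None = None, bins: int = 256) -> float:
    """Histogram-mode intensity outside ``exclude`` — robust to puncta."""
    vals = np.asarray(image, dtype=float)
    if exclude is not None:
        vals = vals[~np.asarray(exclude, dtype=bool)]
    else:
        vals = vals.ravel()
    if vals.size == 0:
        return 0.0
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return lo
    counts, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def object_mask(record: CellRecord, channel: int = 1, tight: bool = False) -> Mask:
    """Segment the cell on one channel.

    Otsu threshold on the absolute deviation from the modal background, holes
    filled, largest 8-connected component kept.  ``tight=True`` additionally
    closes and erodes by 1 px for a snugger boundary (constrained to stay
    inside the default mask).
    """
    from skimage.filters import threshold_otsu

    img = record.channels[channel]
    if float(img.max()) == float(img.min()):
        raise EmptyMaskError(f"channel {channel}: blank image (zero dynamic range)")
    diff = np.abs(img - modal_background(img))
    thr = threshold_otsu(diff)
    binary = diff > thr
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary, structure=_SELEM)
    if n == 0:
        raise EmptyMaskError(f"channel {channel}: no object found")
    largest = 1 + int(np.argmax(ndimage.sum_labels(binary, labels, index=range(1, n + 1))))
    mask = labels == largest
    if tight:
        snug = ndimage.binary_erosion(ndimage.binary_closing(mask, _SELEM), _SELEM) & mask
        if not snug.any():
            raise EmptyMaskError(f"channel {channel}: tight mask vanished")
        return Mask(snug, "object_tight")
    return Mask(mask, "object")


def adaptive_erode(mask: Mask, coefficient_pct: float) -> Mask:
    """Shrink a mask to roughly ``coefficient_pct`` percent of its area.

    Repeated 1-px erosions, stopping at the first iterate whose area drops to
    or below the target fraction; if erosion would empty the mask first, the
    last nonempty iterate is returned.  A coefficient of 100 is the identity.
    """
    if not 0 < coefficient_pct <= 100:
        raise ValueError(f"coefficient_pct={coefficient_pct} not in (0, 100]")
    if not mask:
        raise EmptyMaskError("adaptive_erode: empty input mask")
    if coefficient_pct == 100:
        return Mask(mask.pixels.copy(), "cytoplasm")
    target = coefficient_pct / 100.0 * mask.area_px
    current = mask.pixels
    while True:
        nxt = ndimage.binary_erosion(current, _SELEM)
        if not nxt.any():
            return Mask(current, "cytoplasm")
        current = nxt
        if current.sum() <= target:
            return Mask(current, "cytoplasm")


def erode_mask(mask: Mask, n_px: int) -> Mask:
    """``n_px`` successive 1-px erosions; may return an empty mask."""
    if n_px < 0:
        raise ValueError("n_px must be >= 0")
    out = mask.pixels
    if n_px:
        out = ndimage.binary_erosion(out, _SELEM, iterations=n_px)
    return Mask(out, mask.source)


def build_maskset(
    record: CellRecord,
    object_channel: int = 1,
    coefficient_pct: float = 70,
    nucleus_channel: int | None = None,
    nucleus_erode_px: int = 3,
) -> MaskSet:
    """Construct the full mask partition for one cell.

    cytoplasm = adaptive erosion of the default object mask (intersected with
    the tight object so the partition is exact); membrane = tight object and
    not cytoplasm; nucleus = n-px-eroded object mask on the nuclear channel.
    """
    obj = object_mask(record, object_channel, tight=False)
    tight = object_mask(record, object_channel, tight=True)
    cyto_px = adaptive_erode(obj, coefficient_pct).pixels & tight.pixels
    cyto = Mask(cyto_px, "cytoplasm")
    membrane = Mask(tight.pixels & ~cyto_px, "membrane")
    nucleus = None
    if nucleus_channel is not None:
        nuc = erode_mask(object_mask(record, nucleus_channel), nucleus_erode_px)
        nucleus = Mask(nuc.pixels & obj.pixels, "nucleus")
    return MaskSet(object=obj, object_tight=tight, cytoplasm=cyto, membrane=membrane, nucleus=nucleus)


def export_overlay(maskset: MaskSet, path) -> None:
    """8-bit TIFF overlay for visual QC (object=32, cytoplasm=+64, membrane=+128)."""
    import tifffile

    img = np.zeros(maskset.object.pixels.shape, dtype=np.uint8)
    img[maskset.object.pixels] += 32
    img[maskset.cytoplasm.pixels] += 64
    img[maskset.membrane.pixels] += 128
    if maskset.nucleus is not None:
        img[maskset.nucleus.pixels] += 16
    tifffile.imwrite(path, img)
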