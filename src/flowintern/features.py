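"""Per-cell scalar features.

Intensity statistics, morphometrics, a gradient-based focus metric, GLCM
(Haralick) entropy of the in-mask signal distribution, the internalization
coefficient, and two colocalization scores (bright-detail similarity and 1-D
profile correlation).

The internalization coefficient is the base-10 log of the ratio of *mean*
background-subtracted intensity in an interior mask (cytoplasm or nucleus) to
the mean over the whole cell; positive values mean per-pixel signal
concentrates inside.  GLCM entropy is −Σ p(i,j)·log2 p(i,j) over the
symmetrized co-occurrence matrix of the 8-bit-quantized in-mask image; high
entropy means a spatially uniform (non-punctate) distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .masks import EmptyMaskError, Mask, MaskSet, build_maskset, modal_background
from .records import CellRecord


@dataclass
class GlcmParams:
    """Co-occurrence matrix settings (Haralick convention)."""

    levels: int = 256
    granularity_um: float = 1.0
    directions: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")

    def offset_px(self, pixel_size_um: float) -> int:
        return max(1, round(self.granularity_um / pixel_size_um))


def intensity_features(
    record: CellRecord,
    mask: Mask,
    channel: int,
    background_mask: Mask | None = None,
) -> dict[str, float]:
    """Background-subtracted total / mean / max over a mask.

    Background is the modal intensity outside ``background_mask`` (the object
    mask in the pipeline; defaults to ``mask``); negative residuals clip to 0.
    """
    if not mask:
        raise EmptyMaskError("intensity_features: empty mask")
    img = record.channels[channel]
    bg = modal_background(img, exclude=(background_mask or mask).pixels)
    sub = np.clip(img - bg, 0.0, None)
    vals = sub[mask.pixels]
    return {"total": float(vals.sum()), "mean": float(vals.mean()), "max_pixel": float(vals.max())}


def morphometrics(mask: Mask, pixel_size_um: float = 1.0, circularity_cap: float = 100.0) -> dict[str, float]:
    """Area, perimeter, circularity and aspect ratio of a mask.

    Perimeter is the marching-squares contour length; circularity is the mean
    over SD of boundary-pixel distances to the centroid (large = round, capped
    when the SD vanishes); aspect ratio is minor/major axis of the
    second-moment ellipse, in (0, 1].
    """
    if not mask:
        raise EmptyMaskError("morphometrics: empty mask")
    px = mask.pixels
    area = float(px.sum()) * pixel_size_um**2

    contours = measure.find_contours(px.astype(float), 0.5)
    perimeter = sum(
        float(np.sum(np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1])))) for c in contours
    ) * pixel_size_um

    rr, cc = np.nonzero(px)
    centroid = (rr.mean(), cc.mean())
    boundary = px & ~ndimage.binary_erosion(px, np.ones((3, 3), dtype=bool))
    br, bc = np.nonzero(boundary)
    d = np.hypot(br - centroid[0], bc - centroid[1])
    sd = float(d.std())
    circularity = float(circularity_cap) if sd == 0 else min(float(d.mean()) / sd, circularity_cap)

    props = measure.regionprops(px.astype(np.uint8))[0]
    major, minor = props.axis_major_length, props.axis_minor_length
    aspect = 1.0 if major == 0 else max(min(minor / major, 1.0), 1e-12)
    return {"area_um2": area, "perimeter_um": perimeter, "circularity": circularity, "aspect_ratio": aspect}


def gradient_rms(record: CellRecord, mask: Mask, channel: int = 1) -> float:
    """Focus metric: RMS central-difference gradient magnitude over the mask,
    normalized by the mean in-mask intensity, ×100 (dimensionless)."""
    if not mask:
        raise EmptyMaskError("gradient_rms: empty mask")
    img = record.channels[channel]
    gy, gx = np.gradient(img)
    mag2 = (gy**2 + gx**2)[mask.pixels]
    rms = math.sqrt(float(mag2.mean()))
    return 100.0 * rms / (float(img[mask.pixels].mean()) + 1e-9)


def glcm_entropy(
    record: CellRecord,
    mask: Mask,
    channel: int,
    params: GlcmParams | None = None,
) -> float:
    """GLCM entropy (bits) of the in-mask image.

    In-mask intensities are quantized to ``levels`` gray levels by linear
    min–max scaling (so the value is invariant to affine intensity rescaling);
    co-occurrence counts are accumulated over pixel pairs whose endpoints both
    lie in the mask, at the granularity-derived offset, over the four standard
    directions, symmetrized, and normalized to probabilities.  Returns NaN
    when no valid pair exists (undefined, not zero).
    """
    params = params or GlcmParams()
    px = mask.pixels
    if px.sum() < 2:
        return float("nan")
    img = record.channels[channel]
    vals = img[px]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        quant = np.zeros(img.shape, dtype=np.int64)
    else:
        quant = np.clip(((img - lo) / (hi - lo) * params.levels).astype(np.int64), 0, params.levels - 1)

    dist = params.offset_px(record.pixel_size_um)
    N = params.levels
    counts = np.zeros(N * N, dtype=np.float64)
    H, W = img.shape
    for dr, dc in params.directions:
        dr, dc = dr * dist, dc * dist
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a_ok = px[r0:r1, c0:c1]
        b_ok = px[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        both = a_ok & b_ok
        if not both.any():
            continue
        a = quant[r0:r1, c0:c1][both]
        b = quant[r0 + dr : r1 + dr, c0 + dc : c1 + dc][both]
        np.add.at(counts, a * N + b, 1.0)
        if params.symmetric:
            np.add.at(counts, b * N + a, 1.0)
    total = counts.sum()
    if total == 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def internalization_coefficient(
    record: CellRecord,
    target_mask: Mask,
    cell_mask: Mask,
    channel: int,
    clamp: float = 6.0,
) -> float:
    """log10(mean intensity in target mask / mean over whole cell), clamped to ±6.

    Positive values flag cells whose signal concentrates in the target
    (cytoplasm or nucleus); returns NaN when the whole cell carries no signal.
    """
    if not target_mask or not cell_mask:
        raise EmptyMaskError("internalization_coefficient: empty mask")
    if (target_mask.pixels & ~cell_mask.pixels).any():
        raise ValueError("target mask must be contained in the cell mask")
    img = record.channels[channel]
    bg = modal_background(img, exclude=cell_mask.pixels)
    sub = np.clip(img - bg, 0.0, None)
    mean_cell = float(sub[cell_mask.pixels].mean())
    if mean_cell <= 0:
        return float("nan")
    mean_target = float(sub[target_mask.pixels].mean())
    if mean_target <= 0:
        return -clamp
    return float(np.clip(math.log10(mean_target / mean_cell), -clamp, clamp))


def bright_detail_similarity(
    record: CellRecord,
    channel_a: int,
    channel_b: int,
    mask: Mask,
    radius_px: int = 3,
) -> float:
    """Colocalization of small bright spots of two channels within a mask.

    Each channel is white-top-hat filtered with a disk of ``radius_px`` to
    isolate bright details; the Pearson correlation of the two detail images
    over the mask is clamped to [0, 1].  NaN when either detail image has zero
    variance.
    """
    if not mask:
        raise EmptyMaskError("bright_detail_similarity: empty mask")
    selem = morphology.disk(radius_px)
    a = morphology.white_tophat(record.channels[channel_a], selem)[mask.pixels]
    b = morphology.white_tophat(record.channels[channel_b], selem)[mask.pixels]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return max(r, 0.0)


def profile_colocalization(
    record: CellRecord,
    channel_a: int,
    channel_b: int,
    line: tuple[tuple[float, float], tuple[float, float]],
) -> float:
    """Signed Pearson r of the two channels' 1-D intensity profiles along a line.

    Negative r along a cell diameter indicates an internalized compound
    (interior signal anti-correlated with a membrane marker); positive r a
    membrane-adjacent one.
    """
    src, dst = line
    a = measure.profile_line(record.channels[channel_a], src, dst, order=1, mode="constant")
    b = measure.profile_line(record.channels[channel_b], src, dst, order=1, mode="constant")
    if a.size < 3:
        raise ValueError("profile has fewer than 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance along the profile")
    return float(np.corrcoef(a, b)[0, 1])


def compute_feature_row(
    record: CellRecord,
    maskset: MaskSet,
    compound_channel: int = 2,
    viability_channel: int = 3,
    object_channel: int = 1,
    glcm: GlcmParams | None = None,
) -> dict[str, float]:
    """All scalar features the gating cascade consumes, for one cell."""
    row: dict[str, float] = {
        "id": record.id,
        "sample_name": record.sample_name,
        "timestamp_s": record.timestamp_s,
    }
    row.update(morphometrics(maskset.object, record.pixel_size_um))
    row["gradient_rms"] = gradient_rms(record, maskset.object, object_channel)
    for ch in (compound_channel, viability_channel):
        feats = intensity_features(record, maskset.object, ch, background_mask=maskset.object)
        for k, v in feats.items():
            row[f"{k}_ch{ch}"] = v
    row["entropy_bits"] = glcm_entropy(record, maskset.cytoplasm, compound_channel, glcm)
    row["internalization_coefficient"] = internalization_coefficient(
        record, maskset.cytoplasm, maskset.object, compound_channel
    )
    return row


def compute_feature_table(
    records: list[CellRecord],
    object_channel: int = 1,
    coefficient_pct: float = 70,
    compound_channel: int = 2,
    viability_channel: int = 3,
    glcm: GlcmParams | None = None,
) -> pd.DataFrame:
    """Feature table (one row per cell) for a gallery.

    Cells whose object mask cannot be built get an all-NaN feature row (they
    fail every gate downstream) rather than aborting the run.
    """
    rows = []
    for rec in records:
        try:
            ms = build_maskset(rec, object_channel=object_channel, coefficient_pct=coefficient_pct)
            rows.append(
                compute_feature_row(rec, ms, compound_channel, viability_channel, object_channel, glcm)
            )
        except (EmptyMaskError, ValueError):
            rows.append({"id": rec.id, "sample_name": rec.sample_name, "timestamp_s": rec.timestamp_s})
    return pd.DataFrame(rows).set_index("id", drop=False)
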