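"""Seeded generator of synthetic imaging-flow-cytometry galleries.

Emulates round suspension cells (MT-4-like) as seen by an imaging flow
cytometer at ~1 µm pixel pitch: a brightfield channel showing the cell as an
absorbing disk on a bright background, a compound channel (FAM-like) whose
signal sits either on the plasma-membrane ring or inside the cytoplasm, and a
viability-dye channel (PI-like) separating live from dead cells.  Every event
carries ground truth, and every draw flows from one seed via per-event
substreams, so galleries are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .records import CellRecord

# Brightfield rendering constants (a.u.). The cell is an absorbing disk on a
# bright background; contrast and texture are fixed so that the focus metric
# of sharp cells sits well above the default focus gate while 3-px-defocused
# cells fall below it.
BF_BACKGROUND = 800.0
BF_CELL_LEVEL = 150.0
BF_TEXTURE_CV = 0.10
BF_HALO_PX = 1.3  # brightfield silhouette halo beyond the fluorescence disk (px)
DOUBLET_SEPARATION = 1.8  # centre separation in units of cell radius


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent :class:`SynthConfig`."""


@dataclass
class SynthConfig:
    """Generator settings; defaults define the study conditions.

    ``internalized_fraction`` is the probability that a cell has internalized
    the compound: such cells carry all compound signal inside the cytoplasm
    interior, the rest carry it on the membrane ring, so the population-level
    fraction of internalized signal equals this value in expectation.
    """

    image_size_px: tuple[int, int] = (64, 64)
    pixel_size_um: float = 1.0
    cell_radius_px: tuple[int, int] = (7, 8)
    membrane_width_px: int = 1
    internalized_fraction: float = 0.7
    signal_mode: str = "diffuse"  # {"diffuse", "punctate"}
    puncta_count: int = 4
    puncta_sigma_px: float = 1.0
    total_signal: float = 1e5
    dead_fraction: float = 0.1
    pi_dead_intensity: float = 5e4
    pi_live_intensity: float = 1e3
    doublet_fraction: float = 0.05
    defocus_fraction: float = 0.05
    defocus_sigma_px: float = 3.0
    noise_sd: float = 2.0
    background_level: float = 5.0
    flow_rate_events_per_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("internalized_fraction", "dead_fraction", "doublet_fraction", "defocus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} not in [0, 1]")
        if self.signal_mode not in ("diffuse", "punctate"):
            raise ConfigurationError(f"unknown signal_mode {self.signal_mode!r}")
        if not (self.pi_live_intensity < 1e4 <= self.pi_dead_intensity):
            raise ConfigurationError(
                "need pi_live_intensity < 1e4 <= pi_dead_intensity so the viability gate is exercisable"
            )
        if self.membrane_width_px < 1:
            raise ConfigurationError("membrane_width_px must be >= 1")
        if self.membrane_width_px >= min(self.cell_radius_px):
            raise ConfigurationError("membrane_width_px must be smaller than the minimum cell radius")
        if self.cell_radius_px[0] > self.cell_radius_px[1]:
            raise ConfigurationError("cell_radius_px range is empty")


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-event substream (counter-keyed)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _distance_grid(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center[0], cc - center[1])


def _normalized_field(weights: np.ndarray, total: float) -> np.ndarray:
    s = weights.sum()
    if s <= 0 or total <= 0:
        return np.zeros_like(weights)
    return weights * (total / s)


def _soft_region_field(weights: np.ndarray, region: np.ndarray, total: float) -> np.ndarray:
    """Smooth a weight field but keep it strictly confined to its region, so
    generated signal placement is exact and totals are conserved."""
    w = ndimage.gaussian_filter(weights * region, 0.6) * region
    return _normalized_field(w, total)


def _render_single(
    cfg: SynthConfig,
    rng: np.random.Generator,
    center: tuple[float, float],
    radius: int,
    internalized: bool,
    dead: bool,
    total_signal: float,
    pi_total: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free channel images (brightfield deficit, compound, viability) of one disk."""
    shape = cfg.image_size_px
    d = _distance_grid(shape, center)
    disk = d <= radius
    silhouette = d <= radius + BF_HALO_PX
    ring = disk & (d > radius - cfg.membrane_width_px)
    interior = d <= radius - cfg.membrane_width_px

    # Brightfield is assembled as a *deficit* from the bright background so
    # that overlapping doublet disks compose with a max, not a sum.  Texture
    # stays in the cell core: a clean silhouette edge keeps the Otsu boundary
    # smooth, so 1-px erosions behave like ideal annuli.
    texture = np.clip(1.0 + BF_TEXTURE_CV * rng.standard_normal(shape), 0.5, 1.5)
    core = d <= radius - 1
    bf_deficit = np.where(silhouette, BF_BACKGROUND - BF_CELL_LEVEL, 0.0)
    bf_deficit = bf_deficit * np.where(core, texture, 1.0)

    compound = np.zeros(shape)
    if internalized:
        if cfg.signal_mode == "punctate":
            weights = np.zeros(shape)
            rr, cc = np.nonzero(interior)
            if rr.size:
                picks = rng.integers(0, rr.size, size=max(1, cfg.puncta_count))
                gr, gc = np.mgrid[0 : shape[0], 0 : shape[1]]
                for k in picks:
                    weights += np.exp(
                        -((gr - rr[k]) ** 2 + (gc - cc[k]) ** 2) / (2 * cfg.puncta_sigma_px**2)
                    )
                weights *= interior
            compound = _normalized_field(weights, total_signal)
        else:
            weights = np.clip(1.0 + 0.25 * rng.standard_normal(shape), 0.05, None)
            compound = _soft_region_field(weights, interior, total_signal)
    else:
        weights = np.clip(1.0 + 0.25 * rng.standard_normal(shape), 0.05, None)
        compound = _soft_region_field(weights, ring, total_signal)

    viability = _soft_region_field(np.ones(shape), disk, pi_total)
    return bf_deficit, compound, viability


def generate_cell(
    cfg: SynthConfig,
    rng: np.random.Generator,
    index: int = 0,
    timestamp_s: float = 0.0,
) -> tuple[CellRecord, dict]:
    """Render one event and its ground-truth row.

    Class membership (doublet / dead / defocused / internalized) is drawn from
    ``rng``; the compound channel carries ``total_signal`` split over the
    membrane ring or cytoplasm interior, the viability channel carries the
    live or dead PI total spread over the disk, and Gaussian read noise plus a
    flat fluorescence background are added last.
    """
    shape = cfg.image_size_px
    radius = int(rng.integers(cfg.cell_radius_px[0], cfg.cell_radius_px[1] + 1))
    is_doublet = rng.random() < cfg.doublet_fraction
    is_dead = rng.random() < cfg.dead_fraction
    is_defocused = rng.random() < cfg.defocus_fraction
    internalized = rng.random() < cfg.internalized_fraction

    cy = shape[0] / 2 + rng.uniform(-2, 2)
    cx = shape[1] / 2 + rng.uniform(-2, 2)
    pi_total = cfg.pi_dead_intensity if is_dead else cfg.pi_live_intensity

    centers = [(cy, cx)]
    if is_doublet:
        angle = rng.uniform(0, np.pi)
        off = DOUBLET_SEPARATION * radius / 2.0
        centers = [
            (cy - off * np.sin(angle), cx - off * np.cos(angle)),
            (cy + off * np.sin(angle), cx + off * np.cos(angle)),
        ]

    bf_deficit = np.zeros(shape)
    compound = np.zeros(shape)
    viability = np.zeros(shape)
    for center in centers:
        dfc, cmp_, via = _render_single(
            cfg, rng, center, radius, internalized, is_dead,
            cfg.total_signal / len(centers), pi_total / len(centers),
        )
        bf_deficit = np.maximum(bf_deficit, dfc)
        compound += cmp_
        viability += via

    brightfield = BF_BACKGROUND - ndimage.gaussian_filter(bf_deficit, 0.8)

    if is_defocused:
        brightfield = ndimage.gaussian_filter(brightfield, cfg.defocus_sigma_px)
        compound = ndimage.gaussian_filter(compound, cfg.defocus_sigma_px)
        viability = ndimage.gaussian_filter(viability, cfg.defocus_sigma_px)

    def finish(img: np.ndarray, background: float) -> np.ndarray:
        out = img + background + cfg.noise_sd * rng.standard_normal(shape)
        return np.clip(out, 0.0, None)

    record = CellRecord(
        id=f"cell_{index:05d}",
        channels={
            1: finish(brightfield, 0.0),
            2: finish(compound, cfg.background_level),
            3: finish(viability, cfg.background_level),
        },
        pixel_size_um=cfg.pixel_size_um,
        timestamp_s=timestamp_s,
    )
    truth = {
        "id": record.id,
        "is_doublet": is_doublet,
        "is_dead": is_dead,
        "is_defocused": is_defocused,
        "true_internalized_fraction": 1.0 if internalized else 0.0,
        "true_signal_mode": cfg.signal_mode,
        "true_radius_px": radius,
        "timestamp_s": timestamp_s,
    }
    return record, truth


def generate_gallery(cfg: SynthConfig, n_events: int) -> tuple[list[CellRecord], pd.DataFrame]:
    """Generate ``n_events`` records with strictly increasing timestamps.

    Inter-arrival times are exponential at ``flow_rate_events_per_s``; each
    event uses its own counter-keyed substream of the configured seed, so any
    prefix of a gallery is independent of its length.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    time_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1_000_000_007,)))
    timestamps = np.cumsum(
        time_rng.exponential(1.0 / cfg.flow_rate_events_per_s, size=n_events) + 1e-9
    )
    records, rows = [], []
    for i in range(n_events):
        rec, truth = generate_cell(cfg, _cell_rng(cfg.seed, i), index=i, timestamp_s=float(timestamps[i]))
        records.append(rec)
        rows.append(truth)
    return records, pd.DataFrame(rows)


def generate_single_stain_controls(
    cfg: SynthConfig, spillover: np.ndarray, n_events: int = 100
) -> dict[str, tuple[list[CellRecord], pd.DataFrame]]:
    """Compound-only and viability-only control galleries mixed by ``spillover``.

    ``spillover`` is a 2x2 matrix over (compound, viability): S[i, j] is the
    fraction of channel-i signal leaking into channel j.  Raw single-stain
    images are mixed per pixel by S before background and noise are added.
    """
    S = np.asarray(spillover, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ConfigurationError("spillover matrix must be square")
    if S.shape[0] != 2:
        raise ConfigurationError("controls cover the two fluorescence channels")
    if not np.allclose(np.diag(S), 1.0):
        raise ConfigurationError("spillover diagonal must be 1")
    off = S[~np.eye(2, dtype=bool)]
    if (off < 0).any() or (off >= 1).any():
        raise ConfigurationError("off-diagonal spillover must be in [0, 1)")

    out: dict[str, tuple[list[CellRecord], pd.DataFrame]] = {}
    for stain_idx, (name, sub_cfg) in enumerate(
        [
            # compound-only: no PI at all
            ("compound", replace(cfg, dead_fraction=0.0, pi_live_intensity=0.0,
                                 internalized_fraction=cfg.internalized_fraction,
                                 doublet_fraction=0.0, defocus_fraction=0.0,
                                 seed=cfg.seed + 101)),
            # viability-only: strong PI stain, no compound
            ("viability", replace(cfg, total_signal=0.0, dead_fraction=1.0,
                                  doublet_fraction=0.0, defocus_fraction=0.0,
                                  seed=cfg.seed + 202)),
        ]
    ):
        records, truth = _generate_mixed(sub_cfg, S, n_events)
        out[name] = (records, truth)
    return out


def _generate_mixed(cfg: SynthConfig, S: np.ndarray, n_events: int) -> tuple[list[CellRecord], pd.DataFrame]:
    """Gallery whose raw fluorescence channels are mixed per pixel by S before noise."""
    noiseless = replace(cfg, noise_sd=0.0, background_level=0.0)
    records, truth = generate_gallery(noiseless, n_events)
    post_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(424_242,)))
    mixed_records = []
    for rec in records:
        raw = np.stack([rec.channels[2], rec.channels[3]])  # (2, H, W)
        obs = np.einsum("ij,ihw->jhw", S, raw)
        chans = {1: rec.channels[1]}
        for j, img in enumerate(obs):
            noisy = img + cfg.background_level + cfg.noise_sd * post_rng.standard_normal(img.shape)
            chans[2 + j] = np.clip(noisy, 0.0, None)
        mixed_records.append(
            CellRecord(id=rec.id, channels=chans, pixel_size_um=rec.pixel_size_um,
                       timestamp_s=rec.timestamp_s, sample_name=rec.sample_name)
        )
    return mixed_records, truth
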