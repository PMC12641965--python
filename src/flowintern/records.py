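"""Per-event image records and open on-disk gallery format.

A *gallery* is the open equivalent of a proprietary imaging-flow-cytometry
container: one multipage TIFF per event (pages = channels), a JSON sidecar
mapping channel indices to names plus the pixel size, and an optional CSV
ground-truth table when the gallery is synthetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Conventional channel layout (1-based, as on the instrument).
DEFAULT_CHANNEL_MAP = {1: "brightfield", 2: "compound", 3: "viability"}


@dataclass
class CellRecord:
    """One acquired event: a multichannel image stack plus metadata.

    Parameters
    ----------
    id : str
        Unique event identifier within its gallery.
    channels : dict[int, np.ndarray]
        Channel index -> 2-D intensity array.  All arrays share one shape;
        intensities are nonnegative and finite.
    pixel_size_um : float
        Physical pixel pitch in micrometres.
    timestamp_s : float
        Seconds since the start of acquisition.
    sample_name : str
        The ``<object>_<Num>`` sample identity the event belongs to.
    """

    id: str
    channels: dict[int, np.ndarray]
    pixel_size_um: float = 1.0
    timestamp_s: float = 0.0
    sample_name: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("CellRecord needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel arrays differ in shape: {shapes}")
        for idx, img in self.channels.items():
            img = np.asarray(img, dtype=float)
            if not np.all(np.isfinite(img)) or (img < 0).any():
                raise ValueError(f"channel {idx}: intensities must be nonnegative and finite")
            self.channels[idx] = img

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def stack(self) -> np.ndarray:
        """Channels stacked in index order, shape (n_channels, H, W)."""
        return np.stack([self.channels[k] for k in sorted(self.channels)])


def save_gallery(
    records: list[CellRecord],
    outdir: str | Path,
    ground_truth: pd.DataFrame | None = None,
    channel_map: dict[int, str] | None = None,
) -> Path:
    """Write a gallery: one multipage TIFF per event + JSON sidecar (+ truth CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not records:
        raise ValueError("empty gallery")
    for rec in records:
        tifffile.imwrite(
            outdir / f"{rec.id}.tif", rec.stack().astype(np.float32), photometric="minisblack"
        )
    sidecar = {
        "channel_map": {str(k): v for k, v in (channel_map or DEFAULT_CHANNEL_MAP).items()},
        "pixel_size_um": records[0].pixel_size_um,
        "events": [
            {"id": r.id, "timestamp_s": r.timestamp_s, "sample_name": r.sample_name}
            for r in records
        ],
    }
    (outdir / "gallery.json").write_text(json.dumps(sidecar, indent=1))
    if ground_truth is not None:
        ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    return outdir


def load_gallery(indir: str | Path) -> tuple[list[CellRecord], pd.DataFrame | None]:
    """Read a gallery written by :func:`save_gallery`."""
    indir = Path(indir)
    sidecar = json.loads((indir / "gallery.json").read_text())
    channel_indices = sorted(int(k) for k in sidecar["channel_map"])
    records = []
    for ev in sidecar["events"]:
        stack = tifffile.imread(indir / f"{ev['id']}.tif").astype(float)
        if stack.ndim == 2:
            stack = stack[None]
        records.append(
            CellRecord(
                id=ev["id"],
                channels={idx: stack[i] for i, idx in enumerate(channel_indices)},
                pixel_size_um=float(sidecar["pixel_size_um"]),
                timestamp_s=float(ev["timestamp_s"]),
                sample_name=ev.get("sample_name", ""),
            )
        )
    truth_path = indir / "ground_truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return records, truth
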