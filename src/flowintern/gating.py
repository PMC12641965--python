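"""The six-step gating cascade and per-sample summary reports.

Gate order is fixed: focus → acquisition time → singlets → viability →
compound uptake → internalization.  Boundary conventions: the viability gate
is strictly ``< 1e4`` and the internalization gate strictly ``> 0`` (matching
the thresholds' definitions); all other gates are inclusive.  Cells with a
missing (NaN) feature fail the gate that reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compensation import SpilloverMatrix, apply_compensation
from .features import GlcmParams, compute_feature_table
from .records import CellRecord

GATE_ORDER = ("all", "in_focus", "time_ok", "singlets", "viable", "uptake", "internalized")


@dataclass
class GateConfig:
    """Thresholds of the cascade.

    ``uptake_min_total`` may be a number or ``"auto"``, in which case the
    threshold is the negative control's mean + 3·SD of compound totals.
    """

    focus_min_gradient_rms: float = 40.0
    time_min_s: float = 20.0
    singlet_area_um2: tuple[float, float] = (50.0, 300.0)
    singlet_aspect_ratio_min: float = 0.6
    viability_max_pi: float = 1e4
    uptake_min_total: float | str = 0.0
    internalization_min_ic: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.singlet_area_um2
        if not lo <= hi:
            raise ValueError("singlet area range is empty")


@dataclass
class PopulationTree:
    """Ordered gate memberships; each gate's members belong to its parent."""

    gates: dict[str, list[str]]

    def count(self, gate: str) -> int:
        return len(self.gates[gate])

    @property
    def counts(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.gates.items()}


@dataclass
class SampleSummary:
    """The per-sample statistics-report row (the instrument-report analogue)."""

    file: str
    total_count: int
    viable_single_count: int
    viable_single_pct: float
    uptake_count: int
    uptake_pct: float
    internalized_count: int
    internalized_pct: float
    median_entropy_bits: float
    median_ic: float


def _members(features: pd.DataFrame, ids: list[str], keep: pd.Series) -> list[str]:
    sel = keep.reindex(ids).fillna(False)
    return [i for i in ids if bool(sel.loc[i])]


def gate_focus(features: pd.DataFrame, cfg: GateConfig, ids: list[str] | None = None) -> list[str]:
    ids = list(features.index) if ids is None else ids
    return _members(features, ids, features["gradient_rms"] >= cfg.focus_min_gradient_rms)


def gate_time(features: pd.DataFrame, cfg: GateConfig, ids: list[str] | None = None) -> list[str]:
    ids = list(features.index) if ids is None else ids
    return _members(features, ids, features["timestamp_s"] >= cfg.time_min_s)


def gate_singlets(features: pd.DataFrame, cfg: GateConfig, ids: list[str] | None = None) -> list[str]:
    ids = list(features.index) if ids is None else ids
    lo, hi = cfg.singlet_area_um2
    keep = (
        (features["area_um2"] >= lo)
        & (features["area_um2"] <= hi)
        & (features["aspect_ratio"] >= cfg.singlet_aspect_ratio_min)
    )
    return _members(features, ids, keep)


def gate_viable(features: pd.DataFrame, cfg: GateConfig, ids: list[str] | None = None) -> list[str]:
    """Keep cells with viability-dye total strictly below the threshold
    (compensated totals are used when present)."""
    ids = list(features.index) if ids is None else ids
    col = "total_ch3_comp" if "total_ch3_comp" in features else "total_ch3"
    return _members(features, ids, features[col] < cfg.viability_max_pi)


def gate_uptake(
    features: pd.DataFrame,
    cfg: GateConfig,
    ids: list[str] | None = None,
    negative_control: pd.DataFrame | None = None,
) -> list[str]:
    ids = list(features.index) if ids is None else ids
    col = "total_ch2_comp" if "total_ch2_comp" in features else "total_ch2"
    thr = cfg.uptake_min_total
    if thr == "auto":
        if negative_control is None:
            raise ValueError("uptake_min_total='auto' requires a negative control")
        ctl_col = col if col in negative_control else "total_ch2"
        ctl = negative_control[ctl_col].dropna()
        thr = float(ctl.mean() + 3.0 * ctl.std(ddof=1))
    return _members(features, ids, features[col] >= float(thr))


def gate_internalized(features: pd.DataFrame, cfg: GateConfig, ids: list[str] | None = None) -> list[str]:
    ids = list(features.index) if ids is None else ids
    return _members(features, ids, features["internalization_coefficient"] > cfg.internalization_min_ic)


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else 0.0


def run_pipeline(
    records: list[CellRecord],
    gate_cfg: GateConfig | None = None,
    sample_name: str = "sample_1",
    spillover: SpilloverMatrix | None = None,
    negative_control: pd.DataFrame | None = None,
    coefficient_pct: float = 70,
    glcm: GlcmParams | None = None,
) -> tuple[pd.DataFrame, PopulationTree, SampleSummary]:
    """Full analysis of one gallery: features, gating cascade, summary.

    When a spillover matrix over ('compound', 'viability') is given, the
    fluorescence totals are unmixed before the viability and uptake gates
    (columns ``total_ch2_comp`` / ``total_ch3_comp``).
    """
    if not records:
        raise ValueError("empty gallery")
    gate_cfg = gate_cfg or GateConfig()
    features = compute_feature_table(records, coefficient_pct=coefficient_pct, glcm=glcm)
    if spillover is not None:
        obs = features[["total_ch2", "total_ch3"]].to_numpy(dtype=float)
        comp = apply_compensation(obs, spillover)
        features["total_ch2_comp"] = np.clip(comp[:, 0], 0.0, None)
        features["total_ch3_comp"] = np.clip(comp[:, 1], 0.0, None)

    gates: dict[str, list[str]] = {"all": list(features.index)}
    gates["in_focus"] = gate_focus(features, gate_cfg, gates["all"])
    gates["time_ok"] = gate_time(features, gate_cfg, gates["in_focus"])
    gates["singlets"] = gate_singlets(features, gate_cfg, gates["time_ok"])
    gates["viable"] = gate_viable(features, gate_cfg, gates["singlets"])
    gates["uptake"] = gate_uptake(features, gate_cfg, gates["viable"], negative_control)
    gates["internalized"] = gate_internalized(features, gate_cfg, gates["uptake"])
    tree = PopulationTree(gates)

    uptake = features.loc[gates["uptake"]]
    summary = SampleSummary(
        file=f"{sample_name}.daf",
        total_count=len(gates["all"]),
        viable_single_count=len(gates["viable"]),
        viable_single_pct=_pct(len(gates["viable"]), len(gates["all"])),
        uptake_count=len(gates["uptake"]),
        uptake_pct=_pct(len(gates["uptake"]), len(gates["viable"])),
        internalized_count=len(gates["internalized"]),
        internalized_pct=_pct(len(gates["internalized"]), len(gates["uptake"])),
        median_entropy_bits=float(uptake["entropy_bits"].median()) if len(uptake) else float("nan"),
        median_ic=float(uptake["internalization_coefficient"].median()) if len(uptake) else float("nan"),
    )
    return features, tree, summary


REPORT_COLUMNS = {
    "file": "File",
    "total_count": "Total Count",
    "viable_single_count": "Viable Single Count",
    "viable_single_pct": "Viable Single %",
    "uptake_count": "Uptake Count",
    "uptake_pct": "Uptake %",
    "internalized_count": "Internalized Count",
    "internalized_pct": "Internalized %",
    "median_entropy_bits": "Median Entropy",
    "median_ic": "Median Internalization Coefficient",
}


def write_report(summaries: list[SampleSummary], path: str | Path) -> Path:
    """Tab-delimited per-sample report (UTF-8, dot decimal, header row).

    The first column is ``File`` with ``<object>_<Num>.daf`` entries; numeric
    fields are written at full precision so a write→parse round trip is exact.
    """
    if not summaries:
        raise ValueError("no summaries to write")
    files = [s.file for s in summaries]
    if len(set(files)) != len(files):
        raise ValueError("duplicate File entries in report")
    df = pd.DataFrame([{REPORT_COLUMNS[k]: getattr(s, k) for k in REPORT_COLUMNS} for s in summaries])
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", float_format=None)
    return path
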