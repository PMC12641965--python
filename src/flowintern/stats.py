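"""Effect-size-first statistics over per-timepoint report tables.

Parses tab-delimited statistics reports (one file per time point, keyed by a
``File`` column of ``<object>_<Num>.daf`` entries) into a long table, then:

* between-object comparisons at each time point — one-way ANOVA (F), ω² with
  a 95% CI by noncentral-F inversion, Tukey HSD pairwise p-values and
  Cohen's d, Benjamini–Hochberg adjustment across the pairwise family;
* within-object comparisons across time — one-way repeated-measures ANOVA on
  complete cases, generalized eta-squared (GES) with a seeded bootstrap CI,
  paired t-tests with Cohen's dz and BH adjustment;
* exclusion screening (missing time points, <2 replicates, zero variance),
  Excel/CSV export and dot-plot summaries.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.multitest import multipletests


class ReportFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parsing and descriptives
# ---------------------------------------------------------------------------

def parse_report(path: str | Path, time_label: str) -> pd.DataFrame:
    """Read one per-timepoint report into long format.

    The header row is the first line containing a ``File`` cell (preamble
    lines above it are skipped).  Each File stem splits on its LAST
    underscore: the prefix is the object name (which may itself contain
    underscores), the numeric suffix the replicate.  Every other column that
    parses as numeric becomes a parameter; non-numeric cells become missing.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    header_idx = next(
        (i for i, ln in enumerate(lines) if "File" in ln.split("\t")), None
    )
    if header_idx is None:
        raise ReportFormatError(f"{path.name}: no 'File' column found")
    df = pd.read_csv(io.StringIO("\n".join(lines[header_idx:])), sep="\t", dtype=str)
    rows = []
    for pos, (_, rec) in enumerate(df.iterrows(), start=1):
        stem = str(rec["File"])
        if stem.endswith(".daf"):
            stem = stem[: -len(".daf")]
        obj, _, num = stem.rpartition("_")
        if not obj or not num.isdigit():
            raise ReportFormatError(
                f"{path.name} row {pos}: File entry {rec['File']!r} lacks an _<int> suffix"
            )
        for col in df.columns:
            if col == "File":
                continue
            value = pd.to_numeric(pd.Series([rec[col]]), errors="coerce").iloc[0]
            rows.append(
                {"object": obj, "replicate": int(num), "time": time_label,
                 "parameter": col, "value": float(value) if pd.notna(value) else np.nan}
            )
    return pd.DataFrame(rows)


def load_reports(paths: list[str | Path], time_labels: list[str], time_order: list[str] | None = None) -> pd.DataFrame:
    """Stack per-timepoint reports; ``time`` becomes ordered categorical."""
    if len(paths) != len(time_labels):
        raise ValueError("one time label per report file")
    table = pd.concat([parse_report(p, t) for p, t in zip(paths, time_labels)], ignore_index=True)
    order = time_order or list(dict.fromkeys(time_labels))
    table["time"] = pd.Categorical(table["time"], categories=order, ordered=True)
    dup = table.duplicated(subset=["object", "replicate", "time", "parameter"])
    if dup.any():
        raise ReportFormatError("duplicate (object, replicate, time, parameter) rows")
    return table


def descriptive_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n−1; missing when n=1) and n per (object, time, parameter)."""
    if table.empty:
        raise ValueError("empty table")
    g = table.dropna(subset=["value"]).groupby(["object", "time", "parameter"], observed=True)["value"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan, n="count")
    return out.reset_index()


# ---------------------------------------------------------------------------
# exclusion screening
# ---------------------------------------------------------------------------

@dataclass
class ExclusionLog:
    rows: list[dict] = field(default_factory=list)

    def add(self, unit: str, parameter: str, reason: str) -> None:
        self.rows.append({"unit": unit, "parameter": parameter, "reason": reason})

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["unit", "parameter", "reason"])


def exclusion_screen(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Flag (object, parameter) units unfit for comparative analysis.

    Rules: the object must appear at every time level (else *missing
    timepoint*), with ≥2 replicates at each (else *<2 replicates* /
    *insufficient data* when only one time has data), and the values must not
    be globally constant (*zero variance*).  Excluded units are removed from
    the returned comparative table only — descriptives always use the full
    table.
    """
    log = ExclusionLog()
    times = list(table["time"].cat.categories) if hasattr(table["time"], "cat") else sorted(table["time"].unique())
    keep_mask = pd.Series(True, index=table.index)
    for (obj, param), sub in table.dropna(subset=["value"]).groupby(["object", "parameter"], observed=True):
        counts = sub.groupby("time", observed=False)["replicate"].nunique().reindex(times).fillna(0)
        reason = None
        if len(times) < 2 or counts.sum() < 2:
            reason = "insufficient data"
        elif (counts == 0).any():
            reason = "missing timepoint"
        elif (counts < 2).any():
            reason = "<2 replicates"
        elif sub["value"].nunique() == 1:
            reason = "zero variance"
        if reason:
            log.add(obj, param, reason)
            keep_mask &= ~((table["object"] == obj) & (table["parameter"] == param))
    return table[keep_mask].copy(), log


# ---------------------------------------------------------------------------
# between-object: one-way ANOVA, omega squared, Tukey HSD, Cohen's d
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    parameter: str
    time: str
    F: float
    df: tuple[int, int]
    p: float
    omega_sq: float
    omega_sq_ci: tuple[float, float]
    pairwise: pd.DataFrame | None = None
    infinite_f: bool = False

    def summary(self) -> pd.DataFrame:
        base = pd.DataFrame(
            [{
                "parameter": self.parameter, "time": self.time, "F": self.F,
                "df1": self.df[0], "df2": self.df[1], "p": self.p,
                "omega_sq": self.omega_sq,
                "omega_sq_ci_low": self.omega_sq_ci[0], "omega_sq_ci_high": self.omega_sq_ci[1],
            }]
        )
        return base


def _groups_at(table: pd.DataFrame, parameter: str, time: str) -> dict[str, np.ndarray]:
    sub = table[(table["parameter"] == parameter) & (table["time"] == time)].dropna(subset=["value"])
    groups = {obj: g["value"].to_numpy(dtype=float) for obj, g in sub.groupby("object", observed=True)}
    return {k: v for k, v in groups.items() if v.size >= 2}


def _anova_ss(groups: dict[str, np.ndarray]) -> tuple[float, float, float, int, int]:
    allv = np.concatenate(list(groups.values()))
    gm = allv.mean()
    ssb = sum(v.size * (v.mean() - gm) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    return float(ssb), float(ssw), float(((allv - gm) ** 2).sum()), len(groups), allv.size


def _omega_sq_ci(F: float, df1: int, df2: int, n_total: int, conf: float = 0.95) -> tuple[float, float]:
    """CI by inverting the noncentral-F distribution for the noncentrality λ,
    then mapping λ → ω² via ω² = λ/(λ + N)."""
    if not np.isfinite(F):
        return (0.0, 1.0)
    alpha = 1.0 - conf

    def bound(prob: float) -> float:
        # find λ with ncf.cdf(F; df1, df2, λ) = prob
        if sps.ncf.cdf(F, df1, df2, 0.0) <= prob:
            return 0.0
        hi = 10.0
        while sps.ncf.cdf(F, df1, df2, hi) > prob and hi < 1e7:
            hi *= 2
        return float(optimize.brentq(lambda lam: sps.ncf.cdf(F, df1, df2, lam) - prob, 0.0, hi))

    lam_lo = bound(1.0 - alpha / 2)
    lam_hi = bound(alpha / 2)
    return (lam_lo / (lam_lo + n_total), lam_hi / (lam_hi + n_total))


def oneway_anova(table: pd.DataFrame, parameter: str, time: str, log: ExclusionLog | None = None) -> AnovaResult | None:
    """Between-object one-way ANOVA at one time point, with ω² and its CI.

    Requires ≥2 objects with ≥2 replicates each and nonzero total variance;
    violations are logged and ``None`` returned.
    """
    groups = _groups_at(table, parameter, time)
    unit = f"time={time}"
    if len(groups) < 2:
        if log is not None:
            log.add(unit, parameter, "insufficient data")
        return None
    ssb, ssw, sst, k, n = _anova_ss(groups)
    if sst == 0:
        if log is not None:
            log.add(unit, parameter, "zero variance")
        return None
    df1, df2 = k - 1, n - k
    msw = ssw / df2
    if msw == 0:
        F, p, inf = float("inf"), 0.0, True
    else:
        F, inf = (ssb / df1) / msw, False
        p = float(sps.f.sf(F, df1, df2))
    omega = (ssb - df1 * msw) / (sst + msw) if (sst + msw) > 0 else np.nan
    ci = _omega_sq_ci(F, df1, df2, n)
    return AnovaResult(parameter, str(time), float(F), (df1, df2), p, float(omega), ci, infinite_f=inf)


def tukey_pairwise(table: pd.DataFrame, parameter: str, time: str, log: ExclusionLog | None = None) -> pd.DataFrame | None:
    """Tukey HSD (studentized range, Tukey–Kramer for unequal n) with Cohen's d
    and BH adjustment across the pairwise family of one (parameter, time)."""
    groups = _groups_at(table, parameter, time)
    if len(groups) < 2:
        if log is not None:
            log.add(f"time={time}", parameter, "insufficient data")
        return None
    ssb, ssw, sst, k, n = _anova_ss(groups)
    if sst == 0:
        if log is not None:
            log.add(f"time={time}", parameter, "zero variance")
        return None
    msw = ssw / (n - k)
    rows = []
    for (a, xa), (b, xb) in itertools.combinations(groups.items(), 2):
        diff = xa.mean() - xb.mean()
        pooled = math.sqrt(
            (((xa - xa.mean()) ** 2).sum() + ((xb - xb.mean()) ** 2).sum()) / (xa.size + xb.size - 2)
        )
        d = diff / pooled if pooled > 0 else (0.0 if diff == 0 else math.copysign(float("inf"), diff))
        if msw > 0:
            q = abs(diff) / math.sqrt(msw / 2.0 * (1.0 / xa.size + 1.0 / xb.size))
            p = float(sps.studentized_range.sf(q, k, n - k))
        else:
            p = 0.0 if diff != 0 else 1.0
        rows.append({"pair": f"{a} vs {b}", "mean_diff": float(diff), "tukey_p": p, "cohen_d": float(d)})
    out = pd.DataFrame(rows)
    out["bh_p"] = multipletests(out["tukey_p"], method="fdr_bh")[1]
    out["significant"] = out["bh_p"] < 0.05
    return out


# ---------------------------------------------------------------------------
# within-object: RM-ANOVA, GES, paired t-tests, Cohen's dz
# ---------------------------------------------------------------------------

@dataclass
class RmAnovaResult:
    parameter: str
    object: str
    F: float
    df: tuple[int, int]
    p: float
    ges: float
    ges_ci: tuple[float, float]
    ss: dict[str, float]
    pairwise: pd.DataFrame | None = None
    infinite_f: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "parameter": self.parameter, "object": self.object, "F": self.F,
                "df1": self.df[0], "df2": self.df[1], "p": self.p, "ges": self.ges,
                "ges_ci_low": self.ges_ci[0], "ges_ci_high": self.ges_ci[1],
            }]
        )


def _complete_cases(table: pd.DataFrame, parameter: str, obj: str) -> pd.DataFrame:
    """Replicate × time value matrix, complete cases only, time in level order."""
    sub = table[(table["parameter"] == parameter) & (table["object"] == obj)].dropna(subset=["value"])
    wide = sub.pivot_table(index="replicate", columns="time", values="value", observed=True)
    if hasattr(table["time"], "cat"):
        present = [t for t in table["time"].cat.categories if t in wide.columns]
        wide = wide[present]
    return wide.dropna(axis=0, how="any")


def _rm_decompose(wide: pd.DataFrame) -> dict[str, float]:
    X = wide.to_numpy(dtype=float)
    n, t = X.shape
    gm = X.mean()
    ss_subject = float(t * ((X.mean(axis=1) - gm) ** 2).sum())
    ss_time = float(n * ((X.mean(axis=0) - gm) ** 2).sum())
    sst = float(((X - gm) ** 2).sum())
    ss_error = max(sst - ss_subject - ss_time, 0.0)
    return {"ss_subject": ss_subject, "ss_time": ss_time, "ss_error": ss_error, "ss_total": sst}


def _ges(ss: dict[str, float]) -> float:
    denom = ss["ss_time"] + ss["ss_subject"] + ss["ss_error"]
    return ss["ss_time"] / denom if denom > 0 else float("nan")


def rm_anova(
    table: pd.DataFrame,
    parameter: str,
    obj: str,
    log: ExclusionLog | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> RmAnovaResult | None:
    """One-way within-subject ANOVA across time for one object.

    Complete cases only (replicates present at every time point); GES =
    SS_time / (SS_time + SS_subject + SS_error) with a seeded percentile
    bootstrap CI over subjects.  A zero error SS yields an infinite F,
    reported as such and flagged.
    """
    wide = _complete_cases(table, parameter, obj)
    if wide.shape[1] < 2 or wide.shape[0] < 2:
        if log is not None:
            log.add(obj, parameter, "insufficient data")
        return None
    ss = _rm_decompose(wide)
    n, t = wide.shape
    df1, df2 = t - 1, (n - 1) * (t - 1)
    if ss["ss_total"] == 0:
        if log is not None:
            log.add(obj, parameter, "zero variance")
        return None
    ms_time = ss["ss_time"] / df1
    ms_error = ss["ss_error"] / df2
    if ms_error == 0:
        F, p, inf = float("inf"), 0.0, True
    else:
        F, inf = ms_time / ms_error, False
        p = float(sps.f.sf(F, df1, df2))
    ges = _ges(ss)

    rng = np.random.default_rng(seed)
    boots = []
    X = wide.to_numpy(dtype=float)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        g = _ges(_rm_decompose(pd.DataFrame(X[idx])))
        if np.isfinite(g):
            boots.append(g)
    ci = (
        (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        if boots
        else (float("nan"), float("nan"))
    )
    return RmAnovaResult(parameter, obj, float(F), (df1, df2), p, float(ges), ci, ss, infinite_f=inf)


def paired_tests(
    table: pd.DataFrame, parameter: str, obj: str, log: ExclusionLog | None = None
) -> pd.DataFrame | None:
    """Paired t-tests between time points (complete cases) with Cohen's dz and
    BH adjustment across the time-pair family of one (parameter, object)."""
    wide = _complete_cases(table, parameter, obj)
    if wide.shape[1] < 2 or wide.shape[0] < 2:
        if log is not None:
            log.add(obj, parameter, "insufficient data")
        return None
    rows = []
    for t1, t2 in itertools.combinations(wide.columns, 2):
        diff = (wide[t2] - wide[t1]).to_numpy(dtype=float)
        sd = diff.std(ddof=1)
        if sd == 0:
            if log is not None:
                log.add(obj, parameter, "zero variance")
            rows.append({"pair": f"{t1} vs {t2}", "mean_diff": float(diff.mean()),
                         "t": np.nan, "p": np.nan, "cohen_dz": np.nan})
            continue
        t_stat = diff.mean() / (sd / math.sqrt(diff.size))
        p = float(sps.t.sf(abs(t_stat), diff.size - 1) * 2)
        rows.append({"pair": f"{t1} vs {t2}", "mean_diff": float(diff.mean()),
                     "t": float(t_stat), "p": p, "cohen_dz": float(diff.mean() / sd)})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["bh_p"] = np.nan
    if valid.any():
        out.loc[valid, "bh_p"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    out["significant"] = out["bh_p"] < 0.05
    return out


# ---------------------------------------------------------------------------
# orchestration, export, plotting
# ---------------------------------------------------------------------------

@dataclass
class StatsResults:
    descriptives: pd.DataFrame
    anova: pd.DataFrame
    rm_anova: pd.DataFrame
    excluded: pd.DataFrame


def run_stats(table: pd.DataFrame, boot_seed: int = 0, n_boot: int = 2000) -> StatsResults:
    """The full comparative pipeline over a tidy table."""
    desc = descriptive_stats(table)
    retained, log = exclusion_screen(table)

    anova_rows, rm_rows = [], []
    params = sorted(retained["parameter"].unique())
    times = (
        list(retained["time"].cat.categories)
        if hasattr(retained["time"], "cat")
        else sorted(retained["time"].unique())
    )
    for param in params:
        for time in times:
            res = oneway_anova(retained, param, time, log)
            if res is None:
                continue
            res.pairwise = tukey_pairwise(retained, param, time)
            base = res.summary()
            if res.pairwise is not None:
                for _, pr in res.pairwise.iterrows():
                    row = base.iloc[0].to_dict() | pr.to_dict()
                    anova_rows.append(row)
            else:
                anova_rows.append(base.iloc[0].to_dict())
        for obj in sorted(retained.loc[retained["parameter"] == param, "object"].unique()):
            res = rm_anova(retained, param, obj, log, n_boot=n_boot, seed=boot_seed)
            if res is None:
                continue
            res.pairwise = paired_tests(retained, param, obj)
            base = res.summary()
            if res.pairwise is not None:
                for _, pr in res.pairwise.iterrows():
                    rm_rows.append(base.iloc[0].to_dict() | pr.to_dict())
            else:
                rm_rows.append(base.iloc[0].to_dict())

    # deduplicate exclusion log rows
    excl = log.frame().drop_duplicates().reset_index(drop=True)
    return StatsResults(
        descriptives=desc,
        anova=pd.DataFrame(anova_rows),
        rm_anova=pd.DataFrame(rm_rows),
        excluded=excl,
    )


_SHEETS = {
    "descriptives": "Descriptive statistics",
    "anova": "ANOVA & Tukey",
    "rm_anova": "RM-ANOVA & t-tests",
    "excluded": "Excluded tubes-samples",
}


def export_results(results: StatsResults, outdir: str | Path) -> dict[str, Path]:
    """Write Results.xlsx (four sheets) plus a byte-stable CSV mirror."""
    frames = {k: getattr(results, k) for k in _SHEETS}
    if all(df.empty for df in frames.values()):
        raise ValueError("no results to export")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    xlsx = outdir / "Results.xlsx"
    with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
        for key, sheet in _SHEETS.items():
            frames[key].to_excel(writer, sheet_name=sheet, index=False)
    paths["xlsx"] = xlsx
    for key in _SHEETS:
        p = outdir / f"{key}.csv"
        frames[key].to_csv(p, index=False)
        paths[key] = p
    return paths


def plot_summary(table: pd.DataFrame, outdir: str | Path, mode: str = "per-object") -> list[Path]:
    """Dot plots of means with SD whiskers.

    ``per-object``: one panel per object, x = time; ``per-time``: one panel
    per time point, x = object.  Deterministic layout; PNG output.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    desc = descriptive_stats(table)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    facet, xaxis = ("object", "time") if mode == "per-object" else ("time", "object")
    for param, dsub in desc.groupby("parameter"):
        keys = sorted(dsub[facet].astype(str).unique())
        fig, axes = plt.subplots(1, len(keys), figsize=(3.2 * len(keys), 3.2), squeeze=False, sharey=True)
        for ax, key in zip(axes[0], keys):
            sub = dsub[dsub[facet].astype(str) == key]
            xs = np.arange(len(sub))
            yerr = sub["sd"].to_numpy(dtype=float)
            ax.errorbar(xs, sub["mean"], yerr=np.where(np.isnan(yerr), 0.0, yerr),
                        fmt="o", capsize=3)
            ax.set_xticks(xs, sub[xaxis].astype(str))
            ax.set_title(f"{key}")
            ax.set_xlabel(xaxis)
        axes[0][0].set_ylabel(param)
        fig.suptitle(param)
        fig.tight_layout()
        out = outdir / f"summary_{param}_{mode}.png".replace(" ", "_").replace("%", "pct")
        fig.savefig(out, dpi=120)
        plt.close(fig)
        paths.append(out)
    return paths
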