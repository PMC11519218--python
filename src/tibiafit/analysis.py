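"""Cohort-level statistics on virtual-implantation results.

Implements the study's statistical stage: per-sex descriptives,
Lilliefors-corrected Kolmogorov-Smirnov normality checks, sex comparisons
(two-tailed unpaired t test for normal data, two-sample Mann-Whitney
rank-sum otherwise), Pearson/Spearman correlations chosen by normality,
per-implant-size application ranges with their overlap structure, and
sex-stratified size-frequency tables.

Note: for the unpaired two-group comparison the two-sample rank-sum
(Mann-Whitney U) test is used as the nonparametric alternative; a
signed-rank test is undefined for independent groups of unequal size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import UndefinedTestError

__all__ = [
    "descriptives",
    "normality_check",
    "compare_sexes",
    "correlate",
    "size_ranges",
    "frequency_table",
    "StatReport",
    "build_report",
]

ALPHA = 0.05
_NUMERIC_VARS = ["age", "height", "weight", "bmi", "area_mm2"]


def descriptives(table: pd.DataFrame, by_sex: bool = True) -> pd.DataFrame:
    """Mean/SD and median/min/max per variable, optionally per sex.

    A group with a single value reports SD 0 and is flagged degenerate.
    """
    if table.empty:
        raise ValueError("empty table")
    variables = [c for c in _NUMERIC_VARS if c in table.columns]
    groups = table.groupby("sex") if by_sex else [("all", table)]
    rows = []
    for sex, g in groups:
        if g.empty:
            raise ValueError(f"empty group {sex!r}")
        for var in variables:
            x = g[var].dropna().to_numpy(dtype=float)
            if x.size == 0:
                raise ValueError(f"empty group {sex!r} for {var!r}")
            rows.append(
                {
                    "sex": sex,
                    "variable": var,
                    "n": int(x.size),
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                    "median": float(np.median(x)),
                    "min": float(np.min(x)),
                    "max": float(np.max(x)),
                    "degenerate": bool(x.size < 2),
                }
            )
    return pd.DataFrame(rows)


def normality_check(values: np.ndarray, alpha: float = ALPHA) -> tuple[float, bool]:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    Uses the Lilliefors correction (parameters estimated from the sample).
    Returns (p_value, is_normal) with the decision at ``alpha``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("normality check requires n >= 8")
    if np.ptp(x) == 0:
        raise UndefinedTestError("normality test undefined for constant input")
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(p), bool(p >= alpha)


def compare_sexes(
    values_f: np.ndarray,
    values_m: np.ndarray,
    normal_flag: bool | tuple[bool, bool],
) -> tuple[str, float]:
    """Two-group comparison: unpaired two-tailed t test if both groups are
    normal, two-sample rank-sum (Mann-Whitney U) otherwise."""
    f = np.asarray(values_f, dtype=float)
    m = np.asarray(values_m, dtype=float)
    if f.size < 2 or m.size < 2:
        raise ValueError("each group needs n >= 2")
    both_normal = (
        all(normal_flag) if isinstance(normal_flag, (tuple, list)) else bool(normal_flag)
    )
    if both_normal:
        res = stats.ttest_ind(f, m, equal_var=True)
        return "t-test", float(res.pvalue)
    res = stats.mannwhitneyu(f, m, alternative="two-sided")
    return "rank-sum", float(res.pvalue)


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    normal_flags: tuple[bool, bool] = (True, True),
) -> tuple[float, str, float]:
    """(coefficient, method, p): Pearson when both variables are normal,
    Spearman otherwise; two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation requires n >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("correlation requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedTestError("correlation undefined for zero-variance input")
    if all(normal_flags):
        r, p = stats.pearsonr(x, y)
        return float(r), "pearson", float(p)
    r, p = stats.spearmanr(x, y)
    return float(r), "spearman", float(p)


def size_ranges(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per selected size: min/max/width of the resection area, plus the
    symmetric pairwise interval-overlap matrix.  Sizes without any feasible
    row are omitted (noted by their absence)."""
    ok = table[table["feasible"] & table["size_selected"].notna()]
    if ok.empty:
        raise ValueError("no feasible fits in table")
    rows = []
    for size, g in ok.groupby("size_selected"):
        areas = g["area_mm2"].to_numpy(dtype=float)
        rows.append(
            {
                "size": int(size),
                "n": int(len(areas)),
                "min": float(areas.min()),
                "max": float(areas.max()),
                "width": float(areas.max() - areas.min()),
            }
        )
    ranges = pd.DataFrame(rows).sort_values("size").reset_index(drop=True)
    sizes = ranges["size"].tolist()
    overlap = pd.DataFrame(False, index=sizes, columns=sizes)
    for _, a in ranges.iterrows():
        for _, b in ranges.iterrows():
            hit = a["min"] <= b["max"] and b["min"] <= a["max"]
            overlap.loc[int(a["size"]), int(b["size"])] = bool(hit)
    return ranges, overlap


def frequency_table(table: pd.DataFrame) -> pd.DataFrame:
    """Counts and within-sex proportions of selected sizes (incl. none)."""
    if table.empty:
        raise ValueError("empty table")
    t = table.copy()
    t["size_label"] = t["size_selected"].map(
        lambda s: "none" if pd.isna(s) else str(int(s))
    )
    rows = []
    for sex, g in t.groupby("sex"):
        counts = g["size_label"].value_counts()
        n = int(len(g))
        for label, count in sorted(counts.items()):
            rows.append(
                {
                    "sex": sex,
                    "size": label,
                    "count": int(count),
                    "proportion": float(count / n),
                    "n_sex": n,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StatReport:
    """Serializable summary of the full statistical stage."""

    descriptives: pd.DataFrame
    normality: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    ranges: pd.DataFrame
    overlap: pd.DataFrame
    frequencies: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "alpha": ALPHA,
            "descriptives": self.descriptives.to_dict(orient="records"),
            "normality": self.normality.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "size_ranges": self.ranges.to_dict(orient="records"),
            "overlap": {
                str(i): {str(j): bool(self.overlap.loc[i, j]) for j in self.overlap.columns}
                for i in self.overlap.index
            },
            "frequencies": self.frequencies.to_dict(orient="records"),
            "notes": self.notes,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [
            ("descriptives", self.descriptives),
            ("normality", self.normality),
            ("comparisons", self.comparisons),
            ("correlations", self.correlations),
            ("size_ranges", self.ranges),
            ("frequencies", self.frequencies),
        ]:
            path = directory / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        path = directory / "report.json"
        path.write_text(self.to_json())
        written.append(path)
        return written


def plot_area_by_size(table: pd.DataFrame, path: str | Path) -> None:
    """Strip plot of resection area against selected size, split by sex.

    Mirrors the relationship between tibial contact area and implant size;
    requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = table[table["feasible"] & table["size_selected"].notna()]
    fig, ax = plt.subplots(figsize=(6, 4))
    rng = np.random.default_rng(0)
    markers = {"female": "o", "male": "^"}
    for sex, g in ok.groupby("sex"):
        x = g["size_selected"].to_numpy(dtype=float)
        x = x + rng.uniform(-0.12, 0.12, size=len(x))
        ax.scatter(
            x, g["area_mm2"], s=12, alpha=0.6,
            marker=markers.get(sex, "s"), label=sex,
        )
    ax.set_xlabel("selected component size")
    ax.set_ylabel("resection area [mm$^2$]")
    ax.set_xticks(sorted(ok["size_selected"].dropna().unique()))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def build_report(table: pd.DataFrame) -> StatReport:
    """Run the full statistical stage on a cohort/fit table.

    Expects columns sex, age, height, weight, bmi, area_mm2, size_selected,
    feasible.
    """
    notes: list[str] = []
    desc = descriptives(table, by_sex=True)

    variables = [c for c in _NUMERIC_VARS if c in table.columns]
    norm_rows, flags = [], {}
    for sex, g in table.groupby("sex"):
        for var in variables:
            x = g[var].dropna().to_numpy(dtype=float)
            try:
                p, is_normal = normality_check(x)
            except (ValueError, UndefinedTestError) as exc:
                notes.append(f"normality({sex},{var}) skipped: {exc}")
                p, is_normal = np.nan, False
            flags[(sex, var)] = is_normal
            norm_rows.append(
                {"sex": sex, "variable": var, "p": p, "normal": is_normal}
            )
    normality = pd.DataFrame(norm_rows)

    comp_rows = []
    for var in variables:
        f = table.loc[table["sex"] == "female", var].dropna().to_numpy(dtype=float)
        m = table.loc[table["sex"] == "male", var].dropna().to_numpy(dtype=float)
        if f.size < 2 or m.size < 2:
            notes.append(f"comparison({var}) skipped: group too small")
            continue
        name, p = compare_sexes(
            f, m, (flags.get(("female", var), False), flags.get(("male", var), False))
        )
        comp_rows.append({"variable": var, "test": name, "p": p})
    comparisons = pd.DataFrame(comp_rows)

    corr_rows = []
    for sex, g in table.groupby("sex"):
        for var in ("height", "bmi"):
            if var not in g.columns or "area_mm2" not in g.columns:
                continue
            x = g[var].to_numpy(dtype=float)
            y = g["area_mm2"].to_numpy(dtype=float)
            try:
                r, method, p = correlate(
                    x, y, (flags.get((sex, var), False), flags.get((sex, "area_mm2"), False))
                )
            except (ValueError, UndefinedTestError) as exc:
                notes.append(f"correlation({sex},{var}) skipped: {exc}")
                continue
            corr_rows.append(
                {"sex": sex, "x": var, "y": "area_mm2", "r": r, "method": method, "p": p}
            )
    correlations = pd.DataFrame(corr_rows)

    try:
        ranges, overlap = size_ranges(table)
    except ValueError as exc:
        notes.append(f"size ranges skipped: {exc}")
        ranges = pd.DataFrame(columns=["size", "n", "min", "max", "width"])
        overlap = pd.DataFrame()
    freqs = frequency_table(table)

    return StatReport(
        descriptives=desc,
        normality=normality,
        comparisons=comparisons,
        correlations=correlations,
        ranges=ranges,
        overlap=overlap,
        frequencies=freqs,
        notes=notes,
    )
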