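"""ROI summaries and cohort statistics.

Per subject, the pipeline reduces the pH map to one mean per tissue ROI
(cartilage, meniscus, fluid) over QC-passing voxels, plus one overall mean.
Cohort-level inference uses rank statistics throughout: exact two-sample
rank-sum (Mann-Whitney) tests for between-group contrasts, exact Wilcoxon
signed-rank tests for paired within-subject tissue contrasts, Spearman
correlation for pH against the six KOOS subscales and the pain scale, and
the Shapiro-Wilk statistic as a normality annotation only (the rank tests
are used regardless of it).  No multiple-testing correction is applied; raw
two-sided p-values are reported.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import KOOS_SUBSCALES, LABEL_NAMES, SubjectRecord

__all__ = [
    "SubjectResult",
    "GroupComparison",
    "roi_mean_ph",
    "compare_independent",
    "compare_paired",
    "spearman_correlation",
    "normality_check",
    "cohort_report",
]

TISSUE_LABELS = (1, 2, 3)


@dataclass
class SubjectResult:
    """Per-subject ROI means over QC-passing voxels (None when empty)."""

    subject_id: str
    group: str
    mean_ph: dict[int, float | None]      # per tissue label
    voxel_counts: dict[int, int]
    overall_mean_ph: float | None         # voxel-weighted over all tissues
    overall_count: int


@dataclass
class GroupComparison:
    contrast: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    paired: bool
    method: str
    warning: str | None = None


def roi_mean_ph(ph_map, qc, rois: np.ndarray, tissue_label: int) -> tuple[float | None, int]:
    """Mean pH over QC-passing voxels of one ROI label.

    Returns ``(mean, count)``; the mean is None (missing), never 0, when no
    voxel of the label passes QC.
    """
    ph = ph_map.ph if hasattr(ph_map, "ph") else np.asarray(ph_map)
    passed = qc.passed if hasattr(qc, "passed") else np.asarray(qc, dtype=bool)
    if ph.shape != passed.shape or ph.shape != rois.shape:
        raise ValueError("pH map, QC mask and ROI volume must share a shape")
    sel = passed & (rois == tissue_label) & np.isfinite(ph)
    n = int(sel.sum())
    if n == 0:
        return None, 0
    return float(ph[sel].mean()), n


def compare_independent(values_a, values_b, contrast: str = "") -> GroupComparison:
    """Two-sided rank-sum (Mann-Whitney) test between independent groups.

    Exact null distribution when both arms have <= 12 observations and the
    pooled sample is tie-free; the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both arms must be non-empty")
    warning = None
    if np.array_equal(np.sort(a), np.sort(b)):
        # identical multisets carry no ordering information
        return GroupComparison(contrast, float(a.size * b.size / 2), 1.0,
                               a.size, b.size, False, "rank-sum degenerate")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = a.size <= 12 and b.size <= 12 and not ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    if min(a.size, b.size) < 2:
        warning = "single-observation arm: the exact test cannot reach p < 0.05"
    return GroupComparison(contrast, float(res.statistic),
                           float(min(res.pvalue, 1.0)), a.size, b.size, False,
                           "rank-sum exact" if exact else "rank-sum normal approx",
                           warning)


def compare_paired(values_x, values_y, contrast: str = "") -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on per-subject pairs.

    Zero differences are dropped (standard convention); all-zero differences
    are degenerate and reported as p = 1.  Exact distribution for n <= 25
    non-zero tie-free differences.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return GroupComparison(contrast, 0.0, 1.0, x.size, y.size, True,
                               "signed-rank degenerate")
    ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not ties:
        res = sps.wilcoxon(d, alternative="two-sided", zero_method="wilcox",
                           method="exact")
        stat, p, method = float(res.statistic), float(res.pvalue), "signed-rank exact"
    elif n <= 15:
        # ties in |d|: enumerate all sign patterns on the mid-ranks
        stat, p = _signed_rank_enumeration(d)
        method = "signed-rank exact (enumeration)"
    else:
        res = sps.wilcoxon(d, alternative="two-sided", zero_method="wilcox",
                           method="approx")
        stat, p, method = float(res.statistic), float(res.pvalue), "signed-rank approx"
    warning = None
    if n < 6:
        warning = f"only {n} non-zero pairs: exact two-sided p cannot fall below {2 ** (1 - n):.3g}"
    return GroupComparison(contrast, stat, float(min(p, 1.0)),
                           x.size, y.size, True, method, warning)


def _signed_rank_enumeration(d: np.ndarray) -> tuple[float, float]:
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    n = d.size
    mean = n * (n + 1) / 4.0
    signs = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
    w_null = signs @ ranks
    p = float(np.mean(np.abs(w_null - mean) >= abs(w_obs - mean) - 1e-9))
    return w_obs, p


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rho on mid-ranks with a two-sided p-value.

    Exact permutation p for n <= 9; the t approximation for larger n.
    Constant input has no rank ordering: rho is undefined (NaN, flagged by a
    warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant input: Spearman rho is undefined", stacklevel=2)
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 9:
        # exact permutation distribution of rho under exchangeability
        perms = np.array(list(itertools.permutations(range(n))))
        rho_null = _pearson_rows(rx[perms], ry)
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2)) if abs(rho) < 1 else 0.0
    return rho, min(p, 1.0)


def _pearson_rows(xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    xs = xs - xs.mean(axis=1, keepdims=True)
    y = y - y.mean()
    num = xs @ y
    den = np.sqrt((xs ** 2).sum(axis=1) * (y ** 2).sum())
    return num / den


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p; annotation only, rank tests are always used."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort report


def summarize_subject(record: SubjectRecord, ph_map, qc, rois: np.ndarray) -> SubjectResult:
    """Reduce one subject's pH map to per-tissue and overall ROI means."""
    means: dict[int, float | None] = {}
    counts: dict[int, int] = {}
    total, n_total = 0.0, 0
    for lab in TISSUE_LABELS:
        m, n = roi_mean_ph(ph_map, qc, rois, lab)
        means[lab], counts[lab] = m, n
        if n:
            total += m * n
            n_total += n
    overall = total / n_total if n_total else None
    return SubjectResult(record.subject_id, record.group, means, counts,
                         overall, n_total)


def _subject_frame(results: list[SubjectResult],
                   records: list[SubjectRecord]) -> pd.DataFrame:
    recs = {r.subject_id: r for r in records}
    rows = []
    for res in results:
        rec = recs[res.subject_id]
        row = {
            "subject_id": res.subject_id,
            "group": res.group,
            "agent": rec.agent,
            "overall_mean_ph": res.overall_mean_ph,
            "overall_count": res.overall_count,
        }
        for lab in TISSUE_LABELS:
            row[f"ph_{LABEL_NAMES[lab]}"] = res.mean_ph[lab]
            row[f"n_{LABEL_NAMES[lab]}"] = res.voxel_counts[lab]
        for sub in KOOS_SUBSCALES:
            row[f"koos_{sub}"] = rec.koos[sub]
        row["vaps"] = rec.vaps
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_report(
    results: list[SubjectResult],
    records: list[SubjectRecord],
    out_dir: str | Path,
    make_figures: bool = True,
) -> dict:
    """Write the cohort tables, contrasts, correlations and figures.

    Emits ``subjects.csv`` (per-subject ROI means and scores),
    ``contrasts.json`` (the all-ROI group contrast, three per-tissue group
    contrasts, and the three paired tissue contrasts within each group),
    ``correlations.json`` (overall mean pH against each KOOS subscale and
    the pain scale, with Shapiro-Wilk annotations), and boxplot/scatterplot
    figures.  Subjects missing a score are excluded from correlation rows
    only (logged in the JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = _subject_frame(results, records)
    if df.empty or df["group"].nunique() < 2:
        raise ValueError("need at least one subject per group")
    df.to_csv(out / "subjects.csv", index=False)

    no_oa = df[df.group == "no_oa"]
    oa = df[df.group == "oa"]

    contrasts: list[GroupComparison] = []
    a = no_oa["overall_mean_ph"].dropna()
    b = oa["overall_mean_ph"].dropna()
    contrasts.append(compare_independent(a, b, "all_rois:no_oa_vs_oa"))
    for lab in TISSUE_LABELS:
        col = f"ph_{LABEL_NAMES[lab]}"
        contrasts.append(compare_independent(
            no_oa[col].dropna(), oa[col].dropna(),
            f"{LABEL_NAMES[lab]}:no_oa_vs_oa"))
    for gname, gdf in (("no_oa", no_oa), ("oa", oa)):
        for la, lb in itertools.combinations(TISSUE_LABELS, 2):
            ca, cb = f"ph_{LABEL_NAMES[la]}", f"ph_{LABEL_NAMES[lb]}"
            sub = gdf[[ca, cb]].dropna()
            contrasts.append(compare_paired(
                sub[ca], sub[cb],
                f"{gname}:{LABEL_NAMES[la]}_vs_{LABEL_NAMES[lb]}"))

    correlations = []
    excluded = []
    score_cols = [f"koos_{s}" for s in KOOS_SUBSCALES] + ["vaps"]
    for col in score_cols:
        sub = df[["subject_id", "overall_mean_ph", col]].dropna()
        dropped = sorted(set(df.subject_id) - set(sub.subject_id))
        if dropped:
            excluded.append({"score": col, "subjects": dropped})
        if len(sub) >= 3:
            rho, p = spearman_correlation(sub["overall_mean_ph"], sub[col])
            row = {"score": col, "rho": rho, "p_value": p, "n": int(len(sub))}
        else:
            row = {"score": col, "rho": None, "p_value": None,
                   "n": int(len(sub)),
                   "warning": "fewer than 3 subjects with this score"}
        correlations.append(row)

    normality = {}
    for gname, gdf in (("no_oa", no_oa), ("oa", oa)):
        vals = gdf["overall_mean_ph"].dropna()
        if vals.size >= 3:
            w, p = normality_check(vals)
            normality[gname] = {"W": w, "p_value": p, "n": int(vals.size)}

    report = {
        "contrasts": [asdict(c) for c in contrasts],
        "correlations": correlations,
        "normality": normality,
        "excluded_from_correlations": excluded,
        "group_means": {
            "no_oa": {"mean": float(a.mean()), "sd": float(a.std(ddof=1)) if len(a) > 1 else None, "n": int(len(a))},
            "oa": {"mean": float(b.mean()), "sd": float(b.std(ddof=1)) if len(b) > 1 else None, "n": int(len(b))},
        },
    }
    (out / "contrasts.json").write_text(
        json.dumps({"contrasts": report["contrasts"],
                    "normality": normality}, indent=2))
    (out / "correlations.json").write_text(
        json.dumps({"correlations": correlations,
                    "excluded": excluded}, indent=2))

    if make_figures:
        _figures(df, correlations, out)
    return report


def _figures(df: pd.DataFrame, correlations: list[dict], out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(14, 3.5), sharey=True)
    panels = [("overall_mean_ph", "all ROIs")] + [
        (f"ph_{LABEL_NAMES[lab]}", LABEL_NAMES[lab]) for lab in TISSUE_LABELS
    ]
    for ax, (col, title) in zip(axes, panels):
        data = [df[df.group == g][col].dropna() for g in ("no_oa", "oa")]
        ax.boxplot(data, tick_labels=["no OA", "OA"])
        ax.set_title(title)
    axes[0].set_ylabel("mean pH")
    fig.tight_layout()
    fig.savefig(out / "boxplots_ph_by_group.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(2, 4, figsize=(14, 6.5))
    score_cols = [f"koos_{s}" for s in KOOS_SUBSCALES] + ["vaps"]
    rho_by = {c["score"]: c for c in correlations}
    for ax, col in zip(axes.ravel(), score_cols):
        sub = df[["overall_mean_ph", col, "group"]].dropna()
        for g, color in (("no_oa", "tab:blue"), ("oa", "tab:red")):
            gg = sub[sub.group == g]
            ax.scatter(gg["overall_mean_ph"], gg[col], s=18, c=color, label=g)
        info = rho_by.get(col)
        has_rho = info is not None and info.get("rho") is not None
        ax.set_title(f"{col}  rho={info['rho']:.2f}" if has_rho else col)
        ax.set_xlabel("mean pH")
        ax.set_ylabel(col)
    axes.ravel()[-1].axis("off")
    axes.ravel()[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "scatter_ph_vs_scores.png", dpi=120)
    plt.close(fig)
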