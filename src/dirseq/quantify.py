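"""Allelic activity statistics for DiR-seq count tables.

The screen's statistic chain: scale every sub-library to one million total
reads (so sequencing depth drops out), form the expression level
``E = normalized cDNA / normalized template DNA`` per construct and
replicate, compare the replicate E values of a SNP's two allele constructs
with a two-tailed Student's t-test, and call the SNP regulatory when the
allelic ratio ``R = mean(E_risk) / mean(E_protective)`` clears a fold
threshold (R < 0.8 down, R > 1.2 up) at p < 0.05.  Thresholds are
configurable; the defaults are the screen's published criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_depth",
    "compute_expression",
    "allelic_test",
    "classify_snp",
    "analyze_allelic",
    "replicate_correlation",
    "control_summary",
    "summarize",
    "AllelicResult",
    "NORMALIZED_TOTAL",
]

#: Every sub-library is scaled to this total to remove depth variation.
NORMALIZED_TOTAL = 1_000_000.0

GROUP_COLS = ["sublibrary", "fraction", "replicate"]


def normalize_depth(counts: pd.DataFrame, total: float = NORMALIZED_TOTAL) -> pd.DataFrame:
    """Scale counts so each (sub-library, fraction, replicate) sums to ``total``.

    Adds a real-valued ``norm_count`` column; raw counts are kept.

    Raises
    ------
    ValueError
        If any sub-library group has a zero total (named in the message).
    """
    missing = [c for c in GROUP_COLS + ["count"] if c not in counts.columns]
    if missing:
        raise ValueError(f"count table is missing columns: {missing}")
    out = counts.copy()
    sums = out.groupby(GROUP_COLS)["count"].transform("sum")
    zero = sums <= 0
    if zero.any():
        bad = out.loc[zero, GROUP_COLS].drop_duplicates().itertuples(index=False)
        names = ", ".join("/".join(map(str, b)) for b in bad)
        raise ValueError(f"zero-total sub-library group(s): {names}")
    out["norm_count"] = out["count"] * (total / sums)
    return out


def compute_expression(
    counts: pd.DataFrame, min_template: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression level E per (construct, replicate), with exclusions.

    E = normalized cDNA count / normalized template-DNA count. A construct
    whose *raw* template count falls below ``min_template`` in any replicate
    is excluded entirely (reason ``low_template``); a construct with zero
    cDNA in some replicate is excluded with reason ``zero_cdna`` so that
    E > 0 holds for everything retained.

    Returns (expression long table, exclusion table with reasons).
    """
    if "norm_count" not in counts.columns:
        counts = normalize_depth(counts)
    wide = counts.pivot_table(
        index=["construct_id", "replicate"], columns="fraction",
        values=["count", "norm_count"], aggfunc="sum", fill_value=0.0,
    )
    for fraction in ("template_dna", "cdna"):
        if ("count", fraction) not in wide.columns:
            raise ValueError(f"count table lacks fraction {fraction!r}")

    raw_template = wide[("count", "template_dna")].unstack("replicate")
    raw_cdna = wide[("count", "cdna")].unstack("replicate")
    low = raw_template.min(axis=1) < min_template
    zero_cdna = (raw_cdna <= 0).any(axis=1) & ~low
    excluded = pd.concat([
        pd.DataFrame({"construct_id": low.index[low], "reason": "low_template"}),
        pd.DataFrame({"construct_id": zero_cdna.index[zero_cdna], "reason": "zero_cdna"}),
    ], ignore_index=True)

    keep = ~(low | zero_cdna)
    kept_ids = set(low.index[keep])
    expr = pd.DataFrame({
        "construct_id": wide.index.get_level_values("construct_id"),
        "replicate": wide.index.get_level_values("replicate"),
        "expression": (
            wide[("norm_count", "cdna")] / wide[("norm_count", "template_dna")]
        ).to_numpy(),
    })
    expr = expr[expr["construct_id"].isin(kept_ids)].reset_index(drop=True)
    return expr, excluded


def allelic_test(
    e_risk, e_protective, equal_var: bool = True, log_scale: bool = False,
) -> tuple[float, float]:
    """Allelic ratio and two-tailed t-test p-value for one SNP.

    R = mean(E_risk) / mean(E_protective) on the raw scale; the t-test
    (classic equal-variance Student by default, Welch via ``equal_var=False``)
    runs on the raw replicate values, or on log10 values with ``log_scale``.

    Degenerate variance conventions: both groups constant and equal -> p = 1;
    both constant but different -> p = 0 with a warning.

    Raises
    ------
    ValueError
        If either group has fewer than 2 replicate values.
    """
    a = np.asarray(e_risk, dtype=float)
    b = np.asarray(e_protective, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("allelic test needs >= 2 replicates per allele")
    ratio = float(a.mean() / b.mean())
    ta, tb = (np.log10(a), np.log10(b)) if log_scale else (a, b)
    if ta.var(ddof=1) == 0 and tb.var(ddof=1) == 0:
        if ta.mean() == tb.mean():
            return ratio, 1.0
        warnings.warn(
            "zero variance in both replicate groups with unequal means; p set to 0",
            RuntimeWarning, stacklevel=2,
        )
        return ratio, 0.0
    p = float(stats.ttest_ind(ta, tb, equal_var=equal_var).pvalue)
    return ratio, p


def classify_snp(
    ratio: float, p: float, lo: float = 0.8, hi: float = 1.2, alpha: float = 0.05,
) -> str:
    """Regulatory call from the allelic ratio and p-value (strict inequalities).

    down: R < lo and p < alpha; up: R > hi and p < alpha; otherwise ns.
    """
    if ratio <= 0:
        raise ValueError(f"allelic ratio must be positive, got {ratio}")
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    if p < alpha and ratio < lo:
        return "down"
    if p < alpha and ratio > hi:
        return "up"
    return "ns"


@dataclass
class AllelicResult:
    """Per-SNP screen outcome with the replicate-level evidence retained."""

    snp_id: str
    ratio: float
    p_value: float
    klass: str
    e_risk: tuple[float, ...]
    e_protective: tuple[float, ...]


def analyze_allelic(
    counts: pd.DataFrame, manifest: pd.DataFrame,
    min_template: int = 10, lo: float = 0.8, hi: float = 1.2,
    alpha: float = 0.05, equal_var: bool = True, log_scale: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Full count-table -> per-SNP results pipeline.

    Normalizes depth, forms expression levels, and tests each SNP whose two
    allele constructs both survive the exclusions. Controls do not enter the
    allelic test. Returns a DataFrame with one row per tested SNP: snp_id,
    ratio, p_value, class, and the per-replicate E values (comma-joined).
    With ``fdr=True`` classification uses Benjamini-Hochberg adjusted
    p-values (added as ``p_adj``) instead of raw per-SNP p-values, which is
    not part of the screen's published criterion but offered as an option.
    """
    normalized = normalize_depth(counts)
    expr, excluded = compute_expression(normalized, min_template=min_template)
    alleles = manifest[manifest["allele_class"].isin(["risk", "protective"])]
    cls_of = dict(zip(alleles["construct_id"], alleles["allele_class"]))
    snp_of = dict(zip(alleles["construct_id"], alleles["snp_id"]))
    expr = expr[expr["construct_id"].isin(cls_of)].copy()
    expr["snp_id"] = expr["construct_id"].map(snp_of)
    expr["allele_class"] = expr["construct_id"].map(cls_of)

    rows = []
    for snp_id, grp in expr.sort_values("replicate").groupby("snp_id", sort=True):
        e_risk = grp.loc[grp["allele_class"] == "risk", "expression"].to_numpy()
        e_prot = grp.loc[grp["allele_class"] == "protective", "expression"].to_numpy()
        if e_risk.size < 2 or e_prot.size < 2:
            continue
        ratio, p = allelic_test(e_risk, e_prot, equal_var=equal_var,
                                log_scale=log_scale)
        rows.append({
            "snp_id": snp_id,
            "ratio": ratio,
            "p_value": p,
            "e_risk": ",".join(f"{v:.6g}" for v in e_risk),
            "e_protective": ",".join(f"{v:.6g}" for v in e_prot),
        })
    results = pd.DataFrame(
        rows, columns=["snp_id", "ratio", "p_value", "e_risk", "e_protective"],
    )
    p_for_class = results["p_value"].to_numpy()
    if fdr and len(results):
        results["p_adj"] = stats.false_discovery_control(p_for_class)
        p_for_class = results["p_adj"].to_numpy()
    results["class"] = [
        classify_snp(r, p, lo=lo, hi=hi, alpha=alpha)
        for r, p in zip(results["ratio"], p_for_class)
    ]
    cols = ["snp_id", "ratio", "p_value"] + (["p_adj"] if fdr else []) + \
        ["class", "e_risk", "e_protective"]
    results = results[cols] if len(results) else pd.DataFrame(columns=cols)
    results.attrs["excluded"] = excluded
    return results


def replicate_correlation(
    expr: pd.DataFrame, log: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation between replicate expression profiles.

    Correlates (optionally log10) expression across constructs for every
    replicate pair; a constant vector gives an undefined r, reported as NaN.
    Returns (r matrix, p matrix) indexed by replicate.
    """
    wide = expr.pivot_table(index="construct_id", columns="replicate",
                            values="expression")
    if wide.shape[1] < 2:
        raise ValueError("replicate correlation needs >= 2 replicates")
    vals = np.log10(wide.to_numpy()) if log else wide.to_numpy()
    reps = list(wide.columns)
    r = pd.DataFrame(np.eye(len(reps)), index=reps, columns=reps)
    p = pd.DataFrame(np.zeros((len(reps), len(reps))), index=reps, columns=reps)
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            x, y = vals[:, i], vals[:, j]
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x[mask], y[mask])
                rij, pij = float(res.statistic), float(res.pvalue)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def control_summary(counts: pd.DataFrame, manifest: pd.DataFrame,
                    min_template: int = 10) -> pd.DataFrame:
    """Expression of the control constructs, relative to the promoter control.

    Returns one row per (control construct, replicate) with the raw
    expression level and its value relative to the promoter-only control's
    replicate mean.
    """
    expr, _ = compute_expression(normalize_depth(counts), min_template=min_template)
    controls = manifest.loc[
        manifest["allele_class"].isin(["promoter_control", "blank_control"]),
        "construct_id",
    ]
    sub = expr[expr["construct_id"].isin(controls)].copy()
    promoter = sub.loc[sub["construct_id"] == "promoter_control", "expression"]
    ref = promoter.mean() if len(promoter) else float("nan")
    sub["relative_to_promoter"] = sub["expression"] / ref
    return sub.reset_index(drop=True)


def summarize(results: pd.DataFrame) -> dict[str, int]:
    """Counts of up/down/ns regulatory calls."""
    c = results["class"].value_counts()
    return {k: int(c.get(k, 0)) for k in ("up", "down", "ns")}
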