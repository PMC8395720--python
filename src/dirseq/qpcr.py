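"""qPCR quantification: percent input, fold enrichment, ddCt, allele ratios,
and wild-type fraction after genome editing.

All formulas assume exponential amplification with a per-cycle efficiency
(default 2.0, perfect doubling; configurable per call).  Ct means are taken
across technical replicates before transformation; the standard deviation of
a transformed quantity is propagated by the delta method,
``sd(f) = f * ln(eff) * sd(dCt)``.

Assays covered
--------------
percent input
    ChIP/FAIRE recovery relative to the diluted input chromatin:
    ``100 * eff^((Ct_input - log_eff(1/input_fraction)) - Ct_IP)``.
fold enrichment
    Percent input of the target region over a control region.
relative expression (ddCt)
    Target gene vs a reference gene (e.g. ACTB), sample vs calibrator.
allele-specific ratio
    Allele A vs allele B Ct difference, corrected by the same difference on
    a heterozygous genomic calibrator (3'-terminal allele-specific primers
    amplify selectively but with primer-specific efficiency offsets; the
    calibrator cancels them).
wild-type fraction (getPCR)
    Edited-pool "watching" amplicon over a distal control amplicon,
    referenced to unedited DNA; returns the percentage of wild-type DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "EnrichmentResult",
    "percent_input",
    "percent_input_sd",
    "fold_enrichment",
    "relative_expression",
    "relative_expression_sd",
    "allele_ratio",
    "wt_fraction",
    "read_plate",
    "summarize_plate",
]

ROLES = ("IP", "input", "FAIRE", "sample", "calibrator")


@dataclass
class QpcrMeasurement:
    """One well group: replicate Ct values for a (sample, target, role)."""

    sample: str
    target: str
    role: str
    cts: tuple[float, ...]
    input_fraction: float | None = None
    assay: str = ""

    def __post_init__(self) -> None:
        self.cts = tuple(float(c) for c in self.cts)
        if not self.cts or any(not math.isfinite(c) for c in self.cts):
            raise ValueError(f"{self.sample}/{self.target}: Ct values must be finite")
        if self.role not in ROLES:
            raise ValueError(f"unknown qPCR role {self.role!r}")
        if self.role == "input":
            if self.input_fraction is None or not 0 < self.input_fraction <= 1:
                raise ValueError(
                    f"{self.sample}/{self.target}: input wells need "
                    f"input_fraction in (0, 1], got {self.input_fraction}"
                )

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))

    @property
    def sd_ct(self) -> float:
        return float(np.std(self.cts, ddof=1)) if len(self.cts) > 1 else 0.0


@dataclass
class EnrichmentResult:
    region: str
    percent_input: float
    fold_over_control: float
    sd: float = 0.0


def _log_eff(x: float, efficiency: float) -> float:
    return math.log(x) / math.log(efficiency)


def percent_input(
    ct_ip: float, ct_input: float, input_fraction: float, efficiency: float = 2.0,
) -> float:
    """IP recovery as a percentage of the dilution-adjusted input.

    The input well measures only ``input_fraction`` of the chromatin, so its
    Ct is shifted earlier by ``log_eff(1/input_fraction)`` cycles before the
    comparison: ``100 * eff^((Ct_input - log_eff(1/f)) - Ct_IP)``.
    """
    if input_fraction <= 0:
        raise ValueError(f"input_fraction must be > 0, got {input_fraction}")
    adjusted = ct_input - _log_eff(1.0 / input_fraction, efficiency)
    return 100.0 * efficiency ** (adjusted - ct_ip)


def percent_input_sd(
    cts_ip, cts_input, input_fraction: float, efficiency: float = 2.0,
) -> tuple[float, float]:
    """Percent input from replicate Cts, with delta-method SD.

    The Ct difference's variance is the sum of the two replicate variances;
    ``sd = percent * ln(eff) * sd(dCt)``.
    """
    ip = np.asarray(cts_ip, dtype=float)
    inp = np.asarray(cts_input, dtype=float)
    value = percent_input(ip.mean(), inp.mean(), input_fraction, efficiency)
    var = ip.var(ddof=1) + inp.var(ddof=1)
    return value, value * math.log(efficiency) * math.sqrt(var)


def fold_enrichment(target_percent_input: float, control_percent_input: float) -> float:
    """Target-region enrichment normalized to a control region."""
    if control_percent_input <= 0:
        raise ValueError("control region percent input must be > 0")
    return target_percent_input / control_percent_input


def relative_expression(
    ct_target_sample: float, ct_ref_sample: float,
    ct_target_calibrator: float, ct_ref_calibrator: float,
    efficiency: float = 2.0,
) -> float:
    """ddCt relative expression: target vs reference, sample vs calibrator."""
    for name, v in (("ct_target_calibrator", ct_target_calibrator),
                    ("ct_ref_calibrator", ct_ref_calibrator)):
        if v is None or not math.isfinite(v):
            raise ValueError(f"missing calibrator Ct: {name}")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return efficiency ** (-ddct)


def relative_expression_sd(
    cts_target_sample, cts_ref_sample, cts_target_calibrator, cts_ref_calibrator,
    efficiency: float = 2.0,
) -> tuple[float, float]:
    """ddCt fold with delta-method SD over all four replicate groups."""
    groups = [np.asarray(g, dtype=float) for g in (
        cts_target_sample, cts_ref_sample, cts_target_calibrator, cts_ref_calibrator
    )]
    fold = relative_expression(*(g.mean() for g in groups), efficiency=efficiency)
    var = sum(g.var(ddof=1) for g in groups)
    return fold, fold * math.log(efficiency) * math.sqrt(var)


def allele_ratio(
    ct_allele_a: float, ct_allele_b: float,
    ct_allele_a_calibrator: float, ct_allele_b_calibrator: float,
    efficiency: float = 2.0,
) -> float:
    """Allele A / allele B abundance from allele-specific qPCR.

    The calibrator (genomic/input DNA from the same heterozygous source,
    where the true ratio is 1) corrects allele-primer efficiency differences:
    ``eff^-[(CtA - CtB)_sample - (CtA - CtB)_calibrator]``.
    """
    for name, v in (("ct_allele_a_calibrator", ct_allele_a_calibrator),
                    ("ct_allele_b_calibrator", ct_allele_b_calibrator)):
        if v is None or not math.isfinite(v):
            raise ValueError(
                f"missing calibrator Ct ({name}); the calibrator must be "
                "heterozygous with both alleles measured"
            )
    d = (ct_allele_a - ct_allele_b) - (ct_allele_a_calibrator - ct_allele_b_calibrator)
    return efficiency ** (-d)


def wt_fraction(
    ct_watch_edited: float, ct_control_edited: float,
    ct_watch_ref: float, ct_control_ref: float,
    efficiency: float = 2.0,
) -> float:
    """Percentage of wild-type DNA in an edited pool (getPCR).

    The "watching" amplicon spans the edit site and only amplifies intact
    (wild-type) templates; a control amplicon away from the cut site
    normalizes DNA amounts, and an unedited reference sample anchors 100%:
    ``100 * eff^-[(Ct_watch - Ct_control)_edited - (Ct_watch - Ct_control)_ref]``.
    """
    for name, v in (("ct_watch_ref", ct_watch_ref),
                    ("ct_control_ref", ct_control_ref)):
        if v is None or not math.isfinite(v):
            raise ValueError(f"missing unedited reference Ct: {name}")
    d = (ct_watch_edited - ct_control_edited) - (ct_watch_ref - ct_control_ref)
    return 100.0 * efficiency ** (-d)


# ---------------------------------------------------------------------------
# Plate I/O
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ["sample", "target", "role", "ct", "replicate"]


def read_plate(path) -> pd.DataFrame:
    """Read a plate-export TSV: sample, target, role, ct, replicate
    [, input_fraction]."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate export is missing columns: {sorted(missing)}")
    bad = ~df["role"].isin(ROLES)
    if bad.any():
        raise ValueError(f"unknown roles in plate export: {sorted(df.loc[bad, 'role'].unique())}")
    return df


def summarize_plate(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of Ct per (sample, target, role) well group."""
    out = (
        df.groupby(["sample", "target", "role"], as_index=False)
        .agg(mean_ct=("ct", "mean"), sd_ct=("ct", lambda s: s.std(ddof=1)),
             n=("ct", "size"))
    )
    out["sd_ct"] = out["sd_ct"].fillna(0.0)
    return out
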