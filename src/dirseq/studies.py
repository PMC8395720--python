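"""Whole-pipeline validation studies.

These drive the simulator and the analysis end to end under controlled
conditions: exact count recovery at zero sequencing error, the false-call
rate of the regulatory screen under the null, recovery of planted allelic
effects, and a power curve over allelic fold sizes.  They are used by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import panel as panel_mod
from . import quantify as quant_mod
from . import readproc
from . import simulate as sim_mod

__all__ = [
    "oracle_equivalence",
    "null_call_rate",
    "planted_recovery",
    "power_curve",
    "default_panel",
]


def default_panel(n_snps: int = 213, seed: int = 0):
    """The study panel: synthetic SNPs, full construct set, default scheme."""
    snps = panel_mod.synthesize_snps(n_snps, seed=seed)
    scheme = panel_mod.build_scheme()
    constructs = panel_mod.build_panel(snps, scheme=scheme, tag_seed=seed)
    return snps, scheme, constructs, panel_mod.manifest_frame(constructs)


def oracle_equivalence(
    n_seeds: int = 3, reads_total: int = 200_000, n_snps: int = 213,
    seed: int = 0, workdir=None,
) -> dict:
    """Exact-recovery check: ε = 0 simulate -> FASTQ -> merge -> demux -> count.

    ``reads_total`` is the approximate number of read pairs per run, split
    over 6 libraries (3 replicates x 2 fractions) with one pair per amplicon
    per molecule.  Returns per-seed exact-match fractions (percent of
    (construct, fraction, replicate) cells whose pipeline count equals the
    simulator's realized count) and drop-out totals.
    """
    _, scheme, constructs, manifest = default_panel(n_snps, seed=seed)
    reads_per_library = max(1, reads_total // (6 * len(scheme.amplicons)))
    match_pct = []
    dropped = 0
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for k in range(n_seeds):
            design = sim_mod.SimulationDesign(
                panel=constructs, scheme=scheme,
                reads_per_library=reads_per_library,
                epsilon=0.0, seed=seed + 10_000 + k,
            )
            truth = sim_mod.simulate_counts(design)
            libraries = sim_mod.emit_fastq(truth, Path(tmp) / f"run{k}")
            table = readproc.count_run(libraries, scheme, manifest)
            merged = table.counts.merge(
                truth.counts, on=["construct_id", "fraction", "replicate"],
                suffixes=("_pipe", "_truth"), how="outer",
            )
            pipe = merged["count_pipe"].fillna(0).to_numpy()
            true = merged["count_truth"].fillna(0).to_numpy()
            match_pct.append(100.0 * float((pipe == true).mean()))
            dropped += int(
                table.unassigned[list(readproc.UNASSIGNED_REASONS)].to_numpy().sum()
            )
    return {
        "match_pct": match_pct,
        "all_exact": all(m == 100.0 for m in match_pct),
        "reads_per_library": reads_per_library,
        "dropped_pairs": dropped,
        "n_cells": len(constructs) * 6,
    }


def _screen_once(constructs, scheme, manifest, theta, seed,
                 reads_per_library=1_000_000.0, replicate_cv=0.10,
                 phi=0.05) -> pd.DataFrame:
    design = sim_mod.SimulationDesign(
        panel=constructs, scheme=scheme, reads_per_library=reads_per_library,
        replicate_cv=replicate_cv, phi=phi, theta=theta, seed=seed,
    )
    counts = sim_mod.truth_to_count_table(sim_mod.simulate_counts(design))
    return quant_mod.analyze_allelic(counts, manifest)


def null_call_rate(
    n_runs: int = 20, n_snps: int = 200, seed: int = 0,
    replicate_cv: float = 0.10, phi: float = 0.05,
) -> dict:
    """Fraction of null SNPs (all allelic folds = 1) called regulatory.

    The screen applies a per-SNP t-test at alpha = 0.05 plus a fold gate, so
    the false-call rate should sit at or below alpha; ``bound`` is alpha plus
    a 95% binomial allowance for the finite number of simulated SNP tests.
    """
    _, scheme, constructs, manifest = default_panel(n_snps, seed=seed)
    calls = tested = 0
    for run in range(n_runs):
        res = _screen_once(constructs, scheme, manifest, theta={},
                           seed=seed + 20_000 + run,
                           replicate_cv=replicate_cv, phi=phi)
        s = quant_mod.summarize(res)
        calls += s["up"] + s["down"]
        tested += len(res)
    alpha = 0.05
    rate = calls / tested
    bound = alpha + 1.96 * np.sqrt(alpha * (1 - alpha) / tested)
    return {"rate": rate, "n_tests": tested, "alpha": alpha, "bound": bound}


def planted_recovery(n_snps: int = 200, seed: int = 0) -> dict:
    """Recovery of strong planted effects (folds 2.0 / 0.5) at near-zero noise."""
    snps, scheme, constructs, manifest = default_panel(n_snps, seed=seed)
    theta = {s.snp_id: (2.0 if i % 2 == 0 else 0.5) for i, s in enumerate(snps)}
    res = _screen_once(constructs, scheme, manifest, theta,
                       seed=seed + 30_000, replicate_cv=0.0, phi=0.0)
    want = res["snp_id"].map(lambda s: "up" if theta[s] == 2.0 else "down")
    return {
        "recovery_pct": 100.0 * float((res["class"] == want).mean()),
        "n_planted": len(res),
    }


def power_curve(
    folds=(1.1, 1.2, 1.3, 1.5, 2.0), n_runs: int = 5, n_snps: int = 200,
    seed: int = 0, replicate_cv: float = 0.10, phi: float = 0.05,
) -> pd.DataFrame:
    """Detection power per allelic fold under the noisy study conditions."""
    snps, scheme, constructs, manifest = default_panel(n_snps, seed=seed)
    rows = []
    for fold in folds:
        theta = {s.snp_id: fold for s in snps}
        want = "up" if fold > 1 else ("down" if fold < 1 else None)
        hits = n = 0
        for run in range(n_runs):
            res = _screen_once(constructs, scheme, manifest, theta,
                               seed=seed + 40_000 + run,
                               replicate_cv=replicate_cv, phi=phi)
            if want is None:
                hits += (res["class"] != "ns").sum()
            else:
                hits += (res["class"] == want).sum()
            n += len(res)
        rows.append({"fold": fold, "power": hits / n, "n_tests": n})
    return pd.DataFrame(rows)
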