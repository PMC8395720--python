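"""Synthetic DiR-seq data generator.

Produces ground-truth count tables and paired-end FASTQ files with the
statistical structure the downstream analysis assumes: per-construct plasmid
abundance variation (log-normal), per-SNP allelic activity effects on the
cDNA fraction, replicate-to-replicate expression noise, overdispersed counts,
and per-base sequencing error.  Every read pair is traceable to its construct
through a provenance sidecar, which serves as the exact oracle for pipeline
tests.

Count model
-----------
Template-DNA counts are proportional to plasmid abundance; cDNA counts are
proportional to abundance x construct activity x the SNP's allelic fold
(risk-allele constructs only) x a log-normal replicate factor.  Realized
counts within one library are drawn as a gamma-weighted multinomial
conditioned on a Poisson library size: marginally this behaves like a
negative binomial with dispersion ``phi`` (plain multinomial at ``phi = 0``)
while guaranteeing that counts sum exactly to the drawn library size.

Each realized molecule count yields one read pair per amplicon: read 1 is the
first ``read_len`` bases of the amplicon molecule, read 2 the reverse
complement of its last ``read_len`` bases, so pairs overlap in the middle and
can be merged.  The amplicon molecule carries the sub-library's forward
primer at the 5' end (first amplicon) or the reverse primer's complement at
the 3' end (second amplicon); the sequencing index is recorded in the read
header, Illumina style.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Construct, SubLibraryScheme, reverse_complement

__all__ = [
    "SimulationDesign",
    "TruthTable",
    "simulate_counts",
    "emit_fastq",
    "truth_to_count_table",
    "FRACTIONS",
]

FRACTIONS = ("template_dna", "cdna")

Q_BASE = chr(30 + 33)   # constant call quality Q30
Q_ERR = chr(15 + 33)    # errored bases emitted at Q15
Q_N = chr(2 + 33)       # the masked leading-N cycle


@dataclass
class SimulationDesign:
    """Study conditions for one simulated DiR-seq experiment.

    Parameters
    ----------
    panel : list of Construct
        The reporter panel (from :func:`dirseq.panel.build_panel`).
    scheme : SubLibraryScheme
        Sub-library addressing shared with the read processor.
    n_replicates : int
        Biological replicates per fraction (paper design: 3).
    reads_per_library : float
        Expected molecules per (fraction, replicate) library; each molecule
        yields one read pair per amplicon. The screen targeted about 1e6
        reads per library.
    mu_abund, sigma_abund : float
        Log-normal plasmid abundance parameters (log scale).
    theta : dict
        Per-SNP allelic fold effect, activity(risk) / activity(protective);
        SNPs absent from the dict have fold 1 (no allelic effect).
    baseline_activity : dict
        Optional per-construct activity overrides (default 1.0).
    replicate_cv : float
        Coefficient of variation of the log-normal replicate factor applied
        to cDNA rates (models transfection/expression variability).
    phi : float
        Count overdispersion; 0 gives multinomial (Poisson-like) counts.
    epsilon : float
        Per-base substitution error rate, in [0, 0.1].
    leading_n_frac : float
        Fraction of read-1 records whose first cycle is emitted as ``N``
        (the dark first cycle that must not be trimmed downstream).
    shared_pool : bool
        If True (default) one plasmid pool is transfected into every
        replicate; if False the pool abundances are re-drawn per replicate.
    seed : int
        Seed for count simulation.
    """

    panel: list[Construct]
    scheme: SubLibraryScheme
    n_replicates: int = 3
    reads_per_library: float = 1_000_000
    mu_abund: float = 0.0
    sigma_abund: float = 0.5
    theta: dict[str, float] = field(default_factory=dict)
    baseline_activity: dict[str, float] = field(default_factory=dict)
    replicate_cv: float = 0.0
    phi: float = 0.0
    epsilon: float = 0.0
    leading_n_frac: float = 0.05
    shared_pool: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reads_per_library", "mu_abund", "sigma_abund",
                     "replicate_cv", "phi", "epsilon", "leading_n_frac"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if any(not math.isfinite(v) or v <= 0 for v in self.theta.values()):
            raise ValueError("allelic folds theta must be finite and > 0")
        if not 0 <= self.epsilon <= 0.1:
            raise ValueError(f"epsilon must be in [0, 0.1], got {self.epsilon}")
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")
        if self.reads_per_library < 1:
            raise ValueError("reads_per_library must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def treatments(self) -> pd.DataFrame:
        """Assign each (fraction, replicate) library to a (primer set, index).

        Libraries are enumerated over fractions x replicates and mapped to
        primer sets first, then indexes, mirroring how up to 288 treatments
        are addressed in one sequencing run.
        """
        n_sets = len(self.scheme.primer_sets)
        rows = []
        t = 0
        for fraction in FRACTIONS:
            for rep in range(1, self.n_replicates + 1):
                ps, ix = t % n_sets, t // n_sets
                if ix >= len(self.scheme.indexes):
                    raise ValueError("more libraries than addressable treatments")
                rows.append({
                    "sublibrary": f"p{ps:02d}_i{ix:02d}",
                    "primer_set": ps,
                    "index": ix,
                    "index_seq": self.scheme.indexes[ix],
                    "fraction": fraction,
                    "replicate": rep,
                })
                t += 1
        return pd.DataFrame(rows)


@dataclass
class TruthTable:
    """Ground truth: expected and realized counts per (construct, library)."""

    counts: pd.DataFrame  # columns: construct_id, fraction, replicate, expected, count
    treatments: pd.DataFrame
    design: SimulationDesign

    def library_sizes(self) -> pd.Series:
        return self.counts.groupby(["fraction", "replicate"])["count"].sum()

    def write(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one log-normal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def simulate_counts(design: SimulationDesign) -> TruthTable:
    """Draw the ground-truth count table for every library in the design."""
    rng = np.random.default_rng(design.seed)
    panel = design.panel
    n = len(panel)
    ids = [c.construct_id for c in panel]

    activity = np.array([
        design.baseline_activity.get(c.construct_id, 1.0) for c in panel
    ])
    fold = np.array([
        design.theta.get(c.snp_id, 1.0) if c.allele_class == "risk" else 1.0
        for c in panel
    ])

    shared_abund = rng.lognormal(design.mu_abund, design.sigma_abund, size=n)
    rows = []
    for rep in range(1, design.n_replicates + 1):
        abund = shared_abund if design.shared_pool else rng.lognormal(
            design.mu_abund, design.sigma_abund, size=n
        )
        rep_factor = _lognormal_factor(rng, design.replicate_cv, n)
        for fraction in FRACTIONS:
            if fraction == "template_dna":
                w = abund.copy()
            else:
                w = abund * activity * fold * rep_factor
            p = w / w.sum()
            expected = design.reads_per_library * p
            lib_size = rng.poisson(design.reads_per_library)
            if design.phi > 0:
                g = rng.gamma(1.0 / design.phi, design.phi, size=n)
                pw = w * g
                pw = pw / pw.sum()
            else:
                pw = p
            counts = rng.multinomial(lib_size, pw)
            rows.append(pd.DataFrame({
                "construct_id": ids,
                "fraction": fraction,
                "replicate": rep,
                "expected": expected,
                "count": counts,
            }))
    table = pd.concat(rows, ignore_index=True)
    return TruthTable(counts=table, treatments=design.treatments(), design=design)


def truth_to_count_table(truth: TruthTable) -> pd.DataFrame:
    """Recast a TruthTable as the long-format CountTable the quantifier reads.

    Bypasses FASTQ emission and read processing; used for count-level studies
    (power, calibration) where sequencing is not the question.
    """
    df = truth.counts.merge(
        truth.treatments[["sublibrary", "fraction", "replicate"]],
        on=["fraction", "replicate"],
    )
    return df[["sublibrary", "fraction", "replicate", "construct_id", "count"]].copy()


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

def _amplicon_molecule(construct: Construct, scheme: SubLibraryScheme,
                       amplicon: int, primer_set: int) -> str:
    """The amplified molecule: reporter slice with the set's primer at one end."""
    start, end = scheme.amplicons[amplicon]
    fwd, rev = scheme.primer_sets[primer_set]
    seq = construct.reporter_seq[start:end]
    if amplicon == 0:
        return fwd + seq[len(fwd):]
    return seq[:-len(rev)] + reverse_complement(rev)


def _apply_errors(seq: str, qual: str, positions: np.ndarray,
                  rng: np.random.Generator) -> tuple[str, str]:
    s, q = list(seq), list(qual)
    for pos in positions:
        old = s[pos]
        choices = [b for b in "ACGT" if b != old]
        s[pos] = choices[rng.integers(0, 3)]
        q[pos] = Q_ERR
    return "".join(s), "".join(q)


def emit_fastq(
    truth: TruthTable,
    outdir,
    read_len: int = 150,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write paired gzip FASTQ per sub-library, plus provenance and truth TSVs.

    Returns a manifest DataFrame (one row per library) with the file paths.
    Reads within a pair overlap by ``2 * read_len - amplicon_length`` bases.
    Deterministic and byte-identical for a fixed seed (gzip headers carry no
    timestamps).

    Raises
    ------
    ValueError
        If ``read_len`` is too short for the paired reads to overlap.
    """
    design = truth.design
    scheme = design.scheme
    max_amp = max(e - s for s, e in scheme.amplicons)
    if 2 * read_len <= max_amp:
        raise ValueError(
            f"read_len {read_len} gives no overlap on a {max_amp} bp amplicon"
        )
    rng = np.random.default_rng(design.seed if seed is None else seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel_by_id = {c.construct_id: c for c in design.panel}

    counts = truth.counts
    manifest_rows = []
    prov_chunks = []
    base_qual = Q_BASE * read_len

    for trt in truth.treatments.itertuples():
        lib = counts[(counts["fraction"] == trt.fraction)
                     & (counts["replicate"] == trt.replicate)]
        stem = f"{trt.sublibrary}_{trt.fraction}_rep{trt.replicate}"
        r1_path = outdir / f"{stem}_R1.fastq.gz"
        r2_path = outdir / f"{stem}_R2.fastq.gz"
        r1_lines: list[str] = []
        r2_lines: list[str] = []
        prov_ids: list[str] = []
        prov_cid: list[str] = []
        prov_amp: list[int] = []
        serial = 0
        for row in lib.itertuples():
            n_copies = int(row.count)
            if n_copies == 0:
                continue
            construct = panel_by_id[row.construct_id]
            for amp in range(len(scheme.amplicons)):
                mol = _amplicon_molecule(construct, scheme, amp, trt.primer_set)
                r1 = mol[:read_len]
                r2 = reverse_complement(mol)[:read_len]
                n_err = rng.binomial(read_len, design.epsilon, size=(n_copies, 2))
                lead_n = rng.random(n_copies) < design.leading_n_frac
                for i in range(n_copies):
                    s1, q1, s2, q2 = r1, base_qual, r2, base_qual
                    if n_err[i, 0]:
                        pos = rng.choice(read_len, size=n_err[i, 0], replace=False)
                        s1, q1 = _apply_errors(s1, q1, pos, rng)
                    if n_err[i, 1]:
                        pos = rng.choice(read_len, size=n_err[i, 1], replace=False)
                        s2, q2 = _apply_errors(s2, q2, pos, rng)
                    if lead_n[i]:
                        s1 = "N" + s1[1:]
                        q1 = Q_N + q1[1:]
                    rid = f"sim:{stem}:{serial}"
                    serial += 1
                    header = f"@{rid} {{mate}}:N:0:{trt.index_seq}"
                    r1_lines.append(f"{header.format(mate=1)}\n{s1}\n+\n{q1}\n")
                    r2_lines.append(f"{header.format(mate=2)}\n{s2}\n+\n{q2}\n")
                    prov_ids.append(rid)
                    prov_cid.append(construct.construct_id)
                    prov_amp.append(amp)
        for path, lines in ((r1_path, r1_lines), (r2_path, r2_lines)):
            with open(path, "wb") as raw, gzip.GzipFile(
                filename="", mode="wb", fileobj=raw, compresslevel=1, mtime=0
            ) as gz:
                gz.write("".join(lines).encode())
        prov_chunks.append(pd.DataFrame({
            "read_id": prov_ids,
            "construct_id": prov_cid,
            "amplicon": prov_amp,
            "sublibrary": trt.sublibrary,
            "fraction": trt.fraction,
            "replicate": trt.replicate,
        }))
        manifest_rows.append({
            "sublibrary": trt.sublibrary,
            "primer_set": trt.primer_set,
            "index": trt.index,
            "index_seq": trt.index_seq,
            "fraction": trt.fraction,
            "replicate": trt.replicate,
            "r1": str(r1_path),
            "r2": str(r2_path),
            "n_pairs": serial,
        })

    provenance = (
        pd.concat(prov_chunks, ignore_index=True) if prov_chunks
        else pd.DataFrame(columns=["read_id", "construct_id", "amplicon",
                                   "sublibrary", "fraction", "replicate"])
    )
    provenance.to_csv(outdir / "provenance.tsv.gz", sep="\t", index=False)
    truth.counts.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    truth.treatments.to_csv(outdir / "treatments.tsv", sep="\t", index=False)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "libraries.tsv", sep="\t", index=False)
    return manifest
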