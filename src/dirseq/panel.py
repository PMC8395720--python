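"""Reporter construct panel and sub-library addressing scheme.

A DiR (dinucleotide reporter) screen clones a short SNP-centered genomic
fragment upstream of a minimal promoter; the transcribed reporter carries a
construct-identifying tag made of dinucleotides embedded at fixed positions
inside a 450-bp barcoded region.  Each SNP contributes two constructs (risk
and protective allele), and the pooled library additionally carries a
promoter-only and a blank (no-insert) control.  For sequencing, the barcoded
region is amplified as two overlapping amplicons (271 bp and 270 bp) so that
150-bp paired-end reads can merge across each; 24 tiling primer sets combined
with 12 sequencing indexes address up to 288 treatments in one run.

This module builds the construct panel and the addressing scheme that the
simulator (:mod:`dirseq.simulate`) and the read processor
(:mod:`dirseq.readproc`) share, and reads/writes their plain-text exchange
formats (SNP panel TSV, panel manifest TSV, scheme YAML).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SnpRecord",
    "Construct",
    "SubLibraryScheme",
    "build_panel",
    "assign_tags",
    "build_scheme",
    "synthesize_snps",
    "embed_tag",
    "reverse_complement",
    "read_snp_panel",
    "write_snp_panel",
    "read_manifest",
    "write_manifest",
    "manifest_frame",
    "read_scheme",
    "write_scheme",
]

BASES = "ACGT"
DINUCLEOTIDES = tuple("".join(p) for p in itertools.product(BASES, repeat=2))

#: Length of the transcribed barcoded reporter region (bp).
REPORTER_LEN = 450
#: Default dinucleotide slot offsets (0-based) within the reporter region.
#: Chosen so each amplicon covers three slots (see SubLibraryScheme).
DEFAULT_SLOT_OFFSETS = (50, 200, 260, 350)
#: The two amplicons tiling the barcoded region, half-open over reporter
#: coordinates: 271 bp and 270 bp.
DEFAULT_AMPLICONS = ((0, 271), (180, 450))
#: Width of the SNP-centered insert (bp); the variant sits at the center.
DEFAULT_CONTEXT_WIDTH = 55

PRIMER_LEN = 20
INDEX_LEN = 8
N_PRIMER_SETS = 24
N_INDEXES = 12

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """One risk SNP with both alleles and its SNP-centered genomic context.

    The context carries the *protective* allele at its center base
    (1-based position 28 of a 55-mer, i.e. 0-based index ``width // 2``).
    """

    snp_id: str
    chrom: str
    pos: int
    protective_allele: str
    risk_allele: str
    context: str

    def __post_init__(self) -> None:
        if self.protective_allele not in BASES or self.risk_allele not in BASES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single bases in ACGT, got "
                f"{self.protective_allele!r}/{self.risk_allele!r}"
            )
        if self.protective_allele == self.risk_allele:
            raise ValueError(f"{self.snp_id}: risk and protective alleles are identical")
        if len(self.context) % 2 == 0:
            raise ValueError(
                f"{self.snp_id}: context width must be odd, got {len(self.context)}"
            )
        center = len(self.context) // 2
        if self.context[center] != self.protective_allele:
            raise ValueError(
                f"{self.snp_id}: context center base {self.context[center]!r} does not "
                f"equal the protective allele {self.protective_allele!r}"
            )

    @property
    def risk_context(self) -> str:
        """Context with the center base substituted by the risk allele."""
        c = len(self.context) // 2
        return self.context[:c] + self.risk_allele + self.context[c + 1:]


@dataclass(frozen=True)
class Construct:
    """One reporter plasmid: allele insert plus a tagged 450-bp reporter."""

    construct_id: str
    snp_id: str  # control label for controls
    allele_class: str  # risk | protective | promoter_control | blank_control
    insert_seq: str  # 55-mer; empty for controls
    tag: tuple[str, ...]  # ordered dinucleotides, one per slot
    reporter_seq: str  # 450-mer with tag embedded at the slot offsets

    @property
    def tag_string(self) -> str:
        return "".join(self.tag)


@dataclass
class SubLibraryScheme:
    """Addressing scheme: tiling primer sets, indexes, amplicons, tag slots.

    ``primer_sets[j] = (forward, reverse)``: the forward primer forms the 5'
    end of the first amplicon and the reverse primer the 3' end of the second,
    so every read identifies its primer set (and thereby its amplicon) at one
    end of the merged sequence.  Indexes are matched from the read header.
    """

    primer_sets: list[tuple[str, str]]
    indexes: list[str]
    slot_offsets: tuple[int, ...] = DEFAULT_SLOT_OFFSETS
    amplicons: tuple[tuple[int, int], ...] = DEFAULT_AMPLICONS
    reporter_template: str = ""
    primer_len: int = PRIMER_LEN

    def __post_init__(self) -> None:
        self.primer_sets = [tuple(p) for p in self.primer_sets]
        self.slot_offsets = tuple(self.slot_offsets)
        self.amplicons = tuple(tuple(a) for a in self.amplicons)
        covered = set()
        for start, end in self.amplicons:
            covered.update(self.amplicon_slot_indices((start, end)))
        if covered != set(range(len(self.slot_offsets))):
            raise ValueError("amplicons do not jointly cover all tag slot offsets")

    @property
    def n_treatments(self) -> int:
        """Distinct addressable treatments: primer sets x indexes."""
        return len(self.primer_sets) * len(self.indexes)

    def amplicon_slot_indices(self, amplicon: tuple[int, int]) -> tuple[int, ...]:
        """Indices of tag slots fully contained in an amplicon interval."""
        start, end = amplicon
        return tuple(
            i for i, off in enumerate(self.slot_offsets)
            if off >= start and off + 2 <= end
        )

    @property
    def projections(self) -> tuple[tuple[int, ...], ...]:
        """Per-amplicon slot subsets; tag assignments must be injective on each."""
        return tuple(self.amplicon_slot_indices(a) for a in self.amplicons)

    def amplicon_length(self, i: int) -> int:
        start, end = self.amplicons[i]
        return end - start


# ---------------------------------------------------------------------------
# Reporter backbone and tags
# ---------------------------------------------------------------------------

def reporter_template(
    slot_offsets: tuple[int, ...] = DEFAULT_SLOT_OFFSETS,
    length: int = REPORTER_LEN,
    seed: int = 450,
) -> str:
    """Fixed arbitrary reporter backbone with tag slots blanked to ``NN``.

    Regulatory activity in this model is carried by counts, not by reporter
    sequence content, so any fixed template serves.
    """
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length))
    for off in slot_offsets:
        seq[off:off + 2] = "NN"
    return "".join(seq)


def embed_tag(template: str, tag: tuple[str, ...], slot_offsets: tuple[int, ...]) -> str:
    """Substitute the tag dinucleotides into the template at the slot offsets."""
    if len(tag) != len(slot_offsets):
        raise ValueError(f"tag has {len(tag)} slots, expected {len(slot_offsets)}")
    seq = list(template)
    for off, dinuc in zip(slot_offsets, tag):
        seq[off:off + 2] = dinuc
    return "".join(seq)


def assign_tags(
    n_constructs: int,
    k_slots: int,
    seed: int,
    projections: tuple[tuple[int, ...], ...] | None = None,
) -> list[tuple[str, ...]]:
    """Draw an injective construct -> tag mapping of ``k_slots`` dinucleotides.

    When ``projections`` is given (slot-index subsets, one per amplicon), the
    mapping is additionally injective on every projection, so that a read
    covering only that amplicon's slots still identifies its construct
    unambiguously.  Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If ``16**k_slots`` (or any projection's capacity) cannot hold
        ``n_constructs`` distinct tags.
    """
    if 16 ** k_slots < n_constructs:
        raise ValueError(
            f"tag capacity 16^{k_slots} = {16 ** k_slots} < {n_constructs} constructs"
        )
    projections = tuple(tuple(p) for p in projections) if projections else ()
    for proj in projections:
        if 16 ** len(proj) < n_constructs:
            raise ValueError(
                f"projection {proj} capacity 16^{len(proj)} = {16 ** len(proj)} "
                f"< {n_constructs} constructs"
            )
    rng = np.random.default_rng(seed)
    tags: list[tuple[str, ...]] = []
    seen_full: set[tuple[str, ...]] = set()
    seen_proj: list[set[tuple[str, ...]]] = [set() for _ in projections]
    # Rejection sampling; load factors stay low for the panel sizes in play.
    max_draws = 1000 * max(n_constructs, 1) + 10000
    draws = 0
    while len(tags) < n_constructs:
        draws += 1
        if draws > max_draws:
            raise RuntimeError("tag assignment failed to converge; capacity too tight")
        tag = tuple(DINUCLEOTIDES[i] for i in rng.integers(0, 16, size=k_slots))
        if tag in seen_full:
            continue
        parts = [tuple(tag[i] for i in proj) for proj in projections]
        if any(part in seen for part, seen in zip(parts, seen_proj)):
            continue
        seen_full.add(tag)
        for part, seen in zip(parts, seen_proj):
            seen.add(part)
        tags.append(tag)
    return tags


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------

def build_panel(
    snps: list[SnpRecord],
    context_width: int = DEFAULT_CONTEXT_WIDTH,
    *,
    scheme: SubLibraryScheme | None = None,
    slot_offsets: tuple[int, ...] | None = None,
    tag_seed: int = 0,
) -> list[Construct]:
    """Build the construct panel: two allele constructs per SNP plus controls.

    For each SNP the protective construct carries the context as supplied and
    the risk construct the same context with the center base substituted by
    the risk allele, so the two inserts differ at exactly the center position.
    One promoter-only and one blank (no-insert) control are appended.

    Raises
    ------
    ValueError
        If ``context_width`` is even, a context has the wrong width, or a
        context's center base is not the protective allele (named per SNP).
    """
    if context_width % 2 == 0:
        raise ValueError(f"context_width must be odd, got {context_width}")
    if slot_offsets is None:
        slot_offsets = scheme.slot_offsets if scheme else DEFAULT_SLOT_OFFSETS
    projections = scheme.projections if scheme else None
    template = (
        scheme.reporter_template
        if scheme and scheme.reporter_template
        else reporter_template(slot_offsets)
    )

    for snp in snps:
        if len(snp.context) != context_width:
            raise ValueError(
                f"{snp.snp_id}: context width {len(snp.context)} != {context_width}"
            )
        # center-base/protective-allele agreement is enforced by SnpRecord

    n_constructs = 2 * len(snps) + 2
    tags = assign_tags(n_constructs, len(slot_offsets), tag_seed, projections)
    constructs: list[Construct] = []
    i = 0
    for snp in snps:
        for allele_class, insert in (
            ("protective", snp.context),
            ("risk", snp.risk_context),
        ):
            constructs.append(
                Construct(
                    construct_id=f"{snp.snp_id}_{allele_class}",
                    snp_id=snp.snp_id,
                    allele_class=allele_class,
                    insert_seq=insert,
                    tag=tags[i],
                    reporter_seq=embed_tag(template, tags[i], slot_offsets),
                )
            )
            i += 1
    for label in ("promoter_control", "blank_control"):
        constructs.append(
            Construct(
                construct_id=label,
                snp_id=label,
                allele_class=label,
                insert_seq="",
                tag=tags[i],
                reporter_seq=embed_tag(template, tags[i], slot_offsets),
            )
        )
        i += 1
    return constructs


def build_scheme(
    n_primer_sets: int = N_PRIMER_SETS,
    n_indexes: int = N_INDEXES,
    slot_offsets: tuple[int, ...] = DEFAULT_SLOT_OFFSETS,
    amplicons: tuple[tuple[int, int], ...] = DEFAULT_AMPLICONS,
    seed: int = 24,
    min_primer_distance: int = 5,
) -> SubLibraryScheme:
    """Generate a sub-library addressing scheme with well-separated primers.

    All forward primers and reverse-complemented reverse primers keep a
    pairwise Hamming distance of at least ``min_primer_distance`` so that
    single-mismatch demultiplexing can never be ambiguous.
    """
    rng = np.random.default_rng(seed)

    def _draw_separated(n: int, length: int, existing: list[str]) -> list[str]:
        out: list[str] = []
        pool = list(existing)
        while len(out) < n:
            cand = _random_seq(rng, length)
            arr = np.frombuffer(cand.encode(), dtype=np.uint8)
            ok = True
            for other in pool:
                o = np.frombuffer(other.encode(), dtype=np.uint8)
                if int((arr != o).sum()) < min_primer_distance:
                    ok = False
                    break
            if ok:
                out.append(cand)
                pool.append(cand)
        return out

    fwd = _draw_separated(n_primer_sets, PRIMER_LEN, [])
    # reverse primers stored 5'->3' on the bottom strand; their reverse
    # complements appear at merged-read ends, so separate those too
    rc_rev = _draw_separated(n_primer_sets, PRIMER_LEN, fwd)
    rev = [reverse_complement(s) for s in rc_rev]
    indexes = _draw_separated(n_indexes, INDEX_LEN, [])
    return SubLibraryScheme(
        primer_sets=list(zip(fwd, rev)),
        indexes=indexes,
        slot_offsets=slot_offsets,
        amplicons=amplicons,
        reporter_template=reporter_template(slot_offsets),
    )


def synthesize_snps(n_snps: int = 213, seed: int = 213,
                    context_width: int = DEFAULT_CONTEXT_WIDTH) -> list[SnpRecord]:
    """Generate a synthetic SNP panel with SNP-centered contexts.

    Stand-in for a GWAS-derived panel: rsIDs, random chromosomes/positions,
    and random contexts carrying the protective allele at the center.
    """
    rng = np.random.default_rng(seed)
    snps = []
    for i in range(n_snps):
        ctx = list(_random_seq(rng, context_width))
        center = context_width // 2
        protective = ctx[center]
        risk = rng.choice([b for b in BASES if b != protective])
        snps.append(
            SnpRecord(
                snp_id=f"rs{1000000 + i}",
                chrom=f"chr{rng.integers(1, 23)}",
                pos=int(rng.integers(10_000, 50_000_000)),
                protective_allele=protective,
                risk_allele=str(risk),
                context="".join(ctx),
            )
        )
    return snps


# ---------------------------------------------------------------------------
# Plain-text exchange formats
# ---------------------------------------------------------------------------

SNP_PANEL_COLUMNS = ["snp_id", "chrom", "pos", "protective_allele", "risk_allele", "context"]
MANIFEST_COLUMNS = ["construct_id", "snp_id", "allele_class", "tag", "insert_seq"]


def write_snp_panel(snps: list[SnpRecord], path) -> None:
    pd.DataFrame([asdict(s) for s in snps])[SNP_PANEL_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def read_snp_panel(path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SNP_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SNP panel is missing columns: {sorted(missing)}")
    return [
        SnpRecord(
            snp_id=r.snp_id, chrom=r.chrom, pos=int(r.pos),
            protective_allele=r.protective_allele, risk_allele=r.risk_allele,
            context=r.context,
        )
        for r in df.itertuples()
    ]


def manifest_frame(constructs: list[Construct]) -> pd.DataFrame:
    """Panel manifest as a DataFrame (one row per construct)."""
    rows = [
        {
            "construct_id": c.construct_id,
            "snp_id": c.snp_id,
            "allele_class": c.allele_class,
            "tag": c.tag_string,
            "insert_seq": c.insert_seq,
        }
        for c in constructs
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_manifest(constructs: list[Construct], path) -> None:
    manifest_frame(constructs).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel manifest is missing columns: {sorted(missing)}")
    return df


def write_scheme(scheme: SubLibraryScheme, path) -> None:
    doc = {
        "primer_sets": [list(p) for p in scheme.primer_sets],
        "indexes": list(scheme.indexes),
        "slot_offsets": list(scheme.slot_offsets),
        "amplicons": [list(a) for a in scheme.amplicons],
        "reporter_template": scheme.reporter_template,
        "primer_len": scheme.primer_len,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, default_flow_style=None)


def read_scheme(path) -> SubLibraryScheme:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SubLibraryScheme(
        primer_sets=[tuple(p) for p in doc["primer_sets"]],
        indexes=list(doc["indexes"]),
        slot_offsets=tuple(doc["slot_offsets"]),
        amplicons=tuple(tuple(a) for a in doc["amplicons"]),
        reporter_template=doc.get("reporter_template", ""),
        primer_len=int(doc.get("primer_len", PRIMER_LEN)),
    )
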