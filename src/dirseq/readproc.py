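"""Recover per-construct counts from paired FASTQ.

Stages: quality screen -> overlap merge of each read pair -> demultiplex to a
(primer set, index) sub-library -> extract the dinucleotide tag from the
merged amplicon -> tally against the panel manifest.  Merging and
demultiplexing are implemented twice: a scalar reference path
(:func:`merge_pairs`, :func:`demultiplex`) that states the rules plainly, and
vectorised numpy kernels used by the file-level pipeline; tests hold the two
equal.

Every input pair is accounted for: pairs that drop out are tallied under a
reason code (``low_quality``, ``merge_fail``, ``demux_fail``, ``tag_fail``,
``unknown_tag``), so assigned + unassigned always equals the number of input
pairs.

Merging rule: the best overlap is the longest overlap (read 2
reverse-complemented against the tail of read 1) whose mismatch fraction does
not exceed the threshold; ``N`` matches any base without penalty, and bases
that disagree inside the overlap are resolved toward the higher-quality call.
No 5' trimming is performed anywhere — the dark first cycle ('N') of read 1
must survive so that primer positions stay in frame.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import SubLibraryScheme, reverse_complement

__all__ = [
    "MergedRead",
    "CountTable",
    "merge_pairs",
    "demultiplex",
    "extract_tag",
    "count_tags",
    "build_tag_lookup",
    "process_library",
    "count_run",
    "UNASSIGNED_REASONS",
]

UNASSIGNED_REASONS = ("low_quality", "merge_fail", "demux_fail", "tag_fail", "unknown_tag")

_N = ord("N")
_RC_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC_TABLE[_a] = _b


@dataclass
class MergedRead:
    """A merged read pair: consensus sequence, per-base quality, pair id."""

    sequence: str
    quality: str
    pair_id: str = ""


def _encode(seqs: list[str]) -> np.ndarray:
    """Stack equal-length strings into an (N, L) uint8 array of ASCII codes."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), length)


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------

def _merge_batch(
    s1: np.ndarray, q1: np.ndarray, s2: np.ndarray, q2: np.ndarray,
    min_overlap: int = 10, max_mismatch_frac: float = 0.1,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Vectorised overlap merge of N equal-length pairs.

    Returns (overlap length per read; 0 where no admissible overlap,
    merged sequences, merged qualities). Scans overlaps longest-first and
    keeps the first admissible one per pair.
    """
    n, length = s1.shape
    rc2 = _RC_TABLE[s2][:, ::-1]
    rq2 = q2[:, ::-1]
    best_ov = np.zeros(n, dtype=np.int64)
    unresolved = np.ones(n, dtype=bool)
    for ov in range(length, min_overlap - 1, -1):
        if not unresolved.any():
            break
        idx = np.nonzero(unresolved)[0]
        a = s1[idx, length - ov:]
        b = rc2[idx, :ov]
        mm = ((a != b) & (a != _N) & (b != _N)).sum(axis=1)
        ok = mm <= max_mismatch_frac * ov
        hit = idx[ok]
        best_ov[hit] = ov
        unresolved[hit] = False

    merged_seq: list[str] = [""] * n
    merged_qual: list[str] = [""] * n
    for ov in np.unique(best_ov):
        if ov == 0:
            continue
        idx = np.nonzero(best_ov == ov)[0]
        a, qa = s1[idx, length - ov:], q1[idx, length - ov:]
        b, qb = rc2[idx, :ov], rq2[idx, :ov]
        use_b = ((a == _N) & (b != _N)) | ((a != b) & (b != _N) & (qb > qa))
        cons = np.where(use_b, b, a)
        qcons = np.where(a == b, np.maximum(qa, qb), np.where(use_b, qb, qa))
        head, qhead = s1[idx, :length - ov], q1[idx, :length - ov]
        tail, qtail = rc2[idx, ov:], rq2[idx, ov:]
        full = np.concatenate([head, cons, tail], axis=1)
        qfull = np.concatenate([qhead, qcons, qtail], axis=1)
        for k, row in enumerate(idx):
            merged_seq[row] = full[k].tobytes().decode()
            merged_qual[row] = qfull[k].tobytes().decode()
    return best_ov, merged_seq, merged_qual


def merge_pairs(
    seq1: str, qual1: str, seq2: str, qual2: str,
    min_overlap: int = 10, max_mismatch_frac: float = 0.1,
    pair_id: str = "",
) -> MergedRead | None:
    """Merge one read pair by overlap; None when no admissible overlap exists.

    Read 2 is reverse-complemented and slid against read 1; the longest
    overlap with mismatch fraction <= ``max_mismatch_frac`` wins. ``N``
    matches any base; disagreements keep the higher-quality base (ties keep
    read 1's call).
    """
    if len(seq1) != len(qual1) or len(seq2) != len(qual2):
        raise ValueError("sequence and quality strings must have equal length")
    if len(seq1) != len(seq2):
        # pad the shorter mate on the far side so the batch kernel applies
        raise ValueError("mates must have equal read length")
    ov, seqs, quals = _merge_batch(
        _encode([seq1]), _encode([qual1]), _encode([seq2]), _encode([qual2]),
        min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac,
    )
    if ov[0] == 0:
        return None
    return MergedRead(sequence=seqs[0], quality=quals[0], pair_id=pair_id)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def _primer_bank(scheme: SubLibraryScheme) -> tuple[np.ndarray, int]:
    """Stack forward primers and reverse-complemented reverse primers.

    Row j < n_sets: forward primer of set j (expected at merged-read start,
    first amplicon). Row n_sets + j: reverse complement of set j's reverse
    primer (expected at merged-read end, second amplicon).
    """
    fwd = [p[0] for p in scheme.primer_sets]
    rc_rev = [reverse_complement(p[1]) for p in scheme.primer_sets]
    return _encode(fwd + rc_rev), len(fwd)


def _demux_batch(
    starts: np.ndarray, ends: np.ndarray, bank: np.ndarray, n_sets: int,
    primer_mm: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign (primer set, amplicon) by Hamming distance at both read ends.

    Returns (primer_set, amplicon) arrays with -1 for unassigned (distance
    above budget, or a tie between candidates). ``N`` counts as a mismatch.
    """
    n = starts.shape[0]
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    d_start = (starts[:, None, :] != bank[None, :n_sets, :]).sum(axis=2)
    d_end = (ends[:, None, :] != bank[None, n_sets:, :]).sum(axis=2)
    dist = np.concatenate([d_start, d_end], axis=1)  # (N, 2*n_sets)
    dmin = dist.min(axis=1)
    nmin = (dist == dmin[:, None]).sum(axis=1)
    cand = dist.argmin(axis=1)
    ok = (dmin <= primer_mm) & (nmin == 1)
    primer_set = np.where(ok, cand % n_sets, -1)
    amplicon = np.where(ok, cand // n_sets, -1)
    return primer_set, amplicon


def _index_from_header(title: str) -> str | None:
    """Illumina-style header comment ``mate:filter:flags:INDEX`` -> index seq."""
    parts = title.split()
    if len(parts) < 2:
        return None
    fields = parts[1].split(":")
    if len(fields) < 4 or not fields[-1]:
        return None
    return fields[-1]


def demultiplex(
    merged: MergedRead, header: str, scheme: SubLibraryScheme,
    primer_mm: int = 1,
) -> tuple[int, int, int] | None:
    """Assign one merged read to (primer set, index, amplicon); None if not.

    The primer is matched by Hamming distance (budget ``primer_mm``) against
    the read start (forward primers, first amplicon) and the read end
    (reverse-complemented reverse primers, second amplicon); a tie between
    two candidates at equal best distance is unassigned.  The index is taken
    from the header comment and must match exactly.
    """
    idx_seq = _index_from_header(header)
    if idx_seq is None or idx_seq not in scheme.indexes:
        return None
    plen = scheme.primer_len
    if len(merged.sequence) < plen:
        return None
    bank, n_sets = _primer_bank(scheme)
    ps, amp = _demux_batch(
        _encode([merged.sequence[:plen]]), _encode([merged.sequence[-plen:]]),
        bank, n_sets, primer_mm=primer_mm,
    )
    if ps[0] < 0:
        return None
    return int(ps[0]), scheme.indexes.index(idx_seq), int(amp[0])


# ---------------------------------------------------------------------------
# Tag extraction and counting
# ---------------------------------------------------------------------------

def extract_tag(
    merged: MergedRead | str, amplicon: int, scheme: SubLibraryScheme,
) -> str | None:
    """Concatenate the slot dinucleotides this amplicon covers; None on failure.

    Fails when the merged read does not reach a slot or a slot contains 'N'.
    Offsets are translated from reporter coordinates into the amplicon frame.
    """
    seq = merged if isinstance(merged, str) else merged.sequence
    start, _ = scheme.amplicons[amplicon]
    parts = []
    for i in scheme.amplicon_slot_indices(scheme.amplicons[amplicon]):
        rel = scheme.slot_offsets[i] - start
        if rel + 2 > len(seq):
            return None
        dinuc = seq[rel:rel + 2]
        if "N" in dinuc:
            return None
        parts.append(dinuc)
    return "".join(parts)


def build_tag_lookup(
    manifest: pd.DataFrame, scheme: SubLibraryScheme,
) -> list[dict[str, str]]:
    """Per-amplicon map from partial tag string to construct id.

    A partial tag shared by two constructs is ambiguous for that amplicon and
    is dropped from the map (reads carrying it tally as ``unknown_tag``).
    """
    k = len(scheme.slot_offsets)
    lookups: list[dict[str, str]] = []
    for amp in scheme.amplicons:
        slots = scheme.amplicon_slot_indices(amp)
        table: dict[str, str] = {}
        ambiguous: set[str] = set()
        for row in manifest.itertuples():
            tag = row.tag
            if len(tag) != 2 * k:
                raise ValueError(
                    f"manifest tag {tag!r} does not have {k} dinucleotide slots"
                )
            partial = "".join(tag[2 * i:2 * i + 2] for i in slots)
            if partial in table and table[partial] != row.construct_id:
                ambiguous.add(partial)
            else:
                table[partial] = row.construct_id
        for p in ambiguous:
            del table[p]
        lookups.append(table)
    return lookups


def count_tags(
    tags: list[tuple[int, int, int, str]],
    lookups: list[dict[str, str]],
) -> tuple[Counter, int]:
    """Tally (primer_set, index, amplicon, partial_tag) records against the panel.

    Returns (Counter keyed by (primer_set, index, amplicon, construct_id),
    number of unknown-tag records). Tags absent from the manifest — including
    partial tags that are ambiguous for their amplicon — count as unknown.
    """
    counts: Counter = Counter()
    unknown = 0
    for ps, ix, amp, tag in tags:
        cid = lookups[amp].get(tag)
        if cid is None:
            unknown += 1
        else:
            counts[(ps, ix, amp, cid)] += 1
    return counts, unknown


# ---------------------------------------------------------------------------
# File-level pipeline
# ---------------------------------------------------------------------------

def _read_fastq_pairs(r1_path, r2_path):
    def _open(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    titles, seqs1, quals1, seqs2, quals2 = [], [], [], [], []
    with _open(r1_path) as f1, _open(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            if t1.split()[0] != t2.split()[0]:
                raise ValueError(f"unpaired records: {t1!r} vs {t2!r}")
            titles.append(t1)
            seqs1.append(s1.upper())
            quals1.append(q1)
            seqs2.append(s2.upper())
            quals2.append(q2)
    return titles, seqs1, quals1, seqs2, quals2


def process_library(
    r1_path, r2_path, scheme: SubLibraryScheme, lookups: list[dict[str, str]],
    min_overlap: int = 10, max_mismatch_frac: float = 0.1,
    primer_mm: int = 1, min_mean_quality: float = 10.0,
) -> tuple[Counter, Counter]:
    """Run merge -> demux -> tag -> count over one paired FASTQ file set.

    Returns (assigned counts keyed by (primer_set, index, amplicon,
    construct_id), unassigned tallies keyed by reason code).
    """
    titles, seqs1, quals1, seqs2, quals2 = _read_fastq_pairs(r1_path, r2_path)
    unassigned: Counter = Counter()
    n_total = len(titles)
    if n_total == 0:
        return Counter(), unassigned

    lengths = {len(s) for s in seqs1} | {len(s) for s in seqs2}
    if len(lengths) != 1:
        raise ValueError("mixed read lengths are not supported by the batch path")

    s1, q1 = _encode(seqs1), _encode(quals1)
    s2, q2 = _encode(seqs2), _encode(quals2)

    # quality screen: drop pairs where either mate's mean quality < Q10
    mq1 = (q1.astype(np.int32) - 33).mean(axis=1)
    mq2 = (q2.astype(np.int32) - 33).mean(axis=1)
    keep = (mq1 >= min_mean_quality) & (mq2 >= min_mean_quality)
    unassigned["low_quality"] = int((~keep).sum())

    ov, merged_seq, _ = _merge_batch(
        s1[keep], q1[keep], s2[keep], q2[keep],
        min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac,
    )
    kept_titles = [t for t, k in zip(titles, keep) if k]
    unassigned["merge_fail"] = int((ov == 0).sum())

    plen = scheme.primer_len
    bank, n_sets = _primer_bank(scheme)
    good = np.nonzero(ov > 0)[0]
    # index match from the header, exact
    index_of = {s: i for i, s in enumerate(scheme.indexes)}
    rows = []
    for i in good:
        seq = merged_seq[i]
        idx_seq = _index_from_header(kept_titles[i])
        idx = index_of.get(idx_seq) if idx_seq else None
        if idx is None or len(seq) < plen:
            unassigned["demux_fail"] += 1
            continue
        rows.append((i, idx, seq))
    if rows:
        starts = _encode([seq[:plen] for _, _, seq in rows])
        ends = _encode([seq[-plen:] for _, _, seq in rows])
        ps_arr, amp_arr = _demux_batch(starts, ends, bank, n_sets, primer_mm)
    else:
        ps_arr = amp_arr = np.empty(0, dtype=np.int64)

    tag_records: list[tuple[int, int, int, str]] = []
    for (i, idx, seq), ps, amp in zip(rows, ps_arr, amp_arr):
        if ps < 0:
            unassigned["demux_fail"] += 1
            continue
        tag = extract_tag(seq, int(amp), scheme)
        if tag is None:
            unassigned["tag_fail"] += 1
            continue
        tag_records.append((int(ps), idx, int(amp), tag))

    counts, unknown = count_tags(tag_records, lookups)
    unassigned["unknown_tag"] = unknown
    assert sum(counts.values()) + sum(unassigned.values()) == n_total
    return counts, unassigned


@dataclass
class CountTable:
    """Per-construct counts with full drop-out accounting.

    ``counts``: long format (sublibrary, fraction, replicate, construct_id,
    tag, count) after combining the two amplicons. ``per_amplicon`` keeps the
    raw per-amplicon tallies; ``unassigned`` the reason-coded drop-outs per
    input file.
    """

    counts: pd.DataFrame
    per_amplicon: pd.DataFrame
    unassigned: pd.DataFrame

    def write(self, counts_path, unassigned_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index=False)
        if unassigned_path is not None:
            self.unassigned.to_csv(unassigned_path, sep="\t", index=False)


def _combine_amplicons(per_amp: pd.DataFrame, n_amplicons: int,
                       strategy: str = "mean") -> pd.Series:
    wide = per_amp.pivot_table(
        index=["sublibrary", "fraction", "replicate", "construct_id"],
        columns="amplicon", values="count", aggfunc="sum", fill_value=0,
    ).reindex(columns=range(n_amplicons), fill_value=0)
    if strategy == "mean":
        # round half to even, as an integer count
        return pd.Series(
            np.rint(wide.mean(axis=1)).astype(np.int64), index=wide.index
        )
    if strategy == "sum":
        return wide.sum(axis=1)
    if strategy == "amplicon_a":
        return wide[0]
    raise ValueError(f"unknown amplicon combine strategy: {strategy!r}")


def count_run(
    libraries: pd.DataFrame, scheme: SubLibraryScheme, manifest: pd.DataFrame,
    strategy: str = "mean", **kwargs,
) -> CountTable:
    """Process every library file and assemble the combined CountTable.

    ``libraries`` is the run sheet written by the simulator (columns
    sublibrary, primer_set, index, fraction, replicate, r1, r2). Reads are
    demultiplexed from sequence content and the header index, then mapped
    back to (fraction, replicate) through the run sheet's treatment
    addressing. The two amplicons' counts for one construct are combined by
    ``strategy``: mean (default, rounded half to even), sum, or amplicon_a.
    """
    lookups = build_tag_lookup(manifest, scheme)
    tag_of = dict(zip(manifest["construct_id"], manifest["tag"]))
    addr = {
        (int(r.primer_set), int(r.index)): (r.sublibrary, r.fraction, int(r.replicate))
        for r in libraries.itertuples()
    }
    amp_rows = []
    un_rows = []
    for lib in libraries.itertuples():
        counts, unassigned = process_library(lib.r1, lib.r2, scheme, lookups, **kwargs)
        unaddressed = 0
        for (ps, ix, amp, cid), n in counts.items():
            key = addr.get((ps, ix))
            if key is None:
                unaddressed += n
                continue
            sub, fraction, replicate = key
            amp_rows.append({
                "sublibrary": sub, "fraction": fraction, "replicate": replicate,
                "construct_id": cid, "amplicon": amp, "count": n,
            })
        row = {"sublibrary": lib.sublibrary, "fraction": lib.fraction,
               "replicate": lib.replicate, "n_pairs": getattr(lib, "n_pairs", None)}
        row.update({r: unassigned.get(r, 0) for r in UNASSIGNED_REASONS})
        row["unaddressed"] = unaddressed
        un_rows.append(row)

    per_amp = pd.DataFrame(
        amp_rows, columns=["sublibrary", "fraction", "replicate",
                           "construct_id", "amplicon", "count"],
    )
    if per_amp.empty:
        combined = pd.DataFrame(
            columns=["sublibrary", "fraction", "replicate", "construct_id",
                     "tag", "count"]
        )
    else:
        series = _combine_amplicons(per_amp, len(scheme.amplicons), strategy)
        combined = series.rename("count").reset_index()
        combined["tag"] = combined["construct_id"].map(tag_of)
        combined = combined[["sublibrary", "fraction", "replicate",
                             "construct_id", "tag", "count"]]
    return CountTable(
        counts=combined, per_amplicon=per_amp, unassigned=pd.DataFrame(un_rows)
    )
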