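"""Read processing: merging, demultiplexing, tag extraction, counting."""

import gzip

import numpy as np
import pandas as pd
import pytest

from dirseq import readproc as R
from dirseq import simulate as S
from dirseq.panel import reverse_complement


# ---------------------------------------------------------------------------
# brute-force merge oracle: scores every overlap offset independently
# ---------------------------------------------------------------------------

def brute_force_merge(s1, q1, s2, q2, min_overlap=10, max_mismatch_frac=0.1):
    rc2 = reverse_complement(s2)
    rq2 = q2[::-1]
    for ov in range(min(len(s1), len(s2)), min_overlap - 1, -1):
        a, b = s1[len(s1) - ov:], rc2[:ov]
        mm = sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")
        if mm <= max_mismatch_frac * ov:
            qa, qb = q1[len(s1) - ov:], rq2[:ov]
            cons, qcons = [], []
            for x, y, px, py in zip(a, b, qa, qb):
                if x == y:
                    cons.append(x)
                    qcons.append(max(px, py))
                elif x == "N" and y != "N":
                    cons.append(y)
                    qcons.append(py)
                elif y == "N" or px >= py:
                    cons.append(x)
                    qcons.append(px)
                else:
                    cons.append(y)
                    qcons.append(py)
            return (s1[:len(s1) - ov] + "".join(cons) + rc2[ov:],
                    q1[:len(s1) - ov] + "".join(qcons) + rq2[ov:])
    return None


def _pair_from_molecule(mol, read_len):
    return mol[:read_len], reverse_complement(mol)[:read_len]


def test_merge_matches_brute_force_on_random_pairs():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    for _ in range(200):
        amp_len = int(rng.integers(160, 290))
        mol = "".join(rng.choice(bases, size=amp_len))
        read_len = 150
        s1, s2 = _pair_from_molecule(mol, read_len)
        q1 = "".join(chr(33 + int(q)) for q in rng.integers(12, 40, read_len))
        q2 = "".join(chr(33 + int(q)) for q in rng.integers(12, 40, read_len))
        # sprinkle substitutions and Ns
        s1 = list(s1)
        s2 = list(s2)
        for s in (s1, s2):
            for pos in rng.choice(read_len, size=int(rng.integers(0, 4)), replace=False):
                s[pos] = str(rng.choice(list("ACGTN")))
        s1, s2 = "".join(s1), "".join(s2)
        expect = brute_force_merge(s1, q1, s2, q2)
        got = R.merge_pairs(s1, q1, s2, q2)
        if expect is None:
            assert got is None
        else:
            assert (got.sequence, got.quality) == expect


def test_merge_recovers_amplicon_length(small_panel, scheme):
    mol = small_panel[0].reporter_seq[:271]
    s1, s2 = _pair_from_molecule(mol, 150)
    q = "?" * 150
    merged = R.merge_pairs(s1, q, s2, q)
    assert len(merged.sequence) == 271  # overlap of 2*150 - 271 = 29 bases
    assert merged.sequence == mol


def test_merge_fail_without_overlap():
    rng = np.random.default_rng(1)
    bases = np.array(list("ACGT"))
    s1 = "".join(rng.choice(bases, size=150))
    s2 = "".join(rng.choice(bases, size=150))
    assert R.merge_pairs(s1, "?" * 150, s2, "?" * 150) is None


def test_merge_keeps_higher_quality_base():
    rng = np.random.default_rng(2)
    mol = "".join(np.random.default_rng(3).choice(list("ACGT"), size=271))
    s1, s2 = _pair_from_molecule(mol, 150)
    # disagreement inside the 29-base overlap: flip a base on read 2 at Q15
    pos_in_mol = 135  # within [121, 150) overlap region of read 1
    pos_in_r2 = 270 - pos_in_mol  # read 2 index covering that base, 0-based
    s2l = list(s2)
    truth_base = s1[pos_in_mol]
    s2l[pos_in_r2] = next(b for b in "ACGT" if b != reverse_complement(truth_base))
    q1 = "?" * 150                       # Q30 everywhere
    q2 = "?" * pos_in_r2 + "0" + "?" * (150 - pos_in_r2 - 1)  # Q15 at the flip
    merged = R.merge_pairs(s1, q1, "".join(s2l), q2)
    assert merged.sequence == mol
    assert merged.sequence[pos_in_mol] == truth_base


def _molecule(construct, scheme, amplicon, primer_set):
    from dirseq.simulate import _amplicon_molecule
    return _amplicon_molecule(construct, scheme, amplicon, primer_set)


def test_demultiplex_exact_and_mismatch_budget(small_panel, scheme):
    mol = _molecule(small_panel[0], scheme, 0, primer_set=5)
    header = f"sim:x:0 1:N:0:{scheme.indexes[3]}"
    merged = R.MergedRead(sequence=mol, quality="?" * len(mol))
    assert R.demultiplex(merged, header, scheme) == (5, 3, 0)

    one_mm = "N" + mol[1:]  # the dark leading cycle costs one mismatch
    assert R.demultiplex(R.MergedRead(one_mm, "?" * len(mol)), header, scheme) == (5, 3, 0)

    two = list(mol)
    two[0] = "N"
    two[5] = next(b for b in "ACGT" if b != mol[5])
    assert R.demultiplex(R.MergedRead("".join(two), "?" * len(mol)), header, scheme) is None


def test_demultiplex_second_amplicon_by_read_end(small_panel, scheme):
    mol = _molecule(small_panel[2], scheme, 1, primer_set=11)
    header = f"sim:x:1 2:N:0:{scheme.indexes[0]}"
    assert R.demultiplex(R.MergedRead(mol, "?" * len(mol)), header, scheme) == (11, 0, 1)


def test_demultiplex_tie_is_unassigned(small_panel, scheme):
    """A read start equidistant from two primer sets stays unassigned."""
    p0, p1 = scheme.primer_sets[0][0], scheme.primer_sets[1][0]
    diff = [i for i in range(len(p0)) if p0[i] != p1[i]]
    chimera = list(p0)
    for i in diff[: len(diff) // 2]:
        chimera[i] = p1[i]
    if len(diff) % 2:  # balance an odd count with a base matching neither
        j = diff[-1]
        chimera[j] = next(b for b in "ACGT" if b not in (p0[j], p1[j]))
    d0 = sum(a != b for a, b in zip(chimera, p0))
    d1 = sum(a != b for a, b in zip(chimera, p1))
    assert d0 == d1  # equidistant by construction
    mol = "".join(chimera) + small_panel[0].reporter_seq[20:271]
    header = f"sim:x:2 1:N:0:{scheme.indexes[0]}"
    assert R.demultiplex(R.MergedRead(mol, "?" * len(mol)), header, scheme,
                         primer_mm=len(p0)) is None


def test_demultiplex_index_must_match_exactly(small_panel, scheme):
    mol = _molecule(small_panel[0], scheme, 0, primer_set=0)
    merged = R.MergedRead(mol, "?" * len(mol))
    assert R.demultiplex(merged, "sim:x:0 1:N:0:TTTTTTTT", scheme) is None
    assert R.demultiplex(merged, "sim:x:0", scheme) is None  # malformed header


def test_extract_tag_per_amplicon(small_panel, scheme):
    c = small_panel[0]
    for amp in (0, 1):
        mol = _molecule(c, scheme, amp, primer_set=0)
        slots = scheme.amplicon_slot_indices(scheme.amplicons[amp])
        expect = "".join(c.tag[i] for i in slots)
        assert R.extract_tag(mol, amp, scheme) == expect

    mol0 = _molecule(c, scheme, 0, primer_set=0)
    noisy = mol0[:50] + "N" + mol0[51:]
    assert R.extract_tag(noisy, 0, scheme) is None  # N inside a slot
    assert R.extract_tag(mol0[:100], 0, scheme) is None  # truncated before a slot


def test_count_tags_unknown_and_ambiguous(scheme):
    manifest = pd.DataFrame({
        "construct_id": ["c1", "c2", "c3"],
        "snp_id": ["s1", "s1", "s2"],
        "allele_class": ["risk", "protective", "risk"],
        "tag": ["AACCGGTT", "AACCGGAA", "ACGTACGT"],
        "insert_seq": ["", "", ""],
    })
    lookups = R.build_tag_lookup(manifest, scheme)
    # amplicon 0 sees slots (0,1,2): c1 and c2 share partial "AACCGG" -> ambiguous
    assert "AACCGG" not in lookups[0]
    assert lookups[0]["ACGTAC"] == "c3"
    # amplicon 1 sees slots (1,2,3): all distinct
    assert lookups[1]["CCGGTT"] == "c1"
    counts, unknown = R.count_tags(
        [(0, 0, 0, "ACGTAC"), (0, 0, 0, "AACCGG"), (0, 0, 1, "CCGGTT"),
         (0, 0, 0, "GGGGGG")],
        lookups,
    )
    assert counts[(0, 0, 0, "c3")] == 1
    assert counts[(0, 0, 1, "c1")] == 1
    assert unknown == 2  # ambiguous partial + absent tag


def test_pipeline_reproduces_truth_exactly(small_run, scheme, small_manifest):
    """ε = 0 end-to-end: merge→demux→count equals the simulator's realized
    counts, and equals direct provenance tallies."""
    truth, libraries, outdir = small_run
    table = R.count_run(libraries, scheme, small_manifest)
    merged = table.counts.merge(
        truth.counts, on=["construct_id", "fraction", "replicate"],
        suffixes=("_pipe", "_truth"), how="outer",
    )
    nonzero = merged[(merged["count_pipe"].fillna(0) > 0)
                     | (merged["count_truth"].fillna(0) > 0)]
    assert (nonzero["count_pipe"] == nonzero["count_truth"]).all()

    prov = pd.read_csv(outdir / "provenance.tsv.gz", sep="\t")
    prov_counts = (
        prov.groupby(["construct_id", "fraction", "replicate", "amplicon"])
        .size().rename("count").reset_index()
    )
    amp = table.per_amplicon.merge(
        prov_counts, on=["construct_id", "fraction", "replicate", "amplicon"],
        suffixes=("_pipe", "_prov"), how="outer",
    )
    assert (amp["count_pipe"].fillna(0) == amp["count_prov"].fillna(0)).all()
    assert table.unassigned[list(R.UNASSIGNED_REASONS)].to_numpy().sum() == 0


def test_conservation_under_sequencing_error(small_panel, scheme, small_manifest, tmp_path):
    design = S.SimulationDesign(
        panel=small_panel, scheme=scheme, reads_per_library=800,
        epsilon=0.02, seed=13,
    )
    libraries = S.emit_fastq(S.simulate_counts(design), tmp_path)
    table = R.count_run(libraries, scheme, small_manifest)
    assigned = (
        table.per_amplicon.groupby(["sublibrary", "fraction", "replicate"])["count"].sum()
    )
    un = table.unassigned.set_index(["sublibrary", "fraction", "replicate"])
    for lib in libraries.itertuples():
        key = (lib.sublibrary, lib.fraction, lib.replicate)
        total = assigned.get(key, 0) + un.loc[key, list(R.UNASSIGNED_REASONS)].sum()
        assert total == lib.n_pairs


def test_assigned_fraction_decreases_with_error_rate(small_panel, scheme, small_manifest, tmp_path):
    fractions = []
    for eps in (0.0, 0.005, 0.02):
        design = S.SimulationDesign(
            panel=small_panel, scheme=scheme, reads_per_library=1500,
            epsilon=eps, seed=21,
        )
        libraries = S.emit_fastq(S.simulate_counts(design), tmp_path / f"e{eps}")
        table = R.count_run(libraries, scheme, small_manifest)
        assigned = table.per_amplicon["count"].sum()
        fractions.append(assigned / libraries["n_pairs"].sum())
    assert fractions[0] == 1.0
    assert fractions[0] >= fractions[1] >= fractions[2]


def test_empty_input_yields_empty_table(small_panel, scheme, small_manifest, tmp_path):
    design = S.SimulationDesign(panel=small_panel, scheme=scheme,
                                reads_per_library=100, seed=5)
    truth = S.simulate_counts(design)
    truth.counts["count"] = 0
    libraries = S.emit_fastq(truth, tmp_path)
    table = R.count_run(libraries, scheme, small_manifest)
    assert table.counts.empty
    assert table.unassigned[list(R.UNASSIGNED_REASONS)].to_numpy().sum() == 0


def test_combine_strategies(small_run, scheme, small_manifest):
    truth, libraries, _ = small_run
    mean_t = R.count_run(libraries, scheme, small_manifest, strategy="mean")
    sum_t = R.count_run(libraries, scheme, small_manifest, strategy="sum")
    a_t = R.count_run(libraries, scheme, small_manifest, strategy="amplicon_a")
    key = ["sublibrary", "fraction", "replicate", "construct_id"]
    m = mean_t.counts.set_index(key)["count"]
    s = sum_t.counts.set_index(key)["count"]
    a = a_t.counts.set_index(key)["count"]
    # with ε = 0 both amplicons agree: sum = 2 * mean, amplicon A = mean
    assert (s == 2 * m).all()
    assert (a == m).all()
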