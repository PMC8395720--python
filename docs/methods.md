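# Methods

## The assay model

A DiR-seq screen measures the regulatory activity of short genomic
fragments by cloning them upstream of a minimal promoter in a reporter
whose transcribed region carries construct-identifying dinucleotide tags.
For a SNP screen, each variant contributes two constructs — the 55-bp
SNP-centered context with the protective allele (as supplied) and with the
risk allele substituted at the center base (1-based position 28) — plus a
promoter-only and a blank no-insert control for the pool. Tag counts are
measured in two fractions: the transfected plasmid pool (template DNA) and
the reverse-transcribed reporter RNA (cDNA). The per-construct expression
level is

```
E = (cDNA tag count, depth-normalized) / (template-DNA tag count, depth-normalized)
```

and a SNP's allelic activity is summarized by the ratio
`R = mean(E_risk) / mean(E_protective)` over replicates, tested with a
two-tailed Student's t-test on the replicate E values. The screen calls a
SNP regulatory when `R < 0.8` (down) or `R > 1.2` (up) with `p < 0.05`,
strict inequalities, no multiple-testing correction (a Benjamini–Hochberg
switch exists but is off by default, mirroring the screen's criterion).

## Library geometry and tag layout

The 450-bp barcoded reporter region is sequenced as two amplicons of 271 bp
(`[0, 271)`) and 270 bp (`[180, 450)` in reporter coordinates) so that
150-bp paired-end reads overlap by 29 and 30 bases respectively. The
sub-library address of a read is carried by (a) one of 24 primer sets — the
set's forward primer forms the first 20 bases of amplicon 1 and its reverse
primer the last 20 bases of amplicon 2, so each merged read identifies its
primer set at one end and thereby also its amplicon — and (b) one of 12
sequencing indexes recorded in the read header, giving up to 288
addressable treatments. Primer sequences are generated with a pairwise
Hamming distance of at least 5 (forward and reverse-complemented reverse
primers jointly), so single-mismatch demultiplexing can never be ambiguous.

The exact number and position of tag slots in the physical DiR vector are
not restated here; the package models the tag as `k` dinucleotide slots at
fixed reporter offsets, configurable, with defaults chosen for
identifiability: **4 slots at offsets 50, 200, 260, 350** (0-based).
Amplicon 1 covers slots {0, 1, 2} and amplicon 2 slots {1, 2, 3}; since a
read sees only its own amplicon, tag assignment rejection-samples until the
full tags *and* both three-slot projections are injective over the panel
(16³ = 4096 ≥ 428 constructs per projection). A 3-slot layout cannot
satisfy this — each amplicon would see at most two slots, and 16² = 256 is
below the 428-construct panel — which is why 4 slots is the default. The
reporter backbone is a fixed arbitrary 450-mer with the slots blanked;
activity in this model is carried by counts, not sequence content.

## Synthetic data generator

`dirseq.simulate` emulates the data structure the analysis assumes, not a
sequencer in detail. Per library (fraction × replicate):

- **Abundance**: per-construct plasmid abundance is log-normal
  (`sigma_abund = 0.5` on the log scale by default — order-of-magnitude
  spread typical of pooled clone libraries). One pool is shared across
  replicates by default (`shared_pool`), matching a single transfected
  plasmid prep; re-pooling per replicate is a switch.
- **Activity**: cDNA rates multiply abundance by a per-construct activity
  (default 1), the SNP's allelic fold `theta` on risk constructs, and a
  mean-one log-normal replicate factor with coefficient of variation
  `replicate_cv` (transfection/expression noise; cDNA only).
- **Counts**: the library size is Poisson around `reads_per_library`
  (default 1e6 molecules, the screen's per-library depth), and counts are a
  gamma-weighted multinomial with dispersion `phi` — the sum-conditioned
  analogue of negative-binomial counts, exactly conserving the drawn
  library size; `phi = 0` reduces to a plain multinomial. Negative-binomial
  and log-normal noise families are the conventional choice for
  reporter-assay counts.
- **Reads**: each realized molecule yields one read pair per amplicon; read
  1 is the first 150 bases of the amplicon molecule and read 2 the reverse
  complement of its last 150. Qualities are constant Q30; substitution
  errors at per-base rate `epsilon ∈ [0, 0.1]` are emitted at Q15 so the
  merger's quality-aware tie-break is exercised; a configurable fraction
  (default 5%) of read-1 records carries a dark first cycle ('N'), which
  the pipeline must not trim. No indels, position-dependent error
  profiles, or PCR duplicates are modeled. A provenance sidecar maps every
  read id to its construct for oracle tests.

What passing tests show about real data is therefore limited: exact count
recovery holds under substitution-only errors and uniform read length;
real libraries add indels, quality decay, adapter artifacts, and
cross-contamination that this generator does not emulate.

## Read processing

- **QC** is deliberately minimal: pairs are dropped only when either mate's
  mean quality is below Q10 (reason `low_quality`); there is no 5' trimming
  so the leading 'N' survives and primer positions stay in frame.
- **Merging**: read 2 is reverse-complemented and slid against read 1; the
  *longest* overlap (scanned ≥ `min_overlap = 10`) with mismatch fraction
  ≤ 0.1 wins; 'N' matches anything without penalty; disagreeing bases keep
  the higher-quality call (ties keep read 1). A scalar reference
  implementation and a vectorised batch kernel are held equal by tests
  against a brute-force all-offsets scorer.
- **Demultiplexing**: primer matched by Hamming distance at the merged-read
  start (forward primers) and end (reverse-complement reverse primers)
  with budget 1; equal-best-distance ties are unassigned; the index from
  the header must match exactly (budget 0). These budgets keep simulated
  cross-assignment at zero — a wrong assignment would need ≥ 4 coinciding
  errors given the distance-5 primer separation — while a single error or
  the leading 'N' still assigns correctly.
- **Counting**: the amplicon-specific partial tag is looked up in the
  manifest projection for that amplicon (ambiguous partials are discarded
  to `unknown_tag`); the per-construct count combines the two amplicons'
  tallies by their mean, rounded half-to-even (the two amplicons are
  independent measurements of the same molecule pool); `sum` and
  `amplicon_a` strategies are available. Assigned plus reason-coded
  unassigned pairs always equals the input pair count.

## Quantification choices

- Depth normalization scales every (sub-library, fraction, replicate) group
  to exactly 1,000,000 total reads (real-valued), the screen's stated unit.
- Constructs with a raw template count below `min_template = 10` in any
  replicate are excluded (`low_template`) — a stability floor for the ratio
  denominator; constructs with a zero cDNA count in some replicate are
  excluded (`zero_cdna`) so `E > 0` holds for everything retained.
- The t-test runs on the raw E scale with pooled (equal) variance by
  default — the literal reading of "Student's t-test" — with Welch and
  log10-scale switches. Degenerate inputs follow fixed conventions: both
  groups constant and equal → p = 1; both constant, different → p = 0 with
  a warning.
- Controls are reported but never enter the allelic test.
- Replicate agreement is summarized by Pearson correlation of log10
  expression between replicate pairs; constant vectors report NaN.

## Validation studies (`dirseq.studies`)

- **Oracle equivalence**: at `epsilon = 0`, the full FASTQ → count pipeline
  must reproduce the simulator's realized counts exactly; run at three
  seeds with ~2×10⁵ read pairs over the full 213-SNP panel (≈16,600
  molecules per library), a size that keeps the check under a minute while
  exercising every sub-library and both amplicons.
- **Null calibration**: 20 runs × 200 SNPs with folds all 1, 3 replicates,
  `phi = 0.05`, `replicate_cv = 0.10`, 1e6 reads/library; the up/down call
  rate is compared to alpha = 0.05 plus a 95% binomial allowance for the
  4000 simulated tests.
- **Planted recovery**: folds 2.0/0.5 at `phi = 0`, `replicate_cv = 0`
  must be called up/down for every planted SNP.
- **Power**: detection power at intermediate folds (e.g. 1.5) under the
  noisy setting is reported as a curve, with no asserted level; with three
  replicates and dispersion 0.05 it is modest (tens of percent), which is
  the expected operating regime of fold-threshold MPRA screens.

## qPCR formulas

All transformations assume exponential amplification at efficiency 2.0
(perfect doubling; a per-call `efficiency` parameter is exposed since
per-primer efficiencies are rarely published). Replicate Cts are averaged
before transformation; SDs propagate by the delta method
(`sd = value · ln(eff) · sd(ΔCt)`), validated against Monte-Carlo within
5%. The allele-specific ratio uses a calibrator-normalized ΔΔCt form —
the heterozygous genomic calibrator (true ratio 1) cancels allele-primer
efficiency offsets — and the getPCR wild-type fraction uses the analogous
form with a watching amplicon over the edit site normalized to a distal
control amplicon and an unedited reference sample; both are inferred from
the assay descriptions rather than printed formulas, and are flagged as
package design decisions.

## Known limitations

- The tag-slot geometry is a modeling stand-in; real DiR vectors may differ.
- Headline biological counts of a real screen (numbers of regulatory SNPs)
  depend on the deposited sequencing data and cell context and are not
  reproduced by synthetic runs; the package validates the *procedure*, not
  those numbers.
- The batch read-processing path requires uniform read length within a
  file (the simulator's output; typical of Illumina runs).
- No alignment, UMI handling, adapter inference, or luciferase dual-reporter
  normalization.
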