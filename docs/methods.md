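# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical decisions made where the design was genuinely open.

## Sorted CRISPR screen

### Scoring model

Guide frequencies are `(count + pseudocount) / Σ(count + pseudocount)` per
sample (default pseudocount 0.5, log base 2 throughout). The enrichment
score of a guide is `e = log2(f_sorted / f_day0)`; the LFC between two
conditions is the difference of their enrichment scores. Gene scores use

    z = (x − μ) / (σ / √n)

where `x` is the mean residual of the gene's `n` guides and `μ`, `σ` are
the mean and standard deviation of the residuals of *all* guides, negative
controls included (a `controls_only` flag restricts the reference to the
control guides). `σ` is the population standard deviation (ddof = 0); at a
308-guide library the difference from the sample estimator is negligible,
and the population form makes the brute-force equivalence tests exact.
"Residual" is the enrichment score for a single-condition analysis and the
LFC for a contrast; both paths are exposed, and `score_screen` reports the
per-condition z, the LFC z, and the Z-ratio.

The Z-ratio between conditions a and b is defined here as

    Zr = (d − mean(d)) / sd(d),   d = z_a − z_b,

with `sd` taken over genes (ddof = 1). Centering is this package's choice:
it makes the Z-ratio an exactly standardized score (mean 0, SD 1 over
genes) and is antisymmetric under swapping conditions; the uncentered
variant found in the screening literature differs only by a constant shift
of `mean(d)/sd(d)`, which is near zero in any screen where most genes are
null. Hits are ranked by Z-ratio with a stable sort and lexicographic
tie-break on the gene name. Degenerate inputs (zero residual dispersion, or
identical z vectors) raise rather than divide silently.

### Sort simulation

The generator models what the analysis assumes and nothing more. Day-0
guide frequencies are Dirichlet-multinomial with a single concentration
parameter `1/dispersion` per guide (default dispersion 0.01, i.e. mild
library skew); cells are assigned to guides by a second multinomial draw
from the same frequencies, so library skew cancels in the enrichment score
as it does in a real screen. Per-cell fluorescence is log-normal — the
standard flow-cytometry intensity model — with a gene's effect acting
multiplicatively on the mean (log-scale SD 0.5 by default; setting it to 0
gives deterministic fluorescence for exhaustive-enumeration tests). The low
gate keeps exactly `floor(gate_fraction × n_cells)` cells, ties broken by
stable cell order, matching a sorter's fixed-fraction gate. Sequencing of
the day-0 and sorted pools is an optional extra multinomial resampling
(`day0_depth`, `sorted_depth`), exposed separately because the real
recovery depth of the sorted pool relative to day 0 is not a fixed design
constant; by default counts equal cell tallies.

Study conditions used in the tests and the acceptance script: the 308-guide
library (70 × 4 + 28 controls), a 15% gate, 500 cells per guide
(154,000 cells) for recovery runs, and a 300-gene × 4-guide null library at
the same per-guide depth for calibration. A depleting effect of 0.2 on
fluorescence shifts a gene's cells by −3.2 log-SD, which is the regime the
screen was designed to detect.

## Ribosome stalling

Footprint 5′ ends are mapped to ribosomal sites by fixed offsets
`o_E/o_P/o_A = 9/12/15` nt, read as 0-based distances from the 5′ end to
the first nucleotide of each site codon (nt 9–11 = E, 12–14 = P,
15–17 = A). This reading preserves the canonical 3-nt site spacing, which
the `OffsetConfig` type enforces. Offsets are applied uniformly across read
lengths; length-stratified offset tables are a straightforward extension
but not modeled, since the analyses here use a single offset triple. A read
is in frame when its A-site position lands on a codon boundary; reads whose
E- or A-site codon falls outside the CDS are excluded and counted, so
assigned + excluded always equals the input total.

The metagene profile collects 5′-end counts over an odd window (default
61 nt) centered on each CDS instance of an anchor codon or amino acid.
Each instance is normalized by its own window mean — so highly covered
transcripts do not dominate — and instances with zero window coverage are
dropped before averaging. A pause with the anchor in the A site therefore
peaks at axis position −o_A.

Pause scores are observed/expected counts per category (amino acid, codon,
or joint E-P-A tripeptide). The expectation is coverage-weighted by
default: each transcript contributes its own in-frame read total times its
own category frequency, so codon-usage differences between transcripts of
different abundance do not masquerade as pauses; a pooled `uniform`
estimator is also available. The first and last 5 codons of each CDS are
excluded from both observation and expectation (initiation/termination
artifacts; configurable). Condition comparisons are elementwise score
ratios over a matched category universe, with an optional pseudocount.

The RPF simulator draws footprints per sense codon with probability
proportional to pause strength (stop codons excluded from the sampling
universe), places the 5′ end `o_A` nt upstream of the codon start, and
draws read lengths uniformly on 28–31 nt (a length filter is not modeled).
Exactly `depth` reads are emitted. Because every simulated 5′ end sits on
the codon grid, the simulator reproduces the frame periodicity of real
ribosome profiling but not its off-frame noise, untemplated additions, or
UTR coverage — flat-profile tests therefore use explicitly constructed
uniform coverage rather than the simulator.

## Motif census

Motif counting slides a 3-residue window with stride 1 and counts every
overlapping occurrence. Two motif definitions are supported and mutually
exclusive: an explicit tripeptide list, or a residue-class rule counting
windows whose three residues all lie in a qualifying alphabet. The default
rule alphabet {P, G, D, E, K, R} (proline, glycine, charged residues) is an
explicit stand-in for published eIF5A-dependent motif catalogs; any real
analysis should supply its own motif file, which is why the CLI takes one.
Counts are not length-normalized by default (a per-100-residue density is a
trivial client-side transform of the emitted per-protein table).

Per-protein counts are binned at edges 0 / 1–3 / 4–6 / 7–10 / >10 and the
two sets compared with a two-way homogeneity chi-square (df =
bins − 1, no continuity correction). Bins whose expected count falls below
5 are merged into their left neighbor (right neighbor for the first bin)
until the expectation criterion holds; fewer than two surviving bins is an
error, not a p-value.

The protein-set generator draws residues i.i.d., qualifying with
probability `rate^(1/3)` so that a window qualifies at exactly the stated
per-window rate. Null calibration uses rate 0.02 for both sets
(≈ 6 motifs per 300-residue protein, spreading mass across all default
bins, comparable to ribosomal-protein censuses); power runs use 0.2 vs
0.02 at n = 50 per set. I.i.d. residues ignore the compositional clustering
of real proteins (polyproline runs, charge patches), so the calibration
demonstrates the test's behavior under its own sampling assumptions, not
under real proteome correlation structure.

## Isotopologue natural-abundance correction

For a compound with k carbons the correction matrix C has column i equal to
the binomial(k − i, p) kernel shifted to row i, p = 0.0107 (standard
isotopic-abundance tables). C is lower-triangular with positive diagonal
`(1 − p)^(k−i)`, so the correction solves C·x = M exactly by forward
substitution — no least-squares smoothing. Negative entries, which arise
only from measurement noise, are clipped to zero and the vector
renormalized; the clipped mass is reported as a diagnostic rather than
discarded silently. Only carbon natural abundance is corrected — no ¹⁵N,
²H, or adduct terms — matching the stated scope of the correction this
implements. Peak-area normalization divides each sample by its total
signal and is idempotent.

The pathway map fixes inherited tracer carbons from U-¹³C-arginine:
ornithine 5, putrescine 4, spermidine 4 and N-acetyl-spermidine 4 (the
aminopropyl and acetyl groups are unlabeled); it is user-overridable. Two
labeling summaries are emitted: mean enrichment `Σ i·x_i / k` and the
corrected fraction at the pathway-predicted shift.

The forward simulator models each compound as a two-point mixture of
unlabeled and fully backbone-labeled species. Real tracing data also
contains partially labeled intermediates from pathway cycling; the
two-point mixture is sufficient to validate the correction algebra, which
is linear and therefore indifferent to the mixture's shape.

## pSILAC normalization

The reference is the top `n_top` (default 1000) protein groups by iBAQ
among rows quantified in both iBAQ and ratio, ties broken by stable protein
id; the nascent table's log2 ratios are shifted additively so their median
equals the reference mean. The shift is the only operation, so pairwise
differences between nascent proteins are preserved to machine precision and
the normalization is idempotent. "Median normalized to the mean" is read
literally as an additive match on the log scale. The reference and shift
are computed per replicate by default — mixing-ratio drift is a
per-replicate artifact — with a pooled mode available.

Quantification filtering retains protein groups with at least `min_ratios`
non-missing ratio values spanning at least `min_replicates` distinct
replicates (defaults 2 and 3); both thresholds are parameters because
published filter phrasings of this form are ambiguous between conjunctive
and disjunctive readings.

The simulator generates log-normal iBAQ intensities, Gaussian log2 ratios
around per-replicate shifts, a constant nascent offset, and random
missingness. It does not model intensity-dependent missingness or
peptide-level aggregation noise.

## Problem sizes and determinism

Every generator consumes a `numpy.random.default_rng` seed and is
bit-reproducible. The validation suite and the acceptance script use the
sizes stated above (600k-cell null screens, 100k–1M-read RPF simulations,
500-replicate chi-square calibrations, 250 round-trip vectors,
1,500-protein pSILAC tables); these were chosen as the smallest sizes at
which the statistical properties under test are stable, and the whole
suite completes in well under a minute on one core.
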