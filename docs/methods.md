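# Methods

This note documents the models, conventions, and design choices behind
pogdiv, in the order data flow through the pipeline.

## Ortholog pairing and coding-region extraction

Transcript filtering removes sequences shorter than 30 nt or with more than
20% stop codons; the stop fraction is evaluated over complete codons in
frame 0 of the given orientation, which matches a naive contig scan and is
the documented convention (the choice of frame is otherwise arbitrary for
assembled contigs).

Single-copy ortholog pairs between two transcript sets are found by
reciprocal best hit (RBH). For a two-taxon comparison, RBH yields exactly
the "one gene from each set" groups the rate estimation needs, without
graph clustering. The similarity scorer is deterministic: a shared-8-mer
prefilter (pairs sharing no 8-mer score 0) followed by local nucleotide
alignment (match +2, mismatch −3, gap open −5, extend −2). Score ties are
broken lexicographically by sequence id, which makes the pairing symmetric
in its two arguments and reproducible.

Coding regions are taken as the longest open reading frame over all six
frames, where an ORF is a maximal run of unambiguous non-stop codons; a
terminal stop is excluded and a stop-free frame yields the whole frame.
Ties prefer the forward strand, then the lower frame offset, then the
earlier position. ORFs shorter than 10 codons (default) drop the gene with
a logged reason. A pass-through mode accepts inputs that are already CDS.
This longest-ORF rule is a deliberate, deterministic stand-in for a
model-based CDS predictor and is adequate for simulated and curated CDS
input; it is not a gene finder.

## Codon alignment

The two CDS are translated (standard nuclear code, table 1 — all study
taxa are angiosperm nuclear transcriptomes) and globally aligned at the
protein level with BLOSUM62 and affine gaps (open −10, extend −0.5); the
gap pattern is threaded back onto codons, so gaps occur only in whole-codon
units and the frame is preserved. Traceback ties are resolved by the
aligner's canonical order, so the alignment is deterministic for given
inputs and penalties. Internal coordinates are 0-based half-open
throughout; FASTA output is display-only.

## Substitution-rate estimation

Both estimators work on the gap-stripped codon columns of one alignment;
columns containing an alignment gap or an ambiguous base in either sequence
are excluded pairwise (conservative and deterministic).

Conventions shared by both methods:

* Mutations that create a stop codon count as nonsynonymous in site
  counting, so S + N = 3 × (codons compared) exactly.
* Codon pairs differing at k positions are averaged over the k! orderings
  of single-step paths; orderings passing through a stop codon are
  excluded, and if every ordering is blocked (rare), all orderings are used
  with stop-touching steps scored as nonsynonymous.
* Ratio sentinels: Ks = 0 with Ka > 0 is reported as 99.0; Ks = Ka = 0 as
  NaN. Downstream filtering removes both, together with every Ks = 0 gene.

**NG86 (reference).** Synonymous sites per codon are the per-position
fractions n_syn/3; differences are pathway-averaged with equal weights;
proportions p = d/sites are corrected with the Jukes–Cantor formula
d = −(3/4)·ln(1 − 4p/3). Standard errors come from the delta method,
Var(d) = 9p(1−p) / [S·(3−4p)²]. Proportions ≥ 3/4 raise a saturation
error; such genes are dropped with a log line rather than reported.

**YN00-style (primary).** The transition/transversion rate ratio κ is
estimated from positions where both codons are fourfold-degenerate (all
changes synonymous) or both nondegenerate (all changes nonsynonymous):
within each class the Kimura two-parameter (K2P) transition and
transversion distance components give κ = 2s/v, and the class estimates
are combined weighted by site counts; with no informative differences the
configured default (κ = 2) is used with a warning. Codon frequencies are
F3x4 — products of position-specific nucleotide frequencies pooled over
both sequences, renormalised over sense codons, with a 0.5 pseudocount so
every sense codon stays reachable.

Site counting weights each position's three possible changes by
κ^[transition] × π[target]; the position contributes one site split
between the classes by these weights. Changes to stop codons stay in the
denominator, weighted by the mean sense-codon frequency, so at κ = 1 and
uniform usage the counts reduce exactly to NG86's. Difference counting
weights each pathway ordering by the product over its steps of
κ^[transition] × ω^[nonsynonymous] × π[target], symmetrised over direction;
the resulting synonymous and nonsynonymous difference counts are split
into transition and transversion components and corrected per class with
the K2P formula (this is where transition/transversion bias enters the
multiple-hit correction). ω and the counts are iterated — recount with the
current ω, re-correct, set ω = Ka/Ks — until ω moves by less than 1e-6 or
100 iterations are reached, in which case the last iterate is returned
(the update is a contraction in practice; non-convergence has not been
observed on simulated data). Standard errors use the K2P delta-method
variance.

On simulated data (κ = 2, 2000 codons, branch scale 0.3, 100 replicates
per regime) the mean YN00-style estimate is within about 8% of the true ω
across ω ∈ {0.05, 0.2, 1.0, 2.5}; NG86 is 15–25% low in the same regimes,
the expected behaviour of the equal-weight method under transition bias.

## Selection profiles

Ks histograms use half-open bins [lo, hi) of width 0.01 from 0; a value on
an interior edge belongs to the upper bin, and the last bin is closed at
the maximum. Peak Ks is the modal-bin midpoint; ties go to the lowest tied
bin with a warning. The near-tie ("modified") peak applies only to the
modal bin and its immediate neighbours: if their frequencies differ by
less than 10% of their combined frequency the shared boundary is returned,
and if both neighbours qualify the one closer in frequency wins.
Frequencies are proportions of the filtered total (equivalent to counts).

Category boundaries are lower-closed/upper-open for the purifying bins,
closed [0.9, 1.1] for near-neutral, (1.1, 2] weak positive, (2, ∞) strong
positive — a gap-free, overlap-free partition consistent with the verbal
category definitions. The profile also reports the overall purifying share
(ω < 0.9) and the ω ≥ 1 share, both computed from the filtered gene list,
so either denominator convention (before or after filtering) can be
reconstructed from the emitted counts.

## Clustered-substitution test

For each candidate gene the differing positions of the gap-stripped
alignment (nucleotide coordinates; codon coordinates derivable by integer
division) feed a minimal spanning-window scan statistic: the length of the
shortest window containing any ⌈k/2⌉ + 1 of the k substitutions. The
majority-window form is robust to a minority of dispersed background
changes; the statistic is pluggable. The null distribution draws k
positions uniformly without replacement from the sequence; p-values use
the add-one correction (1 + #{null ≤ observed}) / (1 + n_perm) with
n_perm = 999 by default, so p is never 0. Note that equal spacing does not
maximise this statistic for k ≥ 4 (two tight clusters at opposite ends
force a larger majority window); it does at k = 3. Type-I error at
α = 0.05 is calibrated to the binomial band over 1000 null genes, and
power on substitutions confined to a 5%-of-length window is near 1 at
k = 8.

## Cross-pair associations

Correlations are sample Pearson coefficients with two-sided p-values from
the t-distribution with n − 2 degrees of freedom (the original analyses
report r from a spreadsheet correlation function, which gives no p; the
t-based p is the standard companion). The panel is reported raw, without
multiple-testing correction, as such cross-pair tables usually are.
Category abundances enter as proportions (counts are accepted and
converted). The shared-gene screen uses pairwise deletion: per gene,
ratios of 0 or 99 are dropped, an optional cap (e.g. ω < 0.5) may be
applied, and at least 3 usable pairs are required; genes present in fewer
than 90% of pairs are excluded.

## Simulator

Gene pairs evolve under a continuous-time Markov codon model on the 61
sense codons with rate(x→y) ∝ κ^[transition] × ω^[nonsynonymous] ×
π[target] for single-nucleotide changes; stop codons are unreachable. The
branch-length parameter t is the expected number of substitutions per
codon summed over both branches under the neutral (ω = 1) normalisation,
so the target ω of a gene is well defined whatever its selective regime.
The ancestor is drawn from π (stationary for this reversible chain) and
each branch of length t/2 is simulated with an exact jump-chain (Gillespie)
algorithm whose event log — per-event position and synonymous/nonsynonymous
label — is the ground truth for estimator-recovery and power tests.
Defaults: 500 codons per gene, κ = 2, uniform codon frequencies, t = 0.2
(Ks ≈ t/3 ≈ 0.07, at the upper end of the shallow divergences the method
targets); indels are off (the rate estimators use gap-stripped columns),
with a whole-codon deletion helper for alignment tests.

Cohorts draw each gene's category from a six-way mixture, and its ω
uniformly from per-category ranges chosen away from the category
boundaries (0.02–0.08, 0.15–0.45, 0.55–0.85, 0.92–1.08, 1.2–1.9, 2.2–5)
so that estimation noise, not range overlap, dominates misclassification.
The default mixture (0.25, 0.50, 0.14, 0.03, 0.06, 0.02) sits inside the
observed per-taxon abundance ranges and reproduces the canonical rank
order after estimation.

A fraction (default 0.7) of strong-positive genes carry their
nonsynonymous changes in a 5%-of-length window. A window that small can
only host a modest number of countable substitutions, so these genes are
simulated at a reduced branch length (capped so the expected window
density stays ≈ 0.35 changes/nt) with ω raised inside the window and 0
outside, preserving the gene-wide expected ω. The consequence — clustered
candidates are low-Ks genes with high, noisy ω estimates — mirrors the
real situation in which ω > 2 calls rest on few synonymous substitutions.

Panels map divergence times (default 20 pairs spanning 1.69–10.67 mya) to
branch lengths via t = 0.015 × time (placing peak Ks between ≈ 0.01 and
0.06), and linearly drift the category mixture with time from
(0.34, 0.41, 0.13, 0.025, 0.075, 0.02) to (0.13, 0.645, 0.15, 0.018,
0.045, 0.012): the moderate-purifying share rises with time, the
strong-purifying share falls, and the positively selected share declines
slightly. All randomness derives from a single root seed through spawned
generator streams; identical seeds give byte-identical FASTA and truth
tables.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: gene-wise ω
heterogeneity in realistic category proportions, divergence scaling with
time, a recoverable peak-Ks signal, and a clustered minority among
strong-positive genes. It does not emulate assembly artifacts, expression
filtering, alignment error from real indel processes, codon-usage
variation between genes, rate variation among sites within a gene, or
gene-tree/species-tree discordance. Passing recovery tests therefore
demonstrates correctness of the estimators and summaries under the stated
model, not robustness to those real-data complications.

## Problem sizes in the test suite

The suite exercises the estimators at the sizes where their sampling error
is well characterised: 100 replicates of 2000-codon genes per ω regime for
recovery; 10,000-gene cohorts for rank-order recovery; 20-pair panels of
600 genes × 300 codons for association signs; 1000 null genes (999
permutations each) for cluster-test calibration. These sizes were chosen
as the smallest at which the checked quantities are stable to the asserted
tolerances.

## Known limitations

* The YN00-style estimator is a faithful re-derivation of the counting
  ideas (κ- and frequency-weighted sites, weighted pathways, per-class
  multiple-hit correction), not a line-for-line reimplementation of the
  published yn00 program; small systematic differences from that program
  are expected, and a PAML-format writer is provided for external
  cross-validation.
* RBH pairing is exact for two-taxon comparisons but does not detect
  in-paralogs; genes expressed as one copy per taxon that are paralogous
  between taxa will be paired.
* The cluster test conditions on k and tests spatial arrangement only; it
  has no power for positive selection without spatial aggregation.
* Saturated genes (corrections undefined) are dropped, which slightly
  truncates the high-Ks tail at large t; at the shallow divergences
  targeted here this is negligible.
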