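# pogdiv

Genome-wide profiling of molecular divergence between allopatric taxon
pairs from their putatively single-copy ortholog (POG) pairs.

When two closely related species (or varieties) have been geographically
isolated — for example the classic eastern-Asian / eastern-North-American
disjunct pairs of forest angiosperms — the coding genes they still share
record how selection has acted since the split. For every ortholog pair the
package estimates the synonymous substitution rate *Ks*, the nonsynonymous
rate *Ka*, and their ratio ω = *Ka*/*Ks* (< 1 purifying, ≈ 1 neutral, > 1
positive selection), then summarises a whole transcriptome's worth of genes
into the statistics used for cross-taxon comparison:

* the **Ks distribution** in 0.01-wide bins and its **peak-frequency Ks**
  (modal-bin midpoint, with a near-tie rule that moves the peak to the
  shared boundary of two adjacent bins whose frequencies differ by less
  than 10% of their combined frequency) — a relative divergence proxy;
* the abundances of six **selection categories**: strong purifying
  (ω < 0.1), moderate purifying (0.1–0.5), relaxed purifying (0.5–0.9),
  near-neutral (0.9–1.1), weak/moderate positive (1.1–2), strong positive
  (ω > 2);
* a **clustered-substitution permutation test** for strong-positive
  candidates: are the observed differences packed into a smaller window
  than uniform placement would produce?
* **cross-pair correlations** between divergence time (mya), peak Ks, and
  category abundances, plus a per-gene screen for time trends in ω across
  widely shared genes.

The estimators are authored here: NG86 (equal-weight site counting,
pathway-averaged differences, Jukes–Cantor correction) as the reference
method, and a YN00-style estimator (κ- and codon-frequency-weighted site
counting, ω-weighted pathway averaging, per-class Kimura two-parameter
corrections, iterated to convergence) as the primary method. A codon-model
simulator (rates ∝ κ^[transition] · ω^[nonsynonymous] · π[target]) generates
gene pairs, cohorts, and multi-pair panels with ground truth, so every stage
is testable without any sequence download.

## Worked example

Simulate one taxon pair's cohort (500 genes of 400 codons at the default
selection-category mixture) and run the full per-pair analysis:

```python
from pogdiv import CohortSpec, RunConfig, simulate_cohort
from pogdiv.io import write_cohort
from pogdiv.pipeline import run_pair

genes = simulate_cohort(CohortSpec(n_genes=500, n_codons=400, seed=7))
paths = write_cohort(genes, "demo", "demo")
cfg = RunConfig(fasta_a=str(paths["fasta_a"]), fasta_b=str(paths["fasta_b"]),
                pair_id="demo", out_dir="demo/out",
                pairing="by_id", cds_mode="passthrough", seed=7)
result = run_pair(cfg)
```

The profile printed from `result.profile` for this seed:

```
genes kept: 500/500
peak Ks: 0.065   modified peak Ks: 0.070
  strong_purifying      115  (23.0%)
  moderate_purifying    234  (46.8%)
  relaxed_purifying      99  (19.8%)
  near_neutral           11  (2.2%)
  weak_positive          29  (5.8%)
  strong_positive        12  (2.4%)
purifying (<0.9): 89.6%
cluster candidates (Ka/Ks>2): 12
significant clustering: 1/12
```

Reading this: ~90% of genes are under purifying selection and the category
abundances follow the canonical order (moderate > strong purifying >
relaxed > weak positive > near-neutral > strong positive). The twelve
ω > 2 candidates include genes that merely fluctuated over the threshold —
their substitutions are spread along the gene — and one gene whose changes
are genuinely concentrated in a short window (permutation p = 0.001).

The same workflow is available from the shell:

```bash
pogdiv simulate --mode cohort --n-genes 500 --seed 7 --out-dir demo --pair-id demo
pogdiv all --fasta-a demo/demo_a.fasta --fasta-b demo/demo_b.fasta \
           --pair-id demo --pairing by_id --cds-mode passthrough --out-dir demo/out
```

For real transcript sets use `--pairing rbh` (reciprocal best hit) and
`--cds-mode extract` (longest-ORF extraction over six frames); `pogdiv
associate` then correlates per-pair profiles with divergence times.

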