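# Methods

## Study design being modelled

The package targets a two-generation exposure cross: F0 grandparent
pairs on a folate-deficient (FD, 0.2 mg/kg folic acid) or
folate-sufficient (FS, 2.5 mg/kg) diet, a focal FD-diet F1 male mated
to an unrelated FS female, and their F2 embryos, all whole-genome
sequenced at ~30×. Diet groups A/B/C set which grandparents were on the
FD diet (female / male / both). De novo mutations (DNMs) are counted in
F1 and F2 samples; unrelated FS adults serve as controls for removing
ancestrally shared variants.

## The synthetic generator

The generator emulates the data structure of such a study, not its raw
reads. Its defaults are the study conditions themselves:

| Parameter | Default | Meaning |
|---|---|---|
| `lambda_one_fd` | 87.6 | mean DNMs per F2, one FD grandparent (groups A/B) |
| `lambda_both_fd` | 211 | mean DNMs per F2, both FD grandparents (group C) |
| `lambda_control` | 29.16 | spontaneous expectation (5.4e-9 × 2.7e9 × 2) |
| `lambda_f1` | 38.5 | mean DNMs per focal F1 (77 over two F1 males) |
| `p_mismatch` | 268/575 ≈ 0.466 | probability a DNM is an unrepaired mismatch (true VAF 0.25) |
| `depth_mean` | 30 | sequencing depth (Poisson, truncated ≥ 1) |
| FD spectrum | G:C>A:T = 35.4% | focal-class share under folate deficiency |
| control spectrum | G:C>A:T = 53% | focal-class share on a normal diet |

Per-sample DNM counts are Poisson — the field's default for germline
mutation counts; nothing in the emulated design identifies
overdispersion at these means. Positions are uniform over the unmasked
genome, drawn without replacement, with collisions against background
variants re-drawn. Timing labels are Bernoulli(`p_mismatch`), fixing
true VAF at 0.25 (unrepaired mismatch) or 0.5 (fixed before gamete
formation). Read-level observation is alt ~ Binomial(depth, true VAF);
there is no sequencing-error term, so a non-carrier always shows zero
alternate reads.

Only the focal G:C>A:T proportions are fixed by the emulated study
(53% control, 35.4% FD). The other five class probabilities are a
single choice made from the usual germline spectrum shape
(transition-heavy, Ti/Tv ≈ 2) for the control arm, rescaled
proportionally for the FD arm so each spectrum sums to one. Tests
assert the focal class only.

The genome model is 19 autosomes + X + Y at 1:100 mouse scale (~27 Mb
total), so position draws and window statistics run in seconds. All
rate arithmetic takes genome size explicitly and always uses the
full-scale 2.7 Gb value; the desk-scale genome only hosts simulated
coordinates. Background variation is desk-scale too: 100 heterozygous
founder variants per founder (real mice carry millions) plus a
configurable block of ancestral variants present in every sample —
enough to exercise Mendelian transmission and root-filtering logic
without dominating runtime.

Quality scores default to QUAL ~ U(40, 60) and mapping quality
~ U(50, 60) so that the filters reject only what a test intends; a
`noisy` mode draws both across the filter boundaries. Per-chromosome
coverage profiles give males half-depth X and Y and females near-zero Y,
with 3% multiplicative noise.

What passing tests on this generator do **not** show about real data:
robustness to alignment artefacts, index hopping, cross-sample
contamination, mosaic (sub-0.25 VAF) mutations, or repeat-mediated
miscalls — the generator has none of these failure modes by
construction.

## Filtering and calling conventions

* Depth rule: the hard 20–60× window AND within 3 SD of the sample's
  coverage. Coverage mean/SD default to per-sample statistics over that
  sample's variant records; a genome-wide profile can be supplied
  instead.
* "Minimum quality of 30" is inclusive (≥ 30); "exceeds 30" for mapping
  quality is strict (> 30) — the two phrasings are read literally.
* Variant positions are 1-based; masks and windows are 0-based
  half-open; a position p overlaps [s, e) iff s ≤ p − 1 < e. A window
  of size W therefore receives position p at index (p − 1) // W.
* Indels pass through the SNV rules untouched and are flagged.
* Parental "observed" status uses a lenient presence rule (≥2 alt reads,
  or VAF ≥ 0.05 at depth ≥ 10) rather than the strict candidate filter:
  an inherited variant that merely failed QC in a parent must not
  resurface as a DNM.
* The ancestral-variant step is presence-based set logic: variants
  present in every sibship, or in any control sample, are removed
  everywhere. A phylogenetic reconstruction would identify the same
  universally shared set; set logic does it deterministically.
* DNM calling is defined only for samples with sequenced parents;
  founders (including the unrelated F1 mates) are rejected as focal
  samples.
* Sex inference: male iff Y:autosome depth ≥ 0.25 and X:autosome
  ≤ 0.75; female iff Y ≤ 0.05 and X ≥ 0.75; otherwise ambiguous. The
  comparison is standard; the numeric cutoffs are this package's own
  and sit far from both cluster centres at any realistic depth.

## Timing classification

Observed VAF in [0.30, 0.70] → 2:2; in [0.10, 0.30) → 1:3; otherwise
unclassified. The 0.30 boundary belongs to 2:2 because the two quoted
ranges ("10–30%", "30% to 70%") overlap there; the convention is
configurable (`GenotypeClassRule`). Classification is deliberately
descriptive — no posterior over the true VAF — and the exact binomial
machinery (`expected_misclassification`) quantifies the consequence: at
30×, a true 1:3 variant is misclassified with probability
P(X≤2) + P(X≥9) ≈ 0.27 under Binomial(30, 0.25), which is why observed
1:3 fractions at 30× sit several points below the generating
`p_mismatch`. At depth → ∞ the recovered fractions converge to the
truth (tested).

## Statistical tests

* **Spectrum comparison.** A KS test on categorical spectrum data needs
  a continuous sample; the only construction consistent with that is
  per-sample focal-class fractions. The reference sample is built by
  drawing, for each observed sample with n DNMs, binomial fractions
  Binomial(n, p_ref)/n — the null distribution of the per-sample
  fraction at matched counts. This construction is a package decision
  and is flagged as such.
* **Poisson hotspot test.** Window exposures w_i are the true window
  lengths (terminal windows are shorter); with rate λ = Σc/Σw the
  Pearson statistic Σ(c_i − λw_i)²/(λw_i) is ~χ²(n−1) under the null;
  the p-value is two-sided so under-dispersion is also reported. A
  binned χ² goodness-of-fit (bins merged to expected ≥ 5, df reduced
  for the estimated mean) backs it up on equal-length windows. Windows
  with ≥ 14 mutations are flagged as hotspots by default — a meaningful
  threshold for full-scale 10 Mb windows; on the desk-scale genome use
  a proportionally smaller window. Type-I error is calibrated by
  simulation in the test suite (λ = 3, 100 windows, 1000 replicates).
* **Sex bias.** Two-sample KS on per-sample F2 DNM counts split by
  inferred sex, with medians reported.

## SV screening

Depths are first normalised so sibship members share a common mean.
Candidates overlapping centromere/telomere-proximal intervals (default:
the outer 0.5% of each chromosome end — no distance is prescribed by
the design) are dropped; a candidate is kept iff its region depth
deviates by ≥ 50% from both the genome-wide mean and the flanking
depth; a kept F2 candidate is flagged de novo iff its depth differs
from at least one parent's by ≥ 0.5× that parent's depth (boundaries
inclusive). All rules are ratio-based and scale-invariant (tested).
"Both average values" is read as genome-wide mean + flank. SV discovery
itself is out of scope; the module consumes candidate tables.

## Numerical and reporting conventions

* One seeded `numpy` generator threads through a simulation; derived
  seeds use fixed offsets, and fixture emission is byte-reproducible.
* `expected_dnm_count` returns the exact product (29.16, 76.8);
  rounding to "approximately" integers (half away from zero) happens
  only in report text. The human extrapolation uses the conventional
  baseline of 70 DNMs (and 2.1 deleterious) per generation as explicit
  constants, not the product 76.8 — both appear in reports.
* Degenerate inputs fail loudly: zero depth in `vaf`, zero hematocrit,
  empty sex groups, fewer than 10 windows, single-sample KS, SV rows
  with end ≤ start, masks beyond chromosome ends.

## Problem sizes used in the test suite

Unit and property tests run on toy pedigrees (1–2 sibships, 2–4 F2) and
Monte-Carlo sizes of 10⁴–10⁵ draws; the full suite completes in well
under a minute, and the acceptance script (10⁴ injected DNMs per timing
class, 10⁵ spectrum draws) in a few seconds. These sizes put Monte-Carlo
standard errors an order of magnitude below every asserted tolerance.

## Known limitations

* No mosaic class: true VAFs are exactly {0.25, 0.5}; sub-quarter
  mosaic mutations are neither simulated nor classifiable.
* No sequencing-error model, so parental-dropout false positives can
  only arise through depth, not miscalls.
* The KS construction for spectra is one defensible choice among
  several; with few samples its power is limited.
* Recombination, linkage and phasing are out of scope; inherited
  variants transmit independently.
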