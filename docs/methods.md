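# Methods

## The measurement model behind the estimators

All quantities the package estimates rest on one abundance model. A bait
protein B is distributed among complexes c = 1..K; each complex binds B
through one of its *direct-binder* subunits in 1:1 stoichiometry, so the
molar amount of complex c captured in a pulldown equals the summed molar
amount of its direct binders. A fraction (the *occupancy*) of the bait is
complexed; the remainder is free. MS intensity of protein p in sample s is
modelled as

    I_ps = n_p · N_p · R · ε_ps,     log2 ε_ps ~ Normal(0, σ²)

where n_p is copy number, N_p the count of observable tryptic peptides,
R a single instrument response factor, and ε multiplicative measurement
noise. Dividing by N_p (iBAQ) therefore recovers n_p·R: ratios and shares
of iBAQ values estimate molar ratios and shares. The model deliberately
omits per-peptide ionization efficiency — the peptide-count normalization
is the quantity under test, not spectral physics — so iBAQ closed loops on
synthetic data are exact where real data would show residual
protein-specific bias of typically 2–3 fold.

Missingness is missing-not-at-random: a measurement with log2 intensity x
is lost with probability sigmoid(−k·(x − x₀)). Zero intensity encodes a
missing value throughout (the MaxQuant convention).

## Digestion and observable-peptide counting

Two cleavage rules: Trypsin/P (cut C-terminal of K and R, including
before proline) and an Arg-C-like rule (cut after R only) modelling
tryptic digestion of propionylated histones, where derivatized lysines
block cleavage. With m allowed missed cleavages the products are all runs
of up to m+1 adjacent fully-cleaved fragments, reported with 1-based
coordinates. The iBAQ denominator counts *distinct fully-cleaved* peptide
sequences of length 6–30; the search-engine settings (m = 3 tryptic,
m = 5 propionylated) affect identification, not this denominator, but both
are expressible through `DigestParams`. No mass or charge observability
filter is applied (length-only window); protein sequences are used as
given, with no initiator-Met clipping for the pulldown path.

Correctness is established against a brute-force oracle that enumerates
every contiguous subsequence whose boundaries are termini or cleavage
points and which contains at most m internal sites. The test suite checks
agreement exhaustively for all sequences up to length 6 over the
worst-case alphabet {A,K,R,P} and on seeded random sequences of lengths
7–12 (the property is boundary-combinatorial, so short sequences exercise
every configuration; the random lengths guard the run-length bookkeeping),
and cross-checks the Trypsin/P rule against pyteomics on random 80-mers.

## The label-free differential statistic

The pipeline is: flag filtering → log2 → per-sample median centring →
valid-value filter (≥ 3 present values in at least one group) → MNAR
imputation → Student's t → permutation FDR. Choices that were genuinely
open:

* **Imputation** draws each missing cell of sample s from
  Normal(μ_s − 1.8·σ_s, (0.3·σ_s)²) with μ_s, σ_s from that sample's
  observed values (per-column mode; a whole-matrix mode exists). Width 0.3
  and downshift 1.8 are the workflow's standard parameters and the
  package defaults.
* **Test statistic**: pooled-variance (Student's) t, not Welch. The
  permutation statistic is d = Δ/(s + s₀) with the SAM fudge factor s₀
  defaulting to 0 (configurable).
* **Permutations**: all C(n₁+n₂, n₁) distinct group-label assignments are
  enumerated when their count is at most `n_permutations` (default 250 —
  so 4v4 and 3v3 designs are always exhaustive, identity included);
  otherwise assignments are sampled uniformly without replacement,
  excluding the identity. For each threshold t over the observed |d|
  values, FDR(t) = (mean permuted count of |d*| ≥ t)/(observed count ≥ t);
  q-values are the running minimum of FDR from the smallest |d| upward,
  capped at 1 — the step-up monotonization that makes significance
  order-consistent in |d|.
* **Degenerate variance**: zero pooled variance with a nonzero difference
  yields t = ±∞ and p = 0; with a zero difference, t = 0 and p = 1.

**A note on median centring under composition asymmetry.** Per-sample
median subtraction assumes most proteins are unchanged between samples.
In a bait-vs-control design the bait samples carry the interactors *on
top of* the shared background, which pushes the bait-sample medians up;
after centring, the background drifts slightly negative and — because
label-free replicate noise is small — can reach significance as
*depleted*. This is an artifact of the normalization, not binding, and it
is why interactor lists are read from `EnrichmentResults.enriched`
(significant **and** positive difference) rather than from the raw
significant set. The synthetic planted-interactor screen reproduces the
effect and confirms that the enriched set is clean.

## Complex partitioning, mass balance, ratios

Proportions divide each complex's direct-binder iBAQ sum by the total over
catalog complexes only — free bait and background are excluded from the
denominator and captured instead by the mass balance (direct-binder total
÷ bait iBAQ; values above 1 are flagged as over-assignment). Undetected
direct binders contribute 0 and are listed in the report. Interchangeable
direct binders within a complex are summed. Reported percentages are
rounded to integers; full precision stays in the result frames. iBAQ
means average *detected* treatment-group replicates (zeros are
missingness, not abundance); per-replicate-then-average order is the
default, with summation available.

## Histone acetyl-site quantification

Peptide records are validated against mature-protein reference sequences
(initiator Met removed, so labels like "H3 K18ac" carry the community
numbering; the bundled references are synthetic tail segments with the
canonical site spacing — see `SYNTHETIC_HISTONE_REFERENCES`). Acetyl and
propionyl are mutually exclusive per residue. A multiply-acetylated
peptide contributes only to its combination key, so total intensity is
conserved by the mapping. Quantification is relative (log2 changes), not
site occupancy: no unmodified-peptide normalization is attempted. The
change statistics default to median normalization of log2 site
intensities per sample (total-signal normalization and no normalization
are options); with few quantified sites and large planted changes, median
centring shows the same compression artifact described above, which is
why simulation tests anchor the median with a background of unchanged
sites.

## The synthetic-data generator

`generate_ground_truth` draws a scenario: each complex receives its stated
fraction of bait_amount × occupancy, split among its direct binders by a
Dirichlet draw; non-direct members carry the complex amount times a
per-subunit stoichiometry multiplier (default 1, e.g. 2 for a
doubly-present subunit); background contaminants draw copy numbers
log-uniformly over 10⁻¹–10^1.5 and appear at equal expected intensity in
bait and control samples, while true interactors are absent from control —
the asymmetry the enrichment test needs. Defaults: proportions
0.49/0.28/0.15/0.04/0.03/0.01, occupancy 0.91, 4 bait + 4 control
replicates (the control design is symmetric by assumption and
configurable), log2 noise sd 0.2, dropout midpoint 20 with steepness 1
(≈ 10–20% missingness concentrated in the faint tail, typical of
label-free AP-MS), response factor 10⁵. Random sequences use a combined
K+R frequency of 0.11 and lengths 200–1500. All draws derive from one
master seed through named substreams (ground truth, sequences, noise,
dropout), so enabling or disabling one stage never perturbs another's
values.

What the generator does *not* emulate: peptide-level quantification of
the pulldown (protein-group level only, except the histone table),
per-peptide response differences, retention-time or charge-state
structure, ratio compression between co-eluting species, shared-peptide
protein-group ambiguity. Passing closed-loop tests therefore shows the
estimators are correct under the stated abundance model, not that real
iBAQ values are free of protein-specific bias.

## Problem sizes and numerical choices

The simulation studies in the test suite and acceptance script use sizes
chosen to make the checks sharp yet quick on a single CPU: 100 seeded
runs for the ±5-percentage-point proportion-recovery property, 50 runs of
1000 × (4v4) pure-null matrices for FDR calibration (every 4v4 analysis
is exhaustive over all 70 label assignments), a 148-interactor /
1000-background screen, and the digestion oracle grid described above.
Proportion comparisons on noise-free data are asserted to 1e-9;
median-centring to 1e-12. Ties in |d| are handled by counting all tied
proteins as exceeding the threshold. The histone-site keys sort
lexicographically for deterministic, order-independent output.
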