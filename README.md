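# apquant

Quantitative analysis of affinity-purification mass spectrometry (AP-MS)
pulldowns of a shared enzyme — the HDAC1/2 situation, where one catalytic
subunit is distributed among several competing multiprotein corepressor
complexes (SIN3, NuRD, CoREST, MiDAC, MIER, RERE) — plus the label-free
statistics such an experiment needs and a synthetic-data generator that
makes every stage testable without raw instrument data.

## Who it is for

Proteomics analysts working downstream of a MaxQuant-style search:
you have a `proteinGroups.txt` from a bait-vs-control co-IP, a curated
catalog of complexes and their direct bait-binding subunits, and you want
to know *how the bait is shared among the complexes*, which proteins are
genuinely enriched, and (for histone work) which acetyl sites moved.

## What it computes

**Complex partitioning by iBAQ.** iBAQ divides a protein's summed MS
intensity by its count of theoretically observable tryptic peptides
(fully cleaved, length 6–30), giving a molar-scale abundance. Because each
complex engages the bait through a direct-binder subunit in 1:1
stoichiometry, the share of bait held by complex *c* is

```
p_c = Σ_{d ∈ direct(c)} iBAQ(d)  /  Σ_{c'} Σ_{d ∈ direct(c')} iBAQ(d)
```

with interchangeable paralogous binders summed within a complex. The
**mass balance** — the same numerator divided by the bait's own iBAQ —
says how much of the recovered bait the direct binders jointly explain;
**subunit ratios** iBAQ(a)/iBAQ(b) compare the molar abundance of two
subunits free of protein-length bias.

**Label-free enrichment statistics.** The Perseus-style workflow,
implemented in full: drop reverse/contaminant/site-only rows; log2;
per-sample median centring; keep proteins with ≥ 3 valid values in a
group; impute missing values from a down-shifted Gaussian
N(μ − 1.8σ, (0.3σ)²) per sample (the missing-not-at-random assumption);
two-sided pooled-variance Student's *t* per protein; and permutation-based
FDR on the statistic d = Δ/(s + s₀), exhaustive over group-label
assignments whenever feasible.

**Histone acetyl-site quantification.** Propionylated-histone peptide
records are mapped to mature-protein coordinates and aggregated by
acetyl-site *combination* (a K18+K23 doubly acetylated peptide counts
toward `H3 K18ac+K23ac`, never the single sites), then tested with the
same statistics.

**Synthetic data.** `generate_ground_truth` / `simulate_pulldown` draw
complex-partition scenarios and realize them as protein-group tables with
log-normal measurement noise and intensity-dependent dropout, so the whole
pipeline closes the loop against a known truth.

## Worked example

```python
import apquant as aq

truth = aq.generate_ground_truth(
    proportions=[0.49, 0.28, 0.15, 0.04, 0.03, 0.01], occupancy=0.91, seed=1)
fasta = aq.generate_sequences(truth, seed=1)
dataset = aq.simulate_pulldown(
    truth, fasta, aq.SimulationConfig(noise_sd_log2=0.0, dropout=False, seed=1))
ibaq = aq.compute_ibaq_table(dataset.protein_groups, fasta, dataset.design)
results = aq.ComplexPartitionModel(ibaq, truth.catalog(), bait_id="BAIT").fit()
print(results.summary())
```

prints

```
Complex partition of bait-bound material (direct-binder iBAQ)
  CPX0          49%  (iBAQ sum 4.459e+06, 5 members detected)
  CPX1          28%  (iBAQ sum 2.548e+06, 4 members detected)
  CPX2          15%  (iBAQ sum 1.365e+06, 7 members detected)
  CPX3           4%  (iBAQ sum 3.640e+05, 7 members detected)
  CPX4           3%  (iBAQ sum 2.730e+05, 7 members detected)
  CPX5           1%  (iBAQ sum 9.100e+04, 7 members detected)
  top-3 share: 92%
  bait mass balance (BAIT): 91.0% of bait accounted for
```

i.e. in a noise-free realization the estimator returns the planted
49/28/15/4/3/1 split exactly, the three dominant complexes jointly hold
92% of the bait, and direct binders account for 91% of the recovered bait
(the planted occupancy: the remaining 9% is free bait). On the same
scenario with measurement noise, the enrichment model

```python
noisy = aq.simulate_pulldown(truth, fasta, aq.SimulationConfig(seed=1))
fit = aq.EnrichmentModel(noisy.protein_groups, noisy.design).fit(seed=1)
print(fit.summary())
```

reports the stage-by-stage row counts and the proteins significantly
enriched over control (here 35 at q ≤ 0.05, all of them true complex
members or the bait itself).

The same operations are available from a shell:

```sh
apquant simulate --seed 3 --out demo/
apquant ibaq demo/proteinGroups.txt demo/proteins.fasta demo/design.tsv --out demo/ibaq.tsv
apquant enrich demo/proteinGroups.txt demo/design.tsv --out demo/enrich.tsv
apquant stoich demo/ibaq.tsv demo/catalog.yaml --bait BAIT --out demo/stoich.tsv
```

(`apquant histone`, `apquant overlap` and `apquant diffbind` cover the
acetyl-site, set-overlap and mutant-matrix paths.)

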