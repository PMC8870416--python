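# hrdkit

Genomic-instability (GI) scoring and homologous-recombination-deficiency
(HRD) surrogates from segmented tumor copy-number profiles, with the
clinical association layer of a phase-2 trial translational pipeline and a
synthetic-cohort generator for validating the whole chain.

## Who this is for

Translational groups that profile tumors with a targeted DNA-repair panel
plus a genome-wide SNP backbone, and want to go from segmented copy-number
output (`.cns`-style tables), panel-of-normals genotypes, and a curated
variant table to:

* per-sample copy-number **events** (gains/losses) after purity adjustment,
  a per-segment significance filter (p ≤ 0.001), merging, and a 1 Mb
  artifact filter;
* **LOH** segments called from tumor B-allele frequencies (BAF) at
  constitutively heterozygous SNPs, with the long-LOH (>10 Mb / >15 Mb)
  HRD-signature spans;
* a named **GI parameter vector** per sample (event counts, lengths,
  percentages of the autosomal genome, with and without the BAF 0.3–0.7
  borderline filter, plus the LOH tiers);
* a **mutational HRD** flag (qualifying P/LP or predicted-pathogenic VUS
  variants at ≥100× coverage and VAF >5% in HRR genes);
* trial statistics: ORR/CBR/LTR groupings, exact Clopper–Pearson rate CIs,
  Wilcoxon rank-sum comparisons with Cohen's *d*, Kaplan–Meier/log-rank
  survival, and a parameter-by-grouping association scan with
  Benjamini–Hochberg adjustment alongside raw p values.

## The model in brief

Observed log2 ratio under a two-component tumor/normal mixture with tumor
cell fraction *p* (purity) and tumor copy number *n_t*:

    r = p · n_t / 2 + (1 − p)    ⇒    n_t = (2 · 2^log2 − 2(1 − p)) / p

clamped at 0; gains are called at n_t ≥ 2.5, losses at n_t ≤ 1.5. A het SNP
with tumor allele copies (a, b) has expected BAF

    (p · b + (1 − p)) / (p · (a + b) + 2(1 − p))

so full LOH at purity 0.4 sits at BAF ≈ 0.625 — inside the 0.3–0.7
"balanced" band — which is exactly the purity sensitivity the band-based
LOH call inherits. LOH is decided on the folded BAF (0.5 + |b − 0.5|)
median over ≥10 informative SNPs per segment.

## Worked example

```python
import hrdkit as hk

cohort = hk.simulate_cohort(hk.SimulationConfig(seed=1, n_patients=5))
gi = hk.cohort_gi_table(cohort)
print(gi[["n_events", "n_losses", "pct_genome_loh", "n_loh_gt10mb"]].round(2))
```

```
        n_events  n_losses  pct_genome_loh  n_loh_gt10mb
sample
P001        10.0       4.0           18.09           2.0
P002        11.0      10.0           36.76           4.0
P003         5.0       4.0           30.47           5.0
P004         4.0       0.0            0.00           0.0
P005         7.0       5.0           21.07           2.0
```

Each row is one simulated tumor: `n_events` gains+losses after all filters,
`pct_genome_loh` the percent of the autosomal genome under LOH, and
`n_loh_gt10mb` the count of LOH tracts longer than 10 Mb (the HRD-signature
spans). Patient P002, with a high latent instability level, shows the
expected heavy loss/LOH burden; P004 is quiet.

The same flow is available from the shell:

```sh
hrdkit simulate --n-patients 50 --seed 1 --out runs/cohort
hrdkit gi-features --in runs/cohort --out runs/gi
hrdkit hrd --in runs/cohort --out runs/hrd
hrdkit associate --in runs/cohort --gi runs/gi/gi_features.tsv --out runs/assoc
hrdkit report --in runs/cohort --out runs/report
```

Every subcommand writes a `manifest.json` (resolved config, hash, seed,
version) so runs are auditable and reproducible.

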