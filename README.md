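# circadyn

Analysis of plasma extrachromosomal circular DNA (eccDNA) catalogs, built
for Circle-Seq studies that compare patient groups — in particular type 2
diabetes cohorts sampled before and after short-term intensive insulin
therapy (SIIT) and followed for glycemic remission.

Circle-Seq detectors such as Circle-Map emit one record per candidate
circle with its coordinates and detection statistics (split/discordant
read counts, a score, per-base coverage summaries). `circadyn` consumes
that output schema and implements everything downstream:

* **Filtering** — a circle is kept only if split reads > 2, score > 200,
  mean coverage > coverage sd, coverage increase at both junction edges
  > 0.3, and uncovered fraction < 0.1 (all strict inequalities).
* **Catalog characterization** — EPM (eccDNA per million mapped reads,
  mitochondrial reads excluded), the multi-modal length distribution with
  nucleosome-ladder peak clusters and ~10 bp sub-peak spacing, length
  bands, record-vs-flank GC content, per-chromosome density.
* **Element enrichment** — observed/expected ratios
  `O/E = (fraction of eccDNA starts in class c) / (bp of c / genome bp)`
  for 3′UTR, 5′UTR, CpG, exon, intron, Gene2kbU, Gene2kbD, and normalized
  mapping ratios for the repeat classes (SINE, LINE, LTR, ...).
* **Differential eccGenes** — gene abundance
  `a_g = (n_g / L_g) / Σ_i (n_i / L_i) × 10⁶` (n_g distinct circles whose
  junction falls in gene g, L_g the gene length), two-sided Wilcoxon
  rank-sum per gene with significance at p < 0.05 and |log2FC| ≥ 1, and
  uniquely-present genes by Fisher's exact test.
* **Exon-spanning clusters** — eccDNAs intersecting exons of the same
  gene are clustered; members fully containing an exon are selected and
  compared between groups per exon.
* **Clinical indices** — HOMA-β = 20·FINS/(FPG−3.5), HOMA-IR =
  FPG·FINS/22.5, Matsuda = 10000/√(Glu₀·Ins₀·meanGlu·meanIns), ISSI-2 =
  (AUCins/AUCglu)·Matsuda from 7-point meal-test curves; percent Δ-values;
  remission = FPG < 7 mmol/L and HbA1c < 7 %.
* **Association** — pairwise Pearson correlations of ΔEPM with the
  clinical Δ-values, exon/intron proportion vs FPG, and EPM trajectory
  summaries over pre/post/M6/M12 against remission status.

Because real Circle-Seq cohorts are large and access-controlled, the
package ships a first-class synthetic-data generator
(`circadyn.synthetic_data`) whose defaults encode the catalog structure
such studies report — length clusters at 201 and 338 bp with 10 bp
sub-peaks, a GC mode calibrated to 42.3 %, ~15 % exon-derived starts, a
35-patient pre/post cohort with the expected clinical effect directions,
and a follow-up sub-cohort with remission-dependent EPM trajectories —
so every stage is testable end to end.

## Worked example

```python
import circadyn as cd

config = cd.SimConfig()
genome, annot = cd.build_toy_genome(config, seed=1437)
catalog = cd.simulate_catalog(genome, annot, config, seed=1437,
                              n_records=50_000, timepoint="pre")

peaks = cd.length_peaks(catalog)
prof  = cd.gc_profile(catalog, genome)
print(peaks.centers, peaks.mean_spacing, round(prof.mode * 100, 1))
```

prints

```
[201, 338] 10.0 42.2
```

— the detector recovers the two nucleosome-size cluster centers, the
10 bp sub-peak ladder, and a 42.2 % GC mode from the generated catalog.
On a full simulated cohort (`examples/06_delta_correlations.py`) the
ΔEPM row of the correlation matrix comes out as

```
   x          y      r     p  n
dEPM     dISSI2 -0.524 0.001 35
dEPM   dHOMA_IR  0.209 0.229 35
dEPM       dFPG  0.207 0.234 35
```

meaning patients whose eccDNA load rose most after therapy gained the
least β-cell function (ISSI-2) — the sign pattern the generator encodes.

The `examples/` directory holds one short script per capability
(simulation/characterization, filtering, element enrichment,
differential eccGenes, clinical indices, Δ-correlations).  A thin CLI
mirrors the stages:

```sh
circadyn simulate --seed 1 --out sim/
circadyn filter --in sim/catalogs/P01_pre.tsv --out filtered.tsv
circadyn report --seed 1 --out report/     # full pipeline, one TSV per table
```

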