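# eduseq

Quantification of DNA replication-origin firing, fork recovery and mitotic DNA
synthesis (MiDAS) from binned nascent-strand sequencing tracks, plus the
matching DNA-fiber and microscopy statistics.

## Who this is for

EdU-seq maps origins that fire in early S phase: cells enter S phase in
hydroxyurea (HU), which stalls forks near fired origins, so sequencing of
EdU-labeled nascent DNA yields narrow coverage peaks at those origins.
Comparing peak heights between cell lines (e.g. a parental line versus
CRISPR-edited clones) and between normal and oncogene-induced replication
stress (Cyclin E overexpression) asks whether a gene product changes the
origin-firing program. This package implements the downstream quantification
for such experiments, starting from per-bin read counts (bedGraph), together
with a synthetic-data generator that plants known ground truth so every stage
can be validated end to end.

## The statistic

The genome is divided into fixed bins (10 kb default). An EdU sample is
normalized against a deep genomic-DNA control from the same cells,

    norm_b = (sample_b / control_b) * median(control),

which cancels per-bin library and mappability bias, and converted to **sigma
values** under a Poisson background model with rate λ (trimmed mean of the
normalized track):

    σ_b = norm_b / sqrt(λ).

Background bins sit near sqrt(λ) with unit-scale fluctuations; peak heights
are read in count-noise units. On top of this the package provides:

* **Origin analysis** — peak calling (runs of bins above sqrt(λ)+3), firing
  efficiency (summit-neighborhood max σ), classification by the OE/NE fold
  change ρ = (eff_OE+1)/(eff_NE+1) into constitutive (CN, ρ<2), intermediate
  (2≤ρ<4) and oncogene-induced (Oi, ρ≥4) origins, and per-class cross-sample
  Pearson correlation.
* **Fork dynamics** — adjusted sigma aσ = σ_t − σ_0min after HU release,
  metagene profiles over ±0.3 Mb around origins, and a per-fork speed from the
  growth of the profile's full width at half maximum: rate = Δ(FWHM)/2 / Δt.
  DNA-fiber track lengths convert to rates (length × kb/µm ÷ pulse minutes)
  compared by two-way ANOVA with Fisher's LSD.
* **MiDAS** — EdU-focus positivity (≥2 foci per mitosis), 53BP1-body
  fractions, and region-set signal profiles rescaled to a common relative
  axis, with heatmap rows ranked by region size (double-peak) or signal
  (single-peak), compared by two-way ANOVA with Tukey's test.

## Worked example

```python
from eduseq import (SimulationConfig, simulate_control, simulate_edu_hu,
                    sigma_from_tracks, build_catalog, correlate_catalogs)

cfg = SimulationConfig(seed=7)                      # 2 x 25 Mb, 50 origins
control = simulate_control(cfg)
edu_ne, truth = simulate_edu_hu(cfg, "NE", genotype="WT")
edu_oe, _ = simulate_edu_hu(cfg, "OE", genotype="WT", truth=truth)

sigma_ne = sigma_from_tracks(edu_ne, control)
sigma_oe = sigma_from_tracks(edu_oe, control)
print(f"background lambda = {sigma_ne.background_mean:.1f}, "
      f"background sigma level = {sigma_ne.background_sigma:.1f}")

catalog = build_catalog(sigma_ne, sigma_oe)          # call, quantify, classify
print(f"origins called: {len(catalog)}, class counts: {catalog.class_counts}")

clone_ne, _ = simulate_edu_hu(cfg, "NE", genotype="KO", truth=truth)
summary = correlate_catalogs(catalog, sigma_ne,
                             sigma_from_tracks(clone_ne, control))
for label, d in summary.classes.items():
    print(f"{label:>12}: n = {d['n']:2d}, Pearson r = {d['pearson_r']:.3f}")
```

Output:

```
background lambda = 97.2, background sigma level = 9.9
origins called: 53, class counts: {'CN': 37, 'intermediate': 8, 'Oi': 8}
          CN: n = 37, Pearson r = 0.987
intermediate: n =  8, Pearson r = 0.995
          Oi: n =  8, Pearson r = 0.992
```

The planted truth is 50 origins, two thirds CN and one sixth each
intermediate/Oi; the catalog recovers the counts (with a few near-threshold
extras) and — because the "KO" track was simulated from the *same* firing
program — per-class correlations near 1, the signature of a genotype with no
effect on origin firing.

## Command line

One subcommand per analysis, TSV outputs plus a JSON run manifest:

```bash
eduseq simulate --seed 3 --out fixtures/          # full fixture directory
eduseq sigma   --sample fixtures/edu_NE.bedgraph --control fixtures/control.bedgraph \
               --genome fixtures/genome.chrom.sizes --out ne
eduseq origins --sigma-ne ne.sigma.bedgraph --sigma-oe oe.sigma.bedgraph \
               --genome fixtures/genome.chrom.sizes --out origins/
eduseq forks   --zero rel0.sigma.bedgraph --track 30:rel30.sigma.bedgraph \
               --track 90:rel90.sigma.bedgraph --origins origins/origin_catalog.bed \
               --genome fixtures/genome.chrom.sizes --out forks/
eduseq fibers  --fibers fixtures/fibers.tsv --out fibers/
eduseq midas   --sigma md.sigma.bedgraph --regions fixtures/midas_regions.bed \
               --genome fixtures/genome.chrom.sizes --foci fixtures/midas_foci.tsv --out midas/
```

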