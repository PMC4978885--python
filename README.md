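# ltrtracer

Comparative quantification of LTR retrotransposon content from
low-coverage short reads, by graph clustering with tracer kmers.

## The problem

In plant genomes the dominant repeats are Class I long terminal repeat
(LTR) retrotransposons of the *gypsy* and *copia* superfamilies, and
their differential amplification drives much of the variation in genome
size between even closely related species.  At the sequencing depths
typical of comparative surveys (~0.2-0.7x per species) assembly is
impossible, but repeat abundance is still measurable: in an all-by-all
similarity graph over a few million randomly sampled 100 bp reads,
reads derived from a repeat family cluster together (they match reads
from other copies of the family), while single-copy sequence stays
unclustered.  `ltrtracer` implements this estimator end to end for
people doing comparative TE biology on unassembled genomes:

* **read preprocessing** — end/window quality trimming (Q30 / mean Q25
  in 4 bp windows, minimum 80 bp), chloroplast read removal, random
  subsampling (default 3 M single-end reads);
* **tracer panel** — a reference panel of full-length *gypsy*/*copia*
  elements decomposed into 100 bp kmers with 85 bp overlap, mixed into
  the clustering so clusters inherit superfamily/sublineage labels;
* **graph clustering** — edges at >= 90% identity over >= 55% overlap
  (mgblast-style), clusters = connected components, repetitive fraction
  = reads in clusters holding >= 0.01% of the sample;
* **abundance profiles** — per-sublineage genome proportions with
  replicate mean ± SE, and the gypsy:copia fold ratio;
* **mapping comparison** — a read-mapping estimator (mismatch-ceiling
  assignment to the panel) and a divergence-bias assay showing why
  mapping under-counts diverged genomes while clustering does not;
* **comparative statistics** — coverage arithmetic (C = LN/G, 1 pg =
  978 Mb), Pearson correlation of genome size against repetitive
  fraction, and phylogenetically independent contrasts (Felsenstein)
  with drop-tip pruning;
* **synthetic data** — panels, genomes with known family composition,
  reads, and correlated Brownian tip traits, so every stage is testable
  against ground truth.

## Worked example

Simulate a study-like species genome (five sublineages spanning
4.3-16.2 kb elements, ~70% repetitive, ~4.5-fold more gypsy than copia
bases), read it at ~0.6x, and recover its composition:

```python
from ltrtracer.synthetic import (study_like_specs, simulate_reference_panel,
    simulate_species_genome, simulate_reads, ReadSimConfig,
    STUDY_BACKGROUND_LENGTH, STUDY_MIN_SPACING)
from ltrtracer.tracers import kmerize_panel
from ltrtracer.clustering import cluster_sequences, repetitive_fraction
from ltrtracer.abundance import sublineage_profile, superfamily_ratio

specs = study_like_specs()
panel = simulate_reference_panel(specs, seed=0)
genome = simulate_species_genome(panel, specs, STUDY_BACKGROUND_LENGTH,
                                 seed=1, min_spacing=STUDY_MIN_SPACING)
reads = simulate_reads(genome, ReadSimConfig(n_reads=50_000, error_rate=0.005, seed=2))
tracers, counts = kmerize_panel(panel)

clusters = cluster_sequences(reads, tracers)
estimate = repetitive_fraction(clusters, n_sampled=len(reads))
profile = sublineage_profile(clusters, len(reads),
                             {t.sublineage: t.superfamily for t in tracers})

print(f"repetitive fraction: {estimate.repetitive_fraction:.3f} "
      f"(truth {1 - genome.background_fraction:.3f})")
by_sub = {s.sublineage: s.family_id for s in specs}
for sub, prop in sorted(profile.proportions.items()):
    truth = genome.truth_table[by_sub[sub]]
    print(f"  sublineage {sub}: {100 * prop:5.2f}% of reads (truth {100 * truth:5.2f}%)")
print(f"gypsy:copia fold = {superfamily_ratio(profile):.2f}")
```

Output (about a minute on one core):

```
repetitive fraction: 0.702 (truth 0.698)
  sublineage 1:  9.19% of reads (truth  9.45%)
  sublineage 2:  3.25% of reads (truth  3.21%)
  sublineage A: 28.67% of reads (truth 28.68%)
  sublineage B: 16.93% of reads (truth 16.75%)
  sublineage C: 11.85% of reads (truth 11.75%)
gypsy:copia fold = 4.62
```

Each sublineage's genome proportion is recovered within its binomial
sampling error, and the gypsy:copia fold matches the 4.52 built into the
genome.  The same stages are scriptable from the shell:

```bash
ltrtracer simulate --out run/sim --seed 1 --n-reads 50000
ltrtracer cluster  --reads run/sim/reads.fastq --panel run/sim/panel.fasta \
                   --panel-meta run/sim/panel_meta.tsv --n-sample 50000 --out run/cluster
ltrtracer quantify --reads run/sim/reads.fastq --panel run/sim/panel.fasta \
                   --panel-meta run/sim/panel_meta.tsv --n-sample 20000 --runs 5 --out run/quantify
ltrtracer stats    --out run/stats
ltrtracer compare-mapping --out run/bias
```

Every subcommand writes a `config.json` snapshot (parameters, seeds,
version), and identical seeds give byte-identical outputs.

The packaged species table (nine diploid sunflower species and an
outgroup, with flow-cytometry 2C genome sizes and clustering-derived
repetitive fractions) and study tree topology feed the comparative
layer: `ltrtracer.comparative.study_correlations()` prints the ordinary
Pearson correlation of genome size against repetitive fraction
(r = 0.9121, P = 0.0006, n = 9) and the contrasts-adjusted correlation
on the packaged unit-branch-length topology (r = 0.909, 8 tips, the
hybrid-origin species excluded).

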