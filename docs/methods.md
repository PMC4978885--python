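# Methods

## The estimation problem

Low-coverage shotgun reads (~0.2-0.7x) cannot be assembled, but the
repetitive part of a genome can still be quantified from them: reads
drawn from a repeat family are near-identical to reads from *other*
copies of the same family, so an all-by-all similarity graph over a
random read sample concentrates repeat-derived reads into large connected
components while single-copy reads stay (nearly) isolated.  The fraction
of sampled reads falling in large components estimates the genomic
repetitive fraction, and mixing reference-derived "tracer" kmers into the
clustering transfers family labels onto components without assembly.

## Clustering rule

Two sequences are joined when their best overlap (free-end-gap) alignment
reaches **>= 90% identity** over an overlap of **>= 55%** of the shorter
sequence (both inclusive).  Alignment scoring is match +1, mismatch -2,
gap -3; identity is matches / aligned columns (internal gaps count as
columns); the overlap is measured in aligned columns and compared against
the shorter sequence, which is immaterial for uniform 100 bp reads and
tracers but matters for quality-trimmed reads down to 80 bp.  Both
orientations of the second sequence are tried; deterministic tie-breaks
(diagonal > gap-in-b > gap-in-a; endpoint ties prefer more matches, then
more columns) make results reproducible bit-for-bit.

Clusters are the connected components of this graph.  A component counts
toward the repetitive fraction when it holds at least **0.01%** of the
sampled reads (ceiling; 300 reads at 3 M sampled, 5 at 50 k).  An
optional Louvain community-detection pass can further split components,
but it is off by default: the estimator is defined purely by the
similarity thresholds.

### Exact and scale execution paths

*Exact path* (default up to 1500 sequences): candidate pairs are
prefiltered by a shared canonical exact k-mer.  Pigeonhole argument: an
alignment with identity `i` over `V` columns has at most `floor((1-i)V)`
non-match columns, splitting the matches into at most that many + 1 runs,
so the longest run — a shared exact substring — has at least
`ceil(matches/(errors+1))` bases; minimised over feasible `V` this gives
k = 8 at the default thresholds.  The prefiltered edge set therefore
*equals* the brute-force all-pairs graph (asserted against an all-pairs
oracle in the tests).

*Scale path* (union-find): only connected components are resolved.
Candidate pairs come from shared canonical 11-mers; pairs already in one
component are skipped, greedy passes (bucket anchor + consecutive member
pairs) coalesce the bulk, and exhaustive within-bucket passes then catch
rare bridge pairs until no merges occur.  Failed pairs are cached by
member pair (sound, because pairwise alignment is deterministic).  A
rigorous rejection screen runs before each DP: a qualifying pair must
share at least `matches - 7*(non-match columns + 1)` common 8-mers
(multiset count over sorted per-sequence 8-mer arrays), so pairs below
that bound are rejected without alignment.  The 11-mer candidate
generation is probabilistic per pair (the guarantee is only k = 8), but
component recovery is redundant — any path of qualifying edges connects a
component — and the suite asserts partition equality with the exact path
on mixed 500-sequence inputs.

## Tracer kmers

Each full-length LTR retrotransposon of the reference panel is decomposed
into 100 bp windows advancing by 15 bp (85 bp overlap), i.e.
`floor((L-100)/15)+1` windows per element of length `L`; no 3'-anchored
tail window is emitted, so up to 14 terminal bases go untraced.
Consecutive windows overlap by 85 identical bases — far beyond the
90%/55% rule — so the tracer set of one element always forms a single
connected component, and any read bridging to *any* tracer annotates its
whole cluster.  Tracers are annotation probes only: they are excluded
from the sampled-read count, the cluster-size rule, and all abundance
numerators, since counting them would inflate panel-like families.

Cluster annotation is by majority tracer sublineage, with an ambiguity
flag when the top sublineage holds < 80% of the cluster's tracers or when
tracers mix the gypsy and copia superfamilies (chaining artefacts are
flagged, never silently resolved).

## Read preprocessing

Quality rules: terminal bases below Q30 are stripped; read ends are
trimmed while a terminal 4-base window has mean quality < Q25; reads
shorter than 80 bases are discarded.  The two trimming rules iterate to a
fixed point so trimming is idempotent.  Organelle (chloroplast) reads are
removed by k-mer containment: a read is dropped when >= 50% of its
31-mers occur in the organelle reference k-mer set (both strands) — a
transparent stand-in for read mapping with one interpretable threshold.
Clustering input is a uniform random sample without replacement
(default 3 M reads; smaller datasets are used whole, with a notice).
Replicate analyses (default five runs) resample independently; summaries
are mean +/- SE (sample SD / sqrt(runs)).

## Read-mapping comparison

The alternative estimator maps each read to the panel by ungapped
mismatch counting over all offsets (exact 13-mer seeds guarantee a hit
for any alignment within 6 mismatches per 100 bases; both strands), and
assigns it to the element with the fewest mismatches if the count stays
within the policy — stringent 3 or relaxed 6 mismatches per 100 aligned
bases, with at least 55% of the read aligned inside the element.  Because
each read must individually clear the ceiling, mapped density decays as
genomic copies diverge from the panel (a binomial tail), whereas a
cluster stays annotated as long as *one* read bridges to the tracers.
The divergence-bias assay simulates genomes at fixed true abundance
across a panel-divergence grid (0-12%) and reports each method's Spearman
rank correlation of density against divergence: mapping is consistently
negative (stringent and relaxed), clustering shows no negative trend.

## Synthetic data

The generator provides ground truth for every stage.

* **Panel**: one exemplar per family; two identical terminal repeats of
  length `min(400, L/4)` flank a random internal region (LTR lengths for
  the real panel are unpublished; this convention is arbitrary but
  harmless since tracers tile the whole element).
* **Genomes**: a uniform-random background carrying `copies` mutated
  copies of each family.  Copies derive from a family ancestor such that
  copy-to-copy divergence averages `copy_divergence` and copy-to-exemplar
  divergence averages `panel_divergence` (requires `panel_divergence >=
  copy_divergence/2`; clamped otherwise).  Mutation is substitution-only
  by default so identity arithmetic against the 90% threshold stays
  exact; small indels are available behind `indel_rate`.  The truth table
  records exact per-family base fractions.
* **Reads**: uniform start positions (no GC or coverage bias), uniform
  strand, per-base substitution errors (default 0.5%), flat Q38 quality
  profile, sampling with replacement.
* **Brownian traits**: two traits evolve along a phylogeny with per-branch
  bivariate normal increments of variance `sigma^2 * branch` and a set
  increment correlation, for validating the independent-contrasts
  machinery by simulation.

### Study-like scenario

The default recovery scenario uses five sublineages (gypsy A/B/C, copia
1/2) with element lengths spanning 4.3-16.2 kb, a ~4.5-fold
gypsy-to-copia base ratio, 2% copy divergence, 3% panel divergence, and a
2.65 Mb background: a ~8.8 Mb genome at ~70% repetitive fraction, read at
~0.6x by 50 k 100 bp reads.  Copies are placed with >= 500 bp of
background between insertions.  This dispersed placement is deliberate:
with unconstrained placement, adjacent insertions create chimeric TE-TE
junctions whose reads chain two families into one component (a real
phenomenon in nested-TE genomes), which makes per-family ground truth
ill-defined; recovery experiments need identifiable truth.

### What the simulation does not model

Insertion-age structure, solo LTRs, truncated elements, nested
insertions, satellite/low-complexity DNA, GC-biased coverage, indel
sequencing errors, and paired-end information are all absent.  Passing
recovery tests therefore show that the estimator is correct *under its
own assumptions* (dispersed repeats, substitution-dominated divergence,
uniform low coverage) — not that real libraries are free of the
corresponding biases.

### Known estimator bias at desk scale

Reads starting in the background just upstream of a copy, but overlapping
it by >= 55 bp, legitimately join the family's cluster; reads starting in
the last ~50 bp of a copy may fail to.  These flank effects nearly cancel
but leave a small positive bias in the total repetitive fraction of order
`copies x 50 bp / genome length` (≈ +0.3-0.7% in the study-like scenario,
against a ~0.2% binomial SE at 50 k reads).  The bias shrinks with
element length and becomes negligible relative to sampling error at the
full 3 M-read, multi-kb-element survey scale.

## Comparative statistics

Genome sizes convert at 1 pg = 978 Mb; sequencing coverage is
`C = L * 2N / (1C * 978e6)` for read length `L` (default 100; the
post-trim average of a real library is slightly lower and can be passed
explicitly) and `N` read pairs, against the haploid 1C = 2C/2 size.
Coverages are reported at two decimals, round-half-even.

Cross-species association of genome size and repetitive fraction uses the
ordinary Pearson product-moment correlation (two-sided t, df = n-2) and
phylogenetically independent contrasts: Felsenstein's post-order
algorithm (contrast = daughter difference / sqrt of summed adjusted
branch lengths; node value = branch-length-weighted daughter average;
parent branch extended by the product-over-sum correction), correlation
of contrasts computed through the origin, p from t with
(contrasts - 1) df.  Polytomies raise; tips are pruned with drop-tip
semantics (unifurcations suppressed, branch lengths summed), and the
hybrid-origin species is excluded from the adjusted analysis.  The
implementation agrees with a generalized-least-squares oracle under the
Brownian covariance to 1e-10 and with R's `ape::pic` to machine
precision (frozen reference values in the tests).

The packaged species tree is the study topology with **unit branch
lengths** — the study's branch lengths were not published — so the
adjusted correlation reported here (r ≈ 0.909 on the packaged table) is a
function of that convention; user-supplied trees with real branch lengths
can be swapped in.  The ordinary Pearson r = 0.9121 is
convention-free and reproduces exactly.

## Problem sizes and determinism

Desk-scale defaults — 50 k-read recovery runs, 8 k-read bias assays over
five divergence levels, 500-sequence oracle comparisons, 100-tree
contrast recovery — complete in minutes on one core while leaving every
estimate's sampling error well inside the tolerances tested.  All
randomness flows through explicit integer seeds (numpy `default_rng`);
identical seeds yield byte-identical outputs, including cluster tables
and FASTQ files.
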