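# Methods

## The inference problem

Host-restricted bacterial symbionts erode: relaxed selection, bottlenecks
and deletion bias first pseudogenize genes, then delete them. When several
related, genome-eroded, BGC-carrying symbionts are found in related hosts,
two histories can explain them: (i) one ancestral acquisition followed by
codiversification, or (ii) repeated independent acquisition of related
strains from an environmental pool, each followed by erosion. The package
operationalizes the discriminating observables: monophyly of the eroded
symbionts on a core-genome phylogeny, the parsimony-minimum number of
free-living → symbiotic transitions, topological congruence between
symbiont and host trees, ANI/AF species structure, per-genome erosion
level, and the compositional anomaly of the BGC.

## Decision rule

Let `E` be the set of genomes that carry a BGC interval and whose called
pseudogene fraction is ≥ 5% (free-living baselines sit at ~0%, so any
material fraction flags erosion; the threshold is a config knob). If `E` is
empty the call is `ambiguous` ("no eroded symbionts detected"). Otherwise,
with `M` = monophyly of `E` on the inferred tree, `T` = Hartigan/Fitch
minimum transitions for the binary eroded/other character, and `C` =
shared-bipartition fraction between the symbiont tree restricted to `E` and
the host tree (via the symbiont→host mapping):

* `M` and `C ≥ 0.9` → `single_acquisition_codiversification`
* `not M` or `T ≥ 2` → `multiple_independent_acquisitions`
* otherwise → `ambiguous`

The erosion dispersion (coefficient of variation of pseudogene fractions
across `E`) is reported but deliberately not gated on: heterogeneous
erosion is suggestive of staggered acquisitions but is a weaker, continuous
signal.

## Pseudogene calling and HGT filtering

The caller is purely length-based against each gene's best protein hit:
pseudogene iff `qlen/slen < 0.8` (strict inequality; the boundary is kept
intact). The 0.8 default is a common pseudogene-length convention; it is a
parameter, echoed in output. Genes without hits are tri-state
`unclassified` and excluded from both tallies, since counting them either
way would bias heavily eroded genomes. Putative horizontal transfers are
genes with best-hit identity < 50% (amino-acid level) or without the native
taxon token as a case-sensitive substring of the subject title.

Annotation pseudogene flags are treated as priors that hit-based calls
overwrite; this separates I/O from inference and lets the same genome be
re-called at different thresholds.

## Orthology and the core

Proteins (bacterial translation, internal stops read as X) are clustered
into orthogroups as connected components: an edge joins two proteins when
global-alignment identity ≥ 0.5 over ≥ 0.5 of the longer sequence
(identity = (L − edit distance)/L with L the longer length — a conservative
bound). A sparse 4-mer cosharing prefilter skips pairs that cannot reach
the identity floor; a `prefilter=False` path exists and is tested equal.
This is a deliberate desk-scale simplification of tree-reconciled
hierarchical orthogroups: deterministic, order-independent, and adequate at
simulated divergences.

Following the source procedure for the phylogeny, pseudogenes are removed
from each genome *before* clustering, and putative-HGT genes are excluded
at core selection (any orthogroup containing an excluded gene is dropped
whole). Core orthogroups must be single-copy everywhere and present in
strictly more than X% of genomes. The pipeline starts at X = 90% and walks
the ladder 80 → 70 → … until at least `min_core_loci` (default 3) loci are
usable for the concatenation. Descending further than needed was tested and
rejected: low-prevalence loci are missing precisely in the most eroded
genomes, and the resulting gap pattern makes pairwise distances
inconsistent across pairs, degrading topology recovery.

## Distances and trees

Core loci are concatenated; pairwise p-distances use only sites where both
sequences have an unambiguous base, Jukes–Cantor corrected by default
(`d = −¾ ln(1 − 4p/3)`) because symbiotic branches evolve several-fold
faster than free-living ones and uncorrected p-distances lose additivity
exactly where it matters. Neighbor joining is the canonical Saitou–Nei
algorithm with two determinism guarantees: Q-ties break by lexicographic
taxon-pair label, and negative branch lengths are clamped to zero with the
deficit moved to the sister branch. Bootstrap resamples alignment columns
and reports bipartition percentages.

All tree comparisons run on bipartitions encoded as canonical tip-label
frozensets, so polytomies and arbitrary rootings are handled natively.
Transition counting uses Hartigan's generalization of Fitch's recursion,
which is exact on polytomies (plain Fitch is not); it is validated against
exhaustive enumeration of internal labelings. Tanglegram congruence
restricts both trees to the mapped tips (many-to-one symbiont→host maps
keep the lexicographically smallest symbiont per host), relabels, and
reports shared-bipartition fraction `1 − |A△B|/(|A|+|B|)`; for binary trees
on identical tips this equals `1 − RF/2(n−3)`. Per-node congruence flags
mark which symbiont-tree bipartitions exist in the host tree.

## Composition

Canonical k-mer counting identifies each k-mer with its reverse complement
(lexicographic minimum), making vectors strand-invariant; for odd k the
space has 4^k/2 dimensions (512 at the default k = 5, chosen to match
pentanucleotide practice). Windows containing N are skipped. Ordination is
classical metric scaling (double-centered squared distances, top-2
eigenvectors); coordinates are defined up to rotation/reflection, so
consumers should compare distances, not axes. The BGC anomaly score ranks
the BGC-to-genome distance against non-overlapping background windows using
mid-ranks, so under the null it is approximately uniform on [0, 100]. The
op defaults (20 kb windows, 10 kb step) suit real replicons; the pipeline
default (4 kb/2 kb) suits simulator-scale genomes of tens of kb. Both are
config values.

## ANI and species

Query genomes are cut into consecutive 1020 bp fragments (the classical
fragment length; trailing stubs shorter than 70% of a fragment are
skipped). Each fragment is located in the target by exact 15-mer seeds
(both strands), and aligned to the best-supported diagonal's window with
free end-gaps in the target. Fragments with no seed are *unaligned*: this
matters, because forcing a global alignment of non-homologous DNA yields
~50% edit identity and would inflate aligned fraction. At 15 bp, a seed
survives 5% divergence with probability 0.46 per position — hundreds of
chances per fragment — while chance hits in a 50 kb genome are rare.
Directional ANI is the mean identity of passing fragments; directional AF
is passing-fragment bp over query bp; pairs are symmetrized by arithmetic
mean, with directional values retained. Species are connected components at
ANI ≥ 95% and AF ≥ 60%; component naming follows the smallest member, so
output is order-independent. Chaining is a known property of
connected-component species assignment and is documented rather than
hidden.

## The simulator

The generator writes the study conditions, not a fit to any dataset:

* Host tree: Yule pure-birth, scaled to height 1.0 (the time unit); all
  rates are per unit height. Default 8 hosts.
* Ancestral genome: 120 genes, mean 300 bp (codon-rounded, ≥ 60 bp), GC
  0.59 — the GC of the real eroded symbiont's genome; intergenic spacers
  mean 120 bp. One mid-genome gene is labeled `polA` (COG L); other genes
  draw random COG letters. 5% of genes carry a foreign-taxon hit title to
  exercise the HGT filter.
* BGC: 9 genes (the lgaA–lgaI count), mean 600 bp, GC 0.49 — ten points
  below background, matching the compositional-anomaly regime the analysis
  targets. Intergenic DNA inside the cluster also carries the donor GC;
  without that, the configured ΔGC would be diluted by host-composition
  spacers.
* Free-living evolution: Jukes–Cantor substitutions at 0.02 subs/site per
  unit height; each free-living tip loses the BGC with probability 1.0 by
  default (the free-living clade's secondary loss).
* Symbiotic evolution: substitution rate ×3, ×2 again once `polA` is
  pseudogenized (repair-loss acceleration); pseudogenization as a per-gene
  Poisson process at rate 1.5/unit (an event truncates the annotation to a
  U[0.1, 0.7] fraction, leaving the remnant DNA as intergenic sequence);
  existing pseudogenes deleted at 0.15/unit. With symbiotic durations of
  0.1–0.7 units these rates produce pseudogene fractions of roughly 15–60%,
  bracketing what eroded defensive symbionts actually show (~20–45%).
* Scenarios. *Codiversification*: one eligible free-pool lineage acquires
  the symbiosis partway down its terminal branch and the host tree is
  grafted there, so the true symbiont tree restricted to symbiotic tips
  equals the host tree exactly. *Independent acquisitions*: donors are
  drawn from the pool under three ground-truth conditions that define
  "n independent acquisitions from a diverse pool" — the parsimony-minimum
  transition count equals n; every donor sits on a terminal branch ≥ 0.25
  (established associations: all observed symbionts are substantially
  eroded); and every internal edge between two donors is ≥ 0.05 (diverse
  pool). The last condition excludes draws whose distinguishing edges carry
  only a handful of expected substitutions in the whole core — below the
  information limit of any reconstruction method at this scale.
* Hit tables compare each extant gene to its unmutated ancestral copy;
  percent identity comes from realized substitutions over the annotated
  span.
* `high_signal_codiversification_config` (300 genes, substitution rate
  0.05, pseudogenization 0.5) is the package's definition of a high-signal
  codiversification dataset: enough surviving core loci and substitutions
  that the scaled host topology is fully recoverable, which is what a
  congruence-of-1.0 expectation presumes.

Determinism: one `numpy` Generator drives everything; iteration orders are
sorted; identical configs give byte-identical emitted files (hash-checked
in tests and in the acceptance script).

### What the simulator does not emulate

No recombination, gene gain (beyond the single ancestral BGC insertion),
rearrangement, codon-aware selection, strand asymmetry, or sequencing
error; pseudogenization is truncation only (matching the length-based
caller), not internal stops or frame degradation; genomes are single
replicons. Passing tests therefore show that the inference chain recovers
the truth under the stated generative model — they do not certify
performance on real MAGs, where assembly artifacts, annotation noise and
model misspecification add error the simulator does not represent.

## Numerical and degenerate-input choices

Percentile ties use mid-ranks. NJ inputs must be symmetric to 1e-12.
All-identical ordination input returns points at the origin with a warning.
Genomes with zero genes report zero densities with a warning rather than
erroring, so survey loops do not die on an empty bin. Saturated p ≥ 0.75
raises under JC correction. BED intervals are converted to 1-based
inclusive coordinates on read and back on write. Readers reject coordinate
violations, ambiguity codes other than N, duplicate identifiers and
missing GFF3 headers outright — no clamping.

## Problem sizes

Default analyses use 10–14 genomes of ~40–60 kb with 120–300 genes; the
scenario-recovery batteries use 50 simulated datasets and the caller
battery 20; anomaly nulls use 200 replicates of 0.3–0.5 Mb genomes. These
sizes give every statistic enough replication to be meaningful while
keeping any single analysis in seconds and full batteries in minutes.

## Known limitations

Connected-component orthology can merge paralog families bridged by a
chimeric or slowly diverging member; the ANI aligned fraction depends on
seed sensitivity and so mildly on divergence; congruence is purely
topological (branch lengths are ignored); the scenario rule is a hard
threshold on noisy statistics near its boundaries — borderline datasets
are reported `ambiguous` by design rather than forced into a call.
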