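# Methods

`primerbias` quantifies how the choice of 16S rRNA primer pair distorts
marker-gene community profiles and the microecological inferences drawn from
them. Because the true composition of a community is unobservable in real
sequencing data, every analysis here runs on a synthetic survey whose truth
is known; the primer "lens" is an explicit observation model whose knobs can
be turned on and off, so each downstream statistic can be checked against the
mechanism that is supposed to drive it.

## The generative model

**Regional pool and habitats.** A regional pool of `n_taxa` relative
abundances is drawn log-normal (shape `lognormal_sigma`, default 1.5 — a
typical skew for amplicon surveys) and normalized. Each habitat's profile is
a mixture `(1 - s) * pool + s * habitat_draw` with specialization `s in
[0, 1]`; `s = 0` makes all habitats identical. An optional
`phylo_filtering` weight concentrates the habitat-specific component in one
randomly chosen clade (15–40% of tips), emulating phylogenetically conserved
habitat filtering. The default survey design is five habitats with 36 / 7 /
79 / 40 / 12 biological samples (water, sediment, soil, leaf, gut), each
observed under two primers.

**Phylogeny and taxonomy.** The tree is pure-birth with exponential waiting
times, guaranteeing positive branch lengths and reproducibility. Rank labels
(phylum … genus) are nested contiguous blocks along the tree's leaf order, so
taxonomy follows clades the way real classifications roughly do. Functions
are assigned per genus (0–3 of 20 labels; ~15% of genera unannotated) and
inherited by member taxa — a stand-in, synthetic taxonomy-to-function map in
the role a database like FAPROTAX plays for real data.

**Primer lens.** A primer profile has (i) a 0/1 coverage mask over taxa
(optionally masked genus-wise), (ii) strictly positive log-normal
amplification-efficiency factors, shared across habitats by default — the
lever behind cross-habitat bias consistency — or drawn independently per
habitat, and (iii) an optional resolution merge lumping taxa. A sample's
pre-sequencing weights are `composition * coverage * efficiency`,
renormalized; reads are multinomial at the configured depth.

**Biology vs observation noise.** With `dispersion > 0` each biological
sample's true composition is a Dirichlet draw around its habitat profile
(concentration `profile / dispersion`). The draw is keyed by a
`biology_seed` shared between the two `apply_primer` calls, so both primers
observe the *same* biology — as two amplifications of one DNA extract do.
This separation matters: without shared biology the two primers' distance
matrices decorrelate for reasons that have nothing to do with primers. The
pipeline defaults (`habitat_specialization = 0.8`, `dispersion = 0.02`,
`efficiency_sigma = 0.4`, coverage 1.0 vs 0.9, depth 20 000) were chosen so
the simulated survey reproduces the variance regime of real multi-habitat
surveys — habitat explains several-fold more community variance than primer
choice, and the two primers' Bray–Curtis matrices stay strongly
Mantel-correlated — and they are the conditions the end-to-end tests run
under.

**What the generator does not emulate.** No nucleotide-level sequences, no
chimeras or in-silico PCR, no sequencing error model, no compositional
correlation structure among taxa beyond the shared pool, and the
taxon-function map is random rather than phylogenetically conserved beyond
genus level. Passing tests therefore demonstrate correctness of the
statistical machinery and the direction of primer-driven artifacts under a
controlled mechanism — not that any particular real survey behaves
quantitatively alike.

## Statistics

**Hill numbers.** `q = 0` richness, `q = 1` exp(Shannon), otherwise
`(sum p_i^q)^(1/(1-q))`; non-increasing in `q`.

**Bias vectors.** Per taxon (or per rank after aggregation):
`log2((mean relA_A + eps) / (mean relA_B + eps))` with pseudocount
`eps = 1e-6` on the relative-abundance scale — below any realistic detection
limit at the depths used, keeping log ratios finite. "Major" taxa are those
with mean relative abundance ≥ 0.1% in at least one primer data set.
Significance uses a paired sign-flip permutation test on per-pair log2
ratios (exact enumeration up to 12 pairs, else Monte-Carlo with
`p = (b+1)/(n+1)`), with Benjamini–Hochberg correction across taxa; this
replaces a negative-binomial GLM test, which tests the same directional
claim without a model fit.

**SAD and KLD.** The species abundance distribution is a Gaussian KDE of
log10 mean relative abundance per taxon (zeros excluded), Silverman
bandwidth, 256-point grid spanning the observed range ± 3 bandwidths,
renormalized to sum 1. KLD is computed in bits after flooring both densities
at `eps` and renormalizing; comparisons always share one grid built from the
pooled support.

**Attribution strategies.** Coverage effects are removed by restricting both
tables to genera detected in both ("shared-genus restriction"); efficiency /
depth effects by subsampling every sample without replacement (multivariate
hypergeometric) to the common depth. In the acceptance scenario the taxon
pool is large (1000) so the log-normal rare tail is deep enough for
detection floors to shape the SAD — the regime in which down-sampling
visibly reduces divergence.

**Closed-reference collapse.** Counts of taxa mapping to one reference id
are summed; unmapped taxa are dropped; the discarded fraction is
reads-weighted. The mock reference membership is chosen greedily (taxa in
random order, added to the unmapped set while their expected read share
stays under the target) so a configured read-loss fraction is hit to within
the smallest taxon weight.

**PERMANOVA.** Sequential (Type-I) sums of squares on the Gower-centered
squared-distance matrix, habitat entered before primer before interaction;
dummy codings are rank-handled by SVD projection. p-values come from free
permutation of sample labels, `p = (b+1)/(n_perm+1)`. Negative sequential SS
can occur for non-Euclidean dissimilarities and is reported as-is; a
saturated fit (zero residual) yields `F = inf` rather than a sign-unstable
ratio. The implementation is cross-checked against R `vegan::adonis2
(by = "terms")` in the test suite.

**Mantel / Procrustes.** Mantel uses Spearman by default with simultaneous
row/column permutation (scikit-bio). Procrustes superimposes metric
principal-coordinate embeddings (k = 2) — chosen over NMDS because it is
deterministic and free of stress-minimization convergence issues — and
PROTEST permutes the row correspondence; `m²` is the normalized residual,
invariant to similarity transforms.

**Beta-diversity partition.** Baselga's decomposition: incidence
(Sørensen = Simpson turnover + nestedness) and its abundance analogue
(Bray–Curtis = balanced variation + gradient). Components are reported per
pair plus multi-site means over pairs.

**βMNTD / βNTI.** Abundance-weighted mean nearest-taxon distance with
patristic distances from a single post-order pass. The null shuffles taxon
labels across all tree tips (regional null, 999 randomizations by default);
βNTI is the z-score per pair. A null with zero spread (e.g. a star tree)
yields a flagged NaN, never ±inf. |βNTI| > 1.96 is read as selection, the
sign separating homogeneous (−) from heterogeneous (+) selection.

**Raup–Crick (RC-bray).** The null preserves each sample's richness and
read total; taxa enter with probability proportional to occupancy, and reads
fill proportional to regional relative abundance (one read guarantees
presence). `RCI = 2 [#(null < obs) + 0.5 #ties]/n_null − 1`, clamped to
[−1, 1]. The null's occupancy/regional statistics default to the table's own
but can be supplied from a larger reference community; the self-calibration
experiment uses this to draw the observed table and the nulls from the same
distribution. RCI > 0.95 is read as dispersal limitation and < −0.95 as
homogenizing dispersal (the standard convention; an `rc_convention` switch
inverts it because the two readings circulate in the literature).

**Process partitioning.** Selection first (|βNTI| vs 1.96), then dispersal
(|RCI| vs 0.95), else undominated; a NaN βNTI maps to "undetermined".
Fractions per group sum to 1 exactly (the largest fraction absorbs the
float-division residual).

**NST.** For each within-group pair, observed dissimilarity `D` is compared
with its expectation `E` under the proportional-proportional null:
`NST_pair = D/E` if `D < E`, else `(1−D)/(1−E)`, clamped to [0, 1]. A pair
at its null expectation scores 1 (pure stochasticity), a pair at either
deterministic extreme scores 0, making 0.5 the halfway boundary; the group
value is the mean over pairs. This is a deliberately simple member of the
normalized-stochasticity family: it keeps the 50% boundary interpretable and
is exactly testable (identical samples → 0, neutral data → above 0.5).
Taxonomic (Bray–Curtis or Jaccard) similarity only; no phylogenetic NST.

**Sloan neutral model.** Occurrence frequency of a taxon with metacommunity
relative abundance `p` is `1 − BetaCDF(d; N m p, N m (1−p))`; `p` is
estimated as mean relative abundance, `N` as mean depth, and `m` by bounded
least squares. The default detection limit is `d = ln(2)/N`: under depth-`N`
multinomial sampling, detection probability `1 − (1−x)^N` crosses ½ at
`x = ln 2 / N`, so this is where the sharp-threshold model matches discrete
read sampling — with the naive `d = 1/N` the estimator overshoots `m` by
roughly 30% on count data, which parameter-recovery runs confirm. Per-taxon
classes (above / below / neutral) come from a Wilson 95% band around the
predicted frequency at the observed number of samples.

**Functional redundancy.** `FR = sum_{i != k} p_i p_k s_ik / sum_{i != k}
p_i p_k` with `s_ik` the Jaccard similarity of the two taxa's function sets:
bounded in [0, 1], equal to 1 when all function sets coincide and 0 when all
pairs are disjoint. A `method="rao"` alternative returns `1 − FD/TD` (Rao
quadratic functional dissimilarity over Simpson diversity). Because
self-pairs are excluded, duplicating a taxon is only approximately neutral
(the perfectly redundant within-pair term is O(p²)).

**Niche metrics.** Levins breadth `B_i = 1/sum_h q_ih²` over resource states
(habitats by default), community-weighted by regional relative abundance
into `Bcom in [1, H]`; Pianka overlap
`O_ik = sum_h q_ih q_kh / sqrt(sum q_ih² sum q_kh²)`, abundance-weighted
over pairs into `Ocom in [0, 1]`.

## Seeds and reproducibility

Every operation that draws random numbers takes a seed; compound procedures
split one root seed into named child streams via `numpy.random.SeedSequence`
so adding a stage never perturbs another (the pipeline gives each stage its
own stream, and stage toggling is byte-stable by test). Reports carry a
SHA-256 hash of the resolved configuration plus the seed.

## Problem sizes

The test suite and the acceptance script run the null-model calibrations at
20–30 samples, 150–500 taxa and 999 randomizations, the type-I-error study
at 1000 data sets with 199 permutations each, and the survey pipeline at 300
taxa × 174 sample pairs; these sizes give stable Monte-Carlo estimates for
every property tested while keeping a full run in the tens of seconds on one
core. Larger surveys only change runtime: βNTI scales with
`n_null × samples × taxa × mean richness`, RC-bray and NST with
`n_null × pairs × taxa`.

## Known limitations

* The NST normalization is a simplified member of its family; absolute
  values are not interchangeable with other published implementations,
  though the 50% reading and orderings are.
* RC-bray saturates toward ±1 whenever biological overdispersion (or any
  variance source absent from the null) dominates, as it does in the default
  survey; process fractions then lean heavily on the dispersal categories.
* The Sloan fit pools samples; fitting strongly habitat-structured data
  pooled across habitats yields low R² by design, not by error.
* Closed-reference "mapping" is identity-based on synthetic taxa; nothing is
  said about sequence-level mapping ambiguity.
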