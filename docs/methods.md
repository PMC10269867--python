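# Methods

This note documents the statistical models, the defaults and why they were
chosen, the synthetic-data generator's assumptions, and the numerical
decisions that a maintainer or careful user should know about.

## Rarefaction and alpha diversity

Rarefaction subsamples each library to a fixed depth *without replacement*
(multivariate hypergeometric draws), so rarefied counts have the
hypergeometric expectation `depth · n_i / N` and every rarefied count is
bounded by its original. Libraries below the depth are excluded rather than
upsampled. The shipping depths are 4,000 reads globally and per-site depths
of 4,030 (blood), 10,961 (buccal), 10,329 (cloaca), 9,094 (intestine) and
22,306 (gizzard); a single rarefaction draw is used per sample (no
averaging over draws), with the draw seeded per pipeline stage.

Shannon uses the natural log; Simpson is reported as Gini-Simpson
`1 - Σ p_i²` (bounded in [0, 1]; the concentration form `Σ p_i²` is
available via `gini=False`). Faith's PD includes the path to the root by
default (`include_root=False` subtracts the root-to-MRCA stem). It is
computed from a branch-incidence matrix (sum of branch lengths with at
least one present descendant), which also handles multifurcating roots such
as star trees. Body-site comparisons use Welch's unequal-variance t test
(the pooled-variance test is available via `equal_var=True`) with the
conventional star annotation at 0.05/0.01/0.001/0.0001 and an optional
Bonferroni column.

## UniFrac, PERMANOVA, dispersion

Both UniFrac variants are computed from one branch-incidence matrix shared
across all sample pairs, which makes all-pairs matrices for hundreds of
samples cheap. Weighted UniFrac defaults to the normalised form so values
are comparable across body sites. A branch length carried by the input
tree's root is ignored (crown convention); with rootless-stem inputs the
implementation agrees with scikit-bio's pairwise functions to 1e-10, and
both variants agree with an explicit edge-set oracle in the tests.

PERMANOVA is the one-way distance-based partition: `SS_T = Σ_{i<j} d²/N`,
`SS_W = Σ_g (Σ_{i<j∈g} d²)/n_g`, pseudo-`F = (SS_B/(a-1))/(SS_W/(N-a))`,
`R² = SS_B/SS_T`. The p-value uses the `(count+1)/(n_perm+1)` estimator
(never zero) with ties counted as exceedances (conservative); default 999
permutations. Each metadata variable is tested on its own, mirroring
one-variable-at-a-time effect-size reporting; multi-factor and stratified
designs are out of scope. The dispersion test embeds the distance matrix by
principal coordinates and uses the corrected squared distance to the group
centroid under negative eigenvalues (real-part contribution minus
imaginary-part contribution, clipped at zero — the betadisper rule), then a
one-way F with a permutation p. Size-one groups are excluded with a
warning; a wholly degenerate matrix returns F = 0, p = 1.

## Phylogenetic covariance, Pagel's lambda, PGLS

The species covariance is `C_ij = depth(MRCA(i,j))`, `C_ii` the root-to-tip
depth. After pruning, path lengths are preserved and a stem edge left above
the new root is shared ancestry, so it is added to every entry. Pagel's
lambda scales the off-diagonal of `C`; the fit maximises the Gaussian
likelihood with mean and σ² profiled analytically by GLS at each λ, and λ
searched on [0, 1] by a coarse grid {0, .25, .5, .75, 1} plus a bounded
scalar search (tolerance 1e-8) in the bracketing interval — the likelihood
can be multimodal on small trees, hence the grid. λ is bounded to [0, 1]
(not the looser matrix-positive-definite maximum). A likelihood flat across
the grid (star-like tree, λ unidentifiable) returns the boundary 0 with a
warning and a `flat` flag. Significance is a likelihood-ratio test against
λ = 0 on one degree of freedom.

**Known property, worth stating plainly:** because λ = 0 is a boundary of
the parameter space, the ML estimate sits exactly at 0 in the large
majority of signal-free replicates and the χ²₁ reference makes the LRT
conservative — its realised size is roughly 0.5–1% at a nominal 5% on
100–200-tip trees. This is a property of the standard method, not of this
implementation: on identical trees and traits the fit reproduces R
phytools' λ̂ and p to four decimals. Interpret non-rejections accordingly.

PGLS uses `V = C` (Brownian residuals) by default; `correlation="lambda_ml"`
instead plugs in `C_λ` at the λ that maximises the regression likelihood.
The reported "value" is the GLS slope, with a t-test on `n - 2` df using the
unbiased residual variance. On a star phylogeny PGLS reduces to OLS exactly.
The ordinary (non-phylogenetic) fit reports Pearson's r with its two-sided
p. Both are run for raw and natural-log species mass; species mass is the
arithmetic mean of sampled individuals' field masses in grams, with an
optional species-level fallback column honoured by the metadata loader
(missing masses are never invented).

Subsets follow the standard design: all species; the largest host order
only; and species with more than two sampled individuals (≥ 3 samples,
counted within the body site under analysis). Bonferroni multiplicity is
the number of testable rows sharing a subset block (site × metric), and the
`m` used is recorded in the report. A diversity vector with zero variance
after species averaging yields an explicit `untestable` row, not NaN.

## Phylosymbiosis

Sample-level UniFrac matrices are averaged to species level (mean of all
between-sample distances per species pair) because congruence is defined
against a species-level host phylogeny; a per-sample mode would conflate
intraspecific variation with topology. Dendrograms come from agglomerative
clustering (default complete linkage — the linkage is not standardised in
this literature, so it is configurable and recorded in every output row;
conclusions on synthetic data are stable across complete and average).
Equal-height merge ties resolve toward the lexicographically smallest
member id (ids are sorted before clustering), making dendrograms
bit-reproducible.

nRF is computed on non-trivial *unrooted* splits even though dendrograms
are rooted: `nRF = |S₁ Δ S₂| / (|S₁| + |S₂|)`, which is `RF/(2(n-3))` for
two binary trees; multifurcating host trees simply contribute fewer splits
and the actual split-count denominator is used. Two trees with no
non-trivial splits (n < 4) have nRF 0 by convention. The permutation test
shuffles tip labels uniformly on the fixed dendrogram topology and reports
`p = #{nRF_perm ≤ nRF_obs}/n_perm` (shuffles at least as congruent), with a
`(count+1)/(n_perm+1)` column for users needing a never-zero estimator.
Because shared splits between a random labelling and a fixed tree are rare,
the null concentrates near nRF = 1 (mean > 0.99 by ~30 tips) and the null
distribution is strongly discrete at small n — the test's realised size is
therefore at or below nominal. The end-to-end runner applies the
more-than-two-individuals subset first, rarefies, and emits an
`insufficient n` row when fewer than five eligible species remain.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
sequences. Host and ASV phylogenies are pure-birth (Yule) trees conditioned
on n tips, extended by the conditional post-split waiting time (so pendant
branches are not degenerate), stem dropped (crown convention), rescaled to
unit depth. Traits are draws from `MVN(μ·1, σ²C_λ)`. Species mass is
log-normal with near-Brownian signal (λ = 1 by default, matching the strong
phylogenetic signal body size shows empirically), mean log-mass 4 (~55 g)
and unit variance on the log scale.

Communities are logistic-normal: per-ASV species effects mix host-tree
Brownian structure and iid noise with a single dial
`g = scale·(s·BM + (1-s)·iid)` on the log-abundance scale — s = 1 gives
fully clade-structured compositions, s = 0 none. Each body site adds
offsets to a random 30% of ASVs (sd 2 on the log scale), producing a real
body-site factor for PERMANOVA. Mass and diversity are linked at the
composition level: each species receives a target Shannon value
`h = h₀ + slope_true·(log m - mean) + λ-BM noise` (h₀ = 60% of ln n_asvs,
noise sd 0.25), realised by tempering its logits — Shannon of
`softmax(logits/T)` is monotone in T, so T is solved by bisection. Library
sizes are log-normal with median 20,000 reads and log-sd 1, which leaves a
realistic minority of libraries below the 4,000-read exclusion threshold so
that code path is always exercised. Per-individual masses jitter around the
species mass (log-sd 0.1); taxonomy labels assign the larger root clade to
the dominant order and group genera/families along the species list.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: sequencing error and chimeras,
contamination, overdispersion beyond multinomial sampling, correlated ASV
dynamics within a sample, ecological covariate effects (diet, nest, sex are
generated null), and host trees with topological uncertainty. Defaults
(40 species × 3 individuals × 4 sites, 300 ASVs) describe a modest survey;
the analysis scripts use 60 species × 3 sites and the statistical
validation suite uses 8–200-tip trees and 16-species community simulations,
sizes at which every check runs comfortably on one core.

## Pipeline

`pipeline.run_all` executes alpha → beta → comparative → phylosymbiosis,
writing one TSV per stage with a provenance header (config hash over the
analysis parameters, run seed, per-stage seed). Stage seeds are
`seed + crc32(stage name) mod 2³¹`, giving independent, logged streams; no
timestamps are written, so identical configs and seeds produce byte-
identical reports. A stage whose output exists is skipped, so deleting one
report and re-running recomputes only that stage. Liver and spleen samples
are accepted by the loaders but excluded from the comparative and
phylosymbiosis stages by default (sample sizes for those sites are
typically too low for species-level analysis).

## Limitations

Single-factor PERMANOVA only; no NMDS/ordination plotting; no Chao1/ACE or
coverage-based rarefaction; no Blomberg's K or Ornstein-Uhlenbeck models;
no differential-abundance layer; congruence is scored by nRF only (no
matching-cluster or triplet scores, no Mantel test). The λ-LRT conservatism
described above applies to any downstream use of the lambda p-values.
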