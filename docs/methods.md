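# Methods

## Study design emulated by the generator

The synthetic module reproduces the structure of a pooled two-color
array study of social stress: four regimes — acute, 8 days, 13 days,
and 13 days followed by 5 days of recovery — each with three
independent RNA pools hybridized against sibling-control pools, and
every hybridization repeated with the dyes swapped (24 array
comparisons). The generator's defaults are the package's study
conditions; all are configurable through `SimulationConfig`.

The fold-change model is

    value(g, s) = profile(cluster(g), group(s))
                + loading(g) · (f_s − mean f)
                + ε,   ε ~ N(0, noise_sd²),

where `f_s ∈ [0, 1]` is the tissue-contamination fraction of
biological sample `s`. A dye-swap copy shares its sample's biological
value and differs only by fresh technical noise — the two technical
replicates of one hybridization measure the same RNA pools.
Contamination is additive on the log2 scale; this keeps the planted
correlation structure linear and recoverable, which is the property
the screen exploits, without committing to a particular
mixing-on-the-intensity-scale model.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| genes | 500 (3 stress clusters × 30, 12 markers, 398 background) | enough background for meaningful FDR control while keeping hundreds of seeded runs cheap |
| noise_sd | 0.1 log2 units | typical replicate scatter for pooled two-color arrays |
| profile amplitude | 1.3 | peak per-group \|logFC\| ≈ 0.9, comfortably above the 0.5 call threshold |
| marker loading | 3.5 log2 per unit fraction | plexus transcripts are orders of magnitude enriched; a few % fraction change moves logFC by ~0.1 |
| contamination law | group means 0.09–0.51, per-pool sd 0.03 | dissection batches (≈ groups) share contamination luck, so markers become differential in some regimes while individual-animal contamination stays treatment-independent |
| animals | 9 per group; thymus 0.22 − 0.04·z %, spleen 0.40 + 0.06·z % bw | organ-weight ranges and signs of the chronic-stress response |

**Profile geometry.** Cluster separation under *absolute* centered
correlation requires profile directions whose pairwise |cos| clears
the 0.55 cut; anti-parallel directions do not count as separate. In
the 3-dimensional centered space of four groups, at most four lines
can be pairwise near-orthogonal; the defaults use four lines of the
icosahedral frame (pairwise |cos| = 1/√5 ≈ 0.447): three for stress
clusters and the fourth for the group-mean pattern of the
contamination fractions. With noise_sd = 0.1 the within-cluster
correlation is ≈ 0.97 and the between-cluster correlation ≈ 0.44, so
the r > 0.55 cut separates planted clusters with a wide margin
(profile separation ≈ 9 × noise_sd, well beyond the 4× regime where
recovery is tested).

**Two contamination regimes, deliberately different.** On arrays the
fractions carry group-level mean structure, because pools are
dissected and processed in batches; this is what makes marker genes
*differentially expressed* (and hence clustered) in some regimes. The
per-animal fractions of the validation branch are drawn iid across
groups: an individual animal's dissection spillover has no reason to
track its treatment. This is exactly the dissociation the screen
tests — markers move on arrays yet stay uncorrelated with the
organ-weight stress indices across individuals.

### What the generator does not emulate

Raw two-color spot intensities (spatial artifacts, dye bias beyond
what the swap averages out), RNA-pooling variance beyond `noise_sd`,
probe-level effects (one probe per gene by default), atlas-image
registration error, and qPCR inhibitors/pipetting failures beyond
Gaussian Ct noise. Passing recovery tests therefore shows the
*inference chain* is sound under the stated noise model, not that real
dissections behave this benignly; on real data the screen's verdicts
should be read as evidence, not proof.

## Differential expression

Each array comparison already contrasts a stressed pool with its
sibling control, so the per-group test is a one-sample (paired)
two-sided test of replicate logFCs against zero. Dye-swap pairs are
averaged first (they are technical replicates); the per-group
replicate count is then 3. Moderation shrinks per-gene variances
toward a prior, s̃² = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀²) fitted
by method of moments on log s² via the digamma/trigamma identities of
the scaled-F model; the test df becomes d + d₀. With d₀ = 0 the
moderated test reduces exactly to the plain t. Significance is the
joint rule |logFC| > 0.5 **and** BH-adjusted p < 0.05, both strict —
a gene at exactly 0.5 is not called, whatever its p.

Time-course contrasts are pooled-variance two-sample comparisons of
replicate logFCs, earlier period minus later, with the same joint
rule; BH runs within each contrast family separately (per group, per
period pair), matching per-contrast reporting.

The raw-intensity path: normexp fits observed (foreground −
background) as N(µ, σ²) background plus Exp(α) signal by maximum
likelihood per array/channel (Nelder–Mead on (µ, log σ, log α);
degenerate inputs fall back to subtract-and-floor with a warning) and
replaces intensities by the posterior mean of the signal, which is
strictly positive and monotone. Loess (locally linear, span 0.3,
3 robustness iterations, via statsmodels lowess) removes the M-on-A
trend within arrays; Aquantile quantile-normalizes A-values across
arrays, leaving M untouched. Genes with fewer than 2 finite
replicates in a group are reported untested rather than silently
dropped; a zero-variance zero-mean gene gets p = 1 by convention.

## Clustering

Similarity is |Pearson r| of mean-centered profiles, so anti-correlated
patterns (e.g. up-in-stress vs down-in-stress mirror images) land
together — intended, since a contamination fraction can push marker
fold changes in either direction. Constant profiles have no defined
correlation; they are excluded and reported. Agglomeration is true
UPGMA on d = 1 − |r|: the inter-cluster distance is the arithmetic
mean over all cross-pairs of original items (size-weighted
Lance–Williams update), not the unweighted WPGMA variant. Ties break
deterministically on the smallest (row, column) position in creation
order, for bit-identical results across platforms. Average linkage is
reducible, so merge heights are monotone and threshold cuts are
well-defined: clusters are maximal subtrees with all internal merges
r > 0.55 (strict; singletons allowed), subclusters maximal subtrees
with merges r ≥ 0.75 (inclusive) and ≥ 2 genes. Labels: clusters
numbered by descending size (ties: alphabetically first member),
subclusters lettered the same way. Clustering defaults to the
per-technical-replicate matrix (24 columns); the swap-averaged matrix
can be used instead.

## Atlas scoring

The score of a region is w_b·mean(B) + w_g·mean(G) + w_r·mean(R) over
the ROI with weights (1, 2, 3). Channel means are taken directly on
the RGB planes — black (zero-expression) pixels dilute the means by
design — rather than first classifying pixels into discrete color
classes; the two agree on the synthetic masks and the direct mean is
what "mean intensity per channel" denotes. ROIs are boolean masks or
polygons in 0-based row/col coordinates with boundary pixels included.
Multiple slices of one gene are averaged per region; genes without
imagery are "unavailable" and never flagged. Enrichment is a strict
ratio test (max adjacent score > margin × target score, margin 1.0 by
default, so "anything higher than the hippocampus is suspicious");
the margin is configurable because "enriched" is inherently
qualitative. Cluster screening takes the 4 most central genes
(highest mean absolute centered correlation to the other members —
a deterministic medoid-like rule, ties alphabetical), and escalates
to per-gene screening when ≥ 3 of 4 are flagged (majority rule;
both k and the trigger are configurable).

## Contamination verdicts

Spearman rho is the Pearson correlation of average ranks; p-values
are exact permutation probabilities for n ≤ 10 and the t
approximation with n − 2 df above (the pooled screen runs at ~36
animals, squarely in the approximation regime; the exact route keeps
toy examples honest). The screen pools animals across stress groups
and calls a gene stress-correlated only with the physiological sign
pattern — thymus-negative or spleen-positive — at two-sided
alpha = 0.05; raw rho/p for both organs are always reported, including
significant wrong-sign correlations. No multiple-testing correction is
applied to the screen (raw per-gene correlations are reported as
evidence, not as discoveries). Panel overlap uses the hypergeometric
upper tail against the full simulated gene universe. The verdict rule
is an explicit conjunction: contamination-consistent = (suspect
cluster OR panel member) AND uncorrelated; stress-responsive =
differential AND clean AND panel-free AND stress-correlated; anything
else indeterminate. The report serializes with canonical key order, so
identical seeds yield byte-identical JSON.

## qPCR statistics

Efficiency comes from the dilution-series regression Ct ~ log10
(relative input): E = 10^(−1/slope), accepted in (1, 2.5], flagged
below R² = 0.98. ΔCt is oriented control − sample so that R > 1 means
higher expression in the stressed animal. Triplicate wells collapse by
mean Ct after dropping wells more than 1 cycle from the replicate
median (logged). The Wilcoxon signed-rank test drops zero differences,
mid-ranks ties, and computes the two-sided p exactly by enumerating
all 2ⁿ sign assignments for n ≤ 12 (p = 2 × min tail, capped at 1;
all-zero input is degenerate with p = 1); larger n uses the normal
approximation with continuity and tie corrections. Lilliefors p-values
are Monte-Carlo (10⁴ seeded standard-normal samples of matching size)
rather than table interpolation; Levene uses the classic mean-centered
statistic with the F reference. The reference-gene ranking is a plain
variance decomposition, sqrt(intra-group variance + variance of group
means) on the Ct scale — deliberately simple and *not* equivalent to
model-based stability estimators; it is a surrogate that orders
obviously unstable candidates correctly.

## Numerical conventions

Strict inequalities at both differential-expression thresholds;
deterministic tie-breaks everywhere (UPGMA by position, labels and
representatives alphabetical); BH implemented as the step-up minimum
with mergesort ranks (stable under ties); p-values clipped to [0, 1];
corrected intensities floored at the smallest positive float; all
randomness flows from explicit integer seeds through
`numpy.random.default_rng`, with fixed child-seed derivation per
generator so stages can be re-run independently.

## Problem sizes used in checks

The test suite and the acceptance script measure recovery at the
default study conditions (500 genes, 24 comparisons) over 50–100
seeds, null calibration at 2000 genes, oracle equivalence on hundreds
of random instances (n ≤ 12 for the UPGMA and Wilcoxon enumerations,
vectors ≤ 50 for BH), and qPCR recovery over 50 plates of 9 pairs —
sizes chosen to exercise every code path at the scale of the emulated
study design.

## Known limitations

- The paired test on logFCs is a contract-level stand-in for a
  separate-channel GLS with intra-spot correlation; it estimates the
  same contrast but not with identical efficiency, so exact numerical
  parity with channel-level mixed-model analyses is out of scope.
- The contamination screen classifies; it does not estimate a
  contamination fraction per sample or correct expression values
  (no deconvolution).
- Atlas scoring assumes registered, color-coded masks with known ROIs;
  no segmentation or registration is attempted.
- With only 3 replicates per group, unmoderated per-gene tests have
  df = 2 and little power; the moderated path is the default for a
  reason, and its calibration holds under the hierarchical variance
  model rather than for arbitrary variance configurations.
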