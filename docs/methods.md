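# Methods

This note documents the statistical procedures, the synthetic-data
model behind the test suite, the numerical conventions, and the design
choices that were genuinely open.

## Differential methylation

**Model and test.** A beta value β ∈ [0, 1] is the methylation fraction
of one CpG in one sample. Testing happens on M-values,
M = log2((β + ε)/(1 − β + ε)) with offset ε = 0.01: near the 0/1
boundaries the beta scale compresses variance and t-statistics misbehave
there, while the logit scale is approximately variance-stable. With a
two-group design of three treated vs three control replicates and no
further covariates, the per-CpG test is Welch's unequal-variance t-test
(a mixed model adds nothing without additional structure). Effects are
reported back on the beta scale as Δβ = β̄ₜ − β̄꜀.

**Significance rule.** Raw p ≤ α AND Benjamini–Hochberg FDR ≤ α, default
α = 0.05. Since the BH-adjusted p-value *is* the FDR estimate, the FDR
condition is the binding one; the raw-p condition is kept in the emitted
contract (both fields are reported per record) so that the emitted set
is always a subset of the raw-p ≤ α set. A CpG with zero variance in
both arms and equal means gets p = 1 and is never emitted; zero variance
with unequal means is the infinite-t degeneracy and gets p = 0.

**Count-based calling.** For methylated/coverage matrices, reads are
pooled within each arm per CpG (three replicates of the same culture;
pooling maximizes per-site information at the cost of replicate-level
dispersion, acceptable for the specified two-proportion screen). The
pooled fractions are compared with a two-proportion z-test; whenever a
cell of the pooled 2×2 table is zero, the Haldane +0.5 correction is
applied to both arms. CpGs with pooled coverage below `min_coverage`
(default 10) in either arm are excluded and tallied, never silently
dropped.

**DMRs.** CpGs are clustered by single-linkage on the 1-D genomic
coordinate: adjacent tested CpGs join a cluster while their gap is
≤ `max_gap` (default 1000 bp). This is a declared interpretation — the
clustering space and cutoff were open design points; genomic-coordinate
distance is the only choice that makes "cluster" mean "region".
Member p-values are combined by unweighted Stouffer (symmetric in the
members, unlike Fisher which is dominated by its smallest p); clusters
pass with combined p ≤ α and ≥ `min_cpgs` (default 2) members. Input
must arrive sorted; unsorted input raises rather than silently
reordering, because a silent sort can mask an upstream coordinate bug.

## Differential expression

**Normalization.** TMM: for each sample against a reference (the sample
whose upper-quartile count fraction is closest to the mean), gene-wise
M = log2 ratio of count fractions and A = average log abundance are
computed over genes expressed in both; the upper and lower 30% of M and
5% of A are trimmed by rank; the surviving M are averaged with inverse
delta-method-binomial weights; factors are rescaled to geometric mean 1
(to 1e-12). CPM = count × 1e6 / (library × factor).

**Test.** Genes pass an expression floor (CPM ≥ 1 in ≥ 2 samples,
configurable; a standard practice filter, declared here since the
upstream protocol states none). Per gene, a Wald test on the log2 fold
change of normalized group means under a negative-binomial model:
Var(count) = μ + φμ². The tagwise φ is estimated by method of moments
per arm and shrunk toward the common (median) dispersion with prior
weight `prior_df` = 20 against the residual df. The Wald statistic is
referenced against t with df = residual + prior df — the moderated-df
convention that accounts for the information the shrinkage borrows
across genes. Pure residual df (= 4 here) is far too conservative for a
3 vs 3 design (it misses planted |LFC| = 2 effects outright); a normal
reference is anti-conservative. Under the moderated df, measured on
simulated data: 0/20 null datasets emit any gene, planted sensitivity
≈ 0.99 at |LFC| = 2 and φ = 0.05, empirical FDR ≈ 0.02 at the nominal
0.05. A pseudo-CPM of 0.5 keeps zero-mean arms finite. The same dual
p/FDR ≤ α rule applies; up + down = total by construction.

This caller is a specified procedure, not a port of any published
package; its validation is planted-truth recovery, not coefficient
equality with another implementation.

## ERE motif context

Consensus scanning with IUPAC codes on both strands; an 'N' base in the
*genome* matches no code (an 'N' in the motif matches any real base).
Default motifs: half-site AGGTCA (whose reverse complement TGACCT is the
second half-site orientation — a genomic occurrence of one is a
minus-strand occurrence of the other) and the full palindrome
GGTCANNNTGACC; zero mismatches by default, configurable. Containment of
a hit in an annotation class is decided by its midpoint (unambiguous for
census counting); classes overlap, so the census is not a partition.
Density is hits per kb of class span (union of intervals).

Proximity: half-site hits with midpoint inside the closed window
[pos − w, pos + w] (w = 500 bp) are counted per site; density per kb of
total window span; the background statistic re-draws equal-size CpG sets
from the assayed CpG universe, because DMCs can only occur at assayed
CpGs — random genomic positions would be the wrong null. Windows are
treated independently (no deduplication of overlapping windows). The
site-vs-background contrast is summarized as a density ratio plus a
Mann–Whitney test on per-site counts. "Density" normalization was an
open point; hits/kb with matched-CpG background is the declared choice.

Per-site annotation uses a total precedence order (default
tss > promoter > tfbs > cpg_island > enhancer > gene_body > repeat >
intergenic); tallies sum exactly to the number of sites. Enrichment per
class is the hypergeometric upper tail P(X ≥ k) with
fold = (k/n)/(K/N), BH-adjusted across classes.

## Integration

Inherent cell-type differential methylation: one-way ANOVA on control
M-values across cell types, BH, FDR ≤ α. The exposure/inherent
partition is exact set arithmetic. Promoters default to TSS ± 1 kb in
generated gene models (no standard definition exists; configurable).
Distance from a site s to an interval [a, b): 0 if a ≤ s < b, else
min(a − s, s − (b − 1)) — the nearest *covered base*, declared
explicitly so half-open boundary arithmetic is forced (site 2500 against
promoter [1000, 2000) is 501 bp away). The proximity/DEG-load
association across cell types uses Spearman rank correlation: with four
points only the monotone claim is defensible, and ranks need no
distributional assumptions. Constant inputs return a null correlation
rather than NaN.

## Persistence accounting

Conserved features are exact-coordinate (DMC) or gene-id (DEG)
intersections; array and sequencing CpGs share the reference coordinate
system, so exact matching is the default and a windowed mode (off by
default) exists for coordinate-fuzzy inputs. corrected = parent −
conserved and de_novo = derived − conserved hold exactly by
construction. Percentages are rounded half-up to one decimal — the
convention used when such rates are reported — and recomputing from the
emitted counts reproduces the emitted percentage.

Multi-generation propagation iterates the retention/de-novo step: each
feature survives a generation with probability r, and
round(d × available) new features arise from the universe U. The
expected burden follows B' = rB + d(U − B) with fixed point
B* = dU/(1 − r + d), which the test suite checks against a long
Monte-Carlo run.

## The synthetic-data generator

**What it emulates.** A small genome (default 5 chromosomes × 2 Mb)
with regularly spaced gene slots: promoter (TSS ± 1 kb), gene body (5 kb
downstream of the TSS), a CpG island inside the promoter, two 1-kb
enhancers and an 800-bp repeat per slot. ERE half-sites are planted at
0.5/kb in promoters and at `ere_enhancer_density_ratio` (default 4)
times that per-bp density in enhancers, plus a light 0.25/kb background
in gene bodies (outside promoters) and repeats. Chance occurrences of
the 6-mer in random sequence (~1/kb — enough to drown the planted
signal) are scrubbed by single-base mutation, so planted density is true
density and a zero-mismatch scan recovers exactly the planted list. An
assayed CpG panel (default 20,000 sites) is placed uniformly; every
panel coordinate hosts a real 'CG'.

**Methylomes.** Each cell type's per-CpG mean is cell-type-private
(profile baseline + N(0, 1.5) logit deviation) at the inherent fraction
of CpGs (default 80%) and shared across cell types (anchor 0.6 + shared
deviation) at the rest — this is what makes "inherent cell-type
differential methylation" a recoverable planted quantity. Replicates
add N(0, `noise_sd`) on the logit scale (default 0.05) and
back-transform, so betas stay strictly inside (0, 1) and downstream
M-values are exactly normal. Planted exposure DMCs shift the treated
mean by Δβ = 0.4 with exact direction counts
(round(hypo_fraction × n)); hypo is assigned to the most-methylated
planted sites (hypomethylation needs methylation to lose, mirroring the
direction definitions), and control means are re-anchored into
[0.02 + Δβ, 0.98] where needed so the planted effect is always full
size. Site placement combines three biases: steering toward the
profile's annotation track (probability 0.7), steering toward
ERE-proximal CpGs for ER-positive profiles (probability 0.7; a
receptor-null profile is neutral, not ERE-avoiding), and an exact
two-sided split between inherently variable and invariant CpGs
(default 0.96 somatic/pluripotent, 0.89 germ).

**Default cell profiles.** Four profiles mirror the study's cell types:
two ER-positive somatic profiles and one ERβ-only pluripotent profile
(hypo-dominant, enhancer-biased) and one receptor-null germ profile
(hyper-dominant, promoter-biased, lowest baseline methylation 0.30 —
the germline ground state). Planted totals scale the full-scale
per-cell-type totals to the panel (at the defaults: 700 / 712 / 939 /
478 DMCs and 1 / 1 / 41 / 76 DEGs) with the exact published hypo and
up fractions.

**Expression.** Gene counts are negative binomial (lognormal base
means, dispersion 0.05) with per-sample library factors in [0.7, 1.3];
planted DEGs get |log2 FC| = 2 with exact up/down counts, and 60% of
them are drawn from genes whose promoter hosts a planted DMC — the
promoter-methylation/expression coupling the integration layer then
recovers.

**Reprogramming.** A derived truth set keeps each parent DMC with
probability `reprogram_retention` (default 0.037) and draws
round(`reprogram_de_novo` × available) new sites from non-parent CpGs
(default rate 0.035); DEGs transition analogously at 0.084 / 0.047.
The defaults reproduce the observed conservation percentages in
expectation while the absolute burden scales with the panel.

**Dose.** The dose multiplier saturates as 3d/(2 + d) (1 at the
reference dose, plateau 3×). The plateau form was an open modeling
choice — no quantitative dose-response curve was available to fit — so
it is qualitative only.

**What the generator does not emulate,** and hence what passing tests do
not show about real data: probe-level array artifacts (no detection
p-values, cross-hybridization or batch structure), read-level sequencing
(no FASTQ, alignment or duplication), biological sequence realism beyond
planted CG/motif content, LD-like spatial correlation of methylation
between neighboring CpGs (DMR tests exercise the clustering logic, not
realistic regional autocorrelation), and any pharmacokinetics behind the
dose multiplier.

## Problem sizes

Tests run on 2 × 400 kb genomes with 3,000 CpGs and 60 genes (seconds);
the multi-seed suites (null FDR control, ER-status contrast, Spearman
recovery) use 10–20 seeds at that scale. `scripts/acceptance.py` uses
8,000–24,000-CpG panels depending on the statistic's variance needs —
e.g. the reprogramming conservation percentage uses a 10,000-site parent
set so its binomial standard error (≈0.19 points) resolves 3.7%. The
full default pipeline (20,000 CpGs, 800 genes, four cell types) runs in
well under a minute on one CPU.

## Known limitations

- The count-based DMC caller pools replicates; between-replicate
  overdispersion inflates its false-positive rate on data with real
  biological replicate variance. It is a specified screen, not a
  replacement for a dispersion-aware caller.
- The moment/Wald DEG test is calibrated for the simulated regime
  (moderate dispersion, 3 vs 3); severely overdispersed or
  zero-inflated data would need a likelihood-based caller.
- Fractions reported by the DEG-with-DMC counter use caller-supplied
  denominators; published percentage denominators for such tables are
  often ambiguous and are not guessed here.
- Exact-coordinate persistence matching assumes both feature sets live
  on the same reference; cross-assembly comparisons need the windowed
  mode plus lift-over upstream.
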