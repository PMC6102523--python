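# Methods

This note documents the models implemented in `burpfam`, the defaults and
their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Family identification

The BURP domain is matched as the literal pattern
`C H X{10} C H X{23,27} C H X{23,26} C H X{8} W` with anchors required
verbatim (an `X` in the protein does not satisfy a C/H/W anchor, since the
anchors define the domain). Matching is leftmost with minimal spacers; when
the full pattern is absent, a prefix of at least two CH dyads is annotated
as an incomplete domain (excluded from the curated catalog). The two extra
conserved cysteines seen in most members are annotated when present inside
the matched span but are not required for completeness, because the
defining pattern comprises only the CH repeats and the terminal tryptophan.

Curation order: longest isoform per locus (ties broken by lexicographically
smaller id, deterministic and logged) → complete-ORF screen (multiple of 3,
ATG start, single terminal stop; codons containing N are treated as
non-stop and flagged) → domain screen.

## Phylogeny

Protein distances use pairwise deletion — the family's long, variable
N-terminal regions would discard most columns under complete deletion — with
Poisson correction −ln(1−p) by default and raw p-distance switchable. A
pair whose correction saturates (no shared identical residues) is capped
just below saturation and flagged. Neighbor joining is the Saitou–Nei
algorithm; negative branch length estimates are clamped to zero with a log
entry. Bootstrap resamples alignment columns with replacement; support is
the integer percentage of replicates containing each bipartition
(label-set encoding, so it is invariant to row order and rooting).

Subfamily assignment reads clades off the tree using user-supplied seed
members per label: each leaf takes the label of the smallest non-root clade
containing it and at least one seed (majority of seeds in that clade; ties
lexicographic). Because NJ trees are arbitrarily rooted, the tree is
midpoint-rooted first whenever branch lengths are available; otherwise the
given rooting is used as-is. Seeds are configuration, not inference: where
subfamily boundaries depend on information outside the tree (e.g. motif
architecture), the caller encodes that knowledge in the seed lists.

## Codon alignment and pairwise distances

Back-translation threads each CDS through its aligned protein row (one
residue → one codon, one gap → `---`), trimming a trailing stop codon and
refusing any translation mismatch with the row.

Ks/Ka follow Nei–Gojobori (1986): per-position synonymous site fractions
averaged over both sequences; multi-hit codons averaged over all
substitution pathways with equal weights, excluding pathways through stop
codons (if every pathway is blocked, all pathways are scored with
stop-involving steps as nonsynonymous); Jukes–Cantor correction
d = −(3/4)ln(1 − 4p/3), with saturation flagged when the argument is
non-positive. This estimator was chosen because it is fully specified,
fast, and exactly checkable against pathway enumeration; no claim of
superiority over ML pairwise estimators is made, and the estimator identity
matters more for reproducibility than its efficiency here.

Stop handling deserves a note. By default, columns containing an in-frame
stop are excluded (alignment or annotation artifacts in real data), while
mutations *to* stop codons still count as nonsynonymous site opportunity,
keeping S+N = 3 × codons. These two conventions jointly make the neutral
expectation of Ka/Ks slightly below 1 (≈0.95) on data generated by a
stop-free codon process, because nonsense opportunity is counted but never
realized. The `keep_stop_columns` option retains and scores stop-containing
columns (stops behave as a 21st amino acid); in that regime the neutral
Ka/Ks expectation is 1, which is how the estimator-consistency test is run.

4DTv is the raw proportion of transversions at third positions of columns
whose first two bases are identical in both codons and define a
fourfold-degenerate family — by construction in [0, 1], with 0/0 flagged as
undefined. An HKY-style corrected variant −(1/2)ln(1−2v) is available
behind a flag (off by default) because corrected values can exceed the raw
proportion's range; published 4DTv values above 1 are only representable as
corrected distances, and this package does not attempt to reverse-engineer
which correction produced any particular printed value.

## Duplication classification and dating

Tandem: all same-chromosome family pairs with at most 10 annotated genes
strictly between them in start-coordinate order (boundary inclusive;
intervening family members count as intervening genes — the rule is about
physical adjacency, not family membership; gene order is by start
coordinate, strand ignored). Segmental: collinearity anchor blocks are
consumed as files; per block, anchors with Ks > 1.0 are discarded
(saturation guard), blocks with fewer than 3 surviving anchors are dropped,
and each family pair in a surviving block carries the block's mean ± SD Ks.
Ages are T = Ks/(2λ) with λ per species (defaults ship for
soybean 6.1×10⁻⁹, Brassica 1.4×10⁻⁸, Arabidopsis 1.5×10⁻⁸
substitutions/site/year); printed ages are rounded half-up to one decimal
Mya, with the raw value also emitted.

## Codon site models

The GY94 generator has entries π_j·{1, κ, ω, ωκ} for single-nucleotide
{synonymous transversion, synonymous transition, nonsynonymous
transversion, nonsynonymous transition} changes, zero otherwise, with F3x4
codon frequencies by default (uniform available for tests). Likelihoods use
Felsenstein pruning with alignment-pattern compression and per-node
rescaling; gap/ambiguous codons are missing data (flat partials).

Site-class mixtures share one time scale: every class generator is divided
by the mixture-average flux, so branch lengths are expected substitutions
per codon averaged over classes and a class with larger ω evolves
genuinely faster. This matches the CODEML convention and is essential for
power — normalizing each class separately would reduce ω classes to
composition differences.

Models: M0 (single ω, branch lengths optimized jointly); M3 with K=3 free
(p_k, ω_k) classes; M7 with ω ~ Beta(p, q) discretized into K=10
equal-probability classes represented by their means; M8 = M7 plus an
extra class with ω ≥ 1; branch-site model A (classes ω0, 1, 2a, 2b; the
null pins ω2 = 1; foreground = all branches whose subtree lies inside the
designated clade, stem included). Branch lengths are optimized once under
M0 and then held fixed for M3/M7/M8/branch-site — a deliberate deviation
from CODEML's per-model optimization that keeps desk-scale runtime while
changing log-likelihoods far less than the model differences under test.
Optimization is L-BFGS-B on log/logit-transformed parameters with bounds
(κ ∈ [0.05, 50], ω ∈ [10⁻⁵, 30], beta parameters ∈ [0.05, 50]) and up to 3
random restarts with fixed seeds (fewer in bulk calibration loops). LRTs
use χ² with df 4 (M3 vs M0), 2 (M8 vs M7) and 1 (branch-site, with the
halved 50:50 boundary mixture available); a negative statistic is reported
as computed and flagged.

Positively selected sites: NEB takes the class posterior at the MLEs; BEB
(M8) averages the NEB posterior over a uniform coarse grid (8
points/parameter) on (p0, p, q, ω_s), weighting grid points by their
marginal likelihood. Site likelihoods as a function of ω are precomputed on
a fixed knot grid and linearly interpolated, and the mixture's time scale
is held at its MLE value across the grid — a coarse-grid approximation
consistent with holding branch lengths and κ fixed. Calls are emitted at
the 0.95 and 0.99 posterior tiers, with alignment-column and
reference-sequence coordinates.

## Functional divergence

Type I (rate shifts): per-site substitution counts within each cluster are
Fitch parsimony minima (unweighted; gaps/X are missing and constrain
nothing; all-gap columns are excluded). The two-cluster model is a
mixture: with probability 1−θ a site's rate is a single gamma(α, α) draw
shared by both clusters (giving a bivariate negative-binomial joint for
the counts), with probability θ the two clusters draw independent rates.
θ, α and the cluster depths are estimated by L-BFGS-B maximum likelihood;
the gamma shape is shared across clusters under both states (one fewer
parameter, and the data rarely support separate shapes). SE comes from the
numerical Hessian via the delta method; the LRT against θ=0 uses χ²₁; Qk
is the posterior of the independent-rate state.

Type II (radical property shifts): among columns conserved within both
clusters (majority residue frequency ≥ 0.8, configurable) and differing
between the cluster consensuses, the observed fraction of radical
differences — crossing the property partition {positive, negative, polar,
hydrophobic, special (C, G, P)}, configurable — is compared with a fixed
genetic-code baseline: the radical fraction among all single-nucleotide-
step sense-codon replacements (0.704 under the default partition).
θ_II = (r_obs − r_exp)/(1 − r_exp) is a moment estimator, deliberately not
clamped, so sampling fluctuation below the baseline yields negative values
(as published tables of this coefficient sometimes show); the SE is
binomial. Qk for radical sites comes from the implied two-component
mixture (divergent component emits radical with probability 1, null with
probability r_exp). The baseline is composition-independent by design:
estimating it from the clusters' own composition is circular exactly when
divergence is strong.

## Promoters

The window is the 1500 bp immediately upstream of the translation start
(the analysis anchors at the coding region, not the transcription start,
because gene models' ATG is annotated far more reliably than TSSs), taken
strand-aware and truncated with a flag at chromosome edges. Elements are
IUPAC consensus strings supplied as configuration; the shipped starter
table covers the standard hormone/stress element names with literature
consensus patterns and is explicitly non-canonical — database matrices are
data, not method. Scanning reports every occurrence on both strands,
overlapping matches included, since per-promoter copy numbers are the
summarized quantity; minus-strand hits are reported at the forward-strand
position of their leftmost base. Summaries print per-subfamily totals in
count/members notation plus family-wide mean copies per gene.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume: a
multi-species family with four subfamily clades (deep stems of 0.45
substitutions/codon separating balanced within-clade trees with branches
uniform in [0.03, 0.12]); codon sequences evolved under the same GY94
machinery the selection module fits (default κ=2, ω classes 70% at 0.05
and 30% at 0.4 — a conserved family with a moderately variable minority of
sites); an invariant BURP core (mid-range spacers; ATG start) planted near
the C terminus of every non-decoy member; tandem and segmental duplication
events at configured Ks depths; anchor blocks of 4 with per-anchor scatter
of 10% of the depth (anchors of one block share its age); 1500-bp promoter
windows with planted elements over an i.i.d. 40%-GC background (or an
A/T-only background that makes background matches of GC-containing
patterns impossible, used for exact count checks); and decoys — an
incomplete-domain paralog (terminal W mutated), a redundant shorter
isoform, and a pseudogene with an internal stop.

Duplication depths are specified in Ks units and converted to branch
lengths by inverting the *expected NG86 estimate*: expected pathway-averaged
synonymous differences are computed from the transition matrices and the
parent's codon composition, corrected, and solved for t by Brent's method.
The configured depth is therefore the truth in the estimator's own
currency, and recovery tests measure only sampling noise (≈14% per pair at
depth 0.1 with 1000 codons, shrinking with depth).

Not emulated: indels (the emitted protein alignment is the simulated
sequence matrix — real alignment uncertainty is absent, so tests say
nothing about aligner errors), genome rearrangements beyond the planted
blocks, transposition-mediated duplication, promoter grammar or PWM-level
motif realism, and rate variation beyond the configured ω classes. Passing
tests demonstrate internal consistency of the estimators under their own
model, not robustness to real-data violations of it.

## Problem sizes and validation protocol

Checks on synthetic data use sizes chosen to give the relevant statistic
adequate power while staying desk-scale: M0 recovery at 8 taxa × 500
codons; M7-vs-M8 null calibration over 50 replicates at 5 taxa × 100
codons with one optimizer start per model and branch lengths from each
replicate's M0 fit; empirical-Bayes site recovery at 8 taxa × 300 codons
with 10% of sites at ω=5; θ_I recovery over 20 replicates of 300 sites
drawn from the generative model; the end-to-end family at 24 members plus
duplicates and decoys with 200 codons. The published full-size fits (125
sequences) are out of scope: their printed parameter values depend on the
original tool versions, so validation rests on the oracle identities and
recovery checks instead.

## Known limitations

* NG86 assumes equal mutation rates; with transition bias (κ>1) it is a
  biased Ks estimator, as is well known. The package fixes the estimator
  for reproducibility rather than correcting the bias.
* Branch lengths fixed after M0 slightly misstate per-model lnL relative
  to full per-model optimization.
* The BEB grid is coarse (8 points/parameter) and holds the time scale and
  κ at their MLEs; posteriors near the 0.95 threshold can differ from a
  full-precision implementation.
* Fitch counts are exact for binary trees; multifurcating nodes use the
  single-node Hartigan bound.
* θ_II is a moment estimator with a fixed code-informed baseline, not the
  full model-based estimator; its SE ignores baseline uncertainty.
* The subfamily assignment depends on midpoint rooting when branch lengths
  exist; for star-like trees the midpoint is unstable.
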