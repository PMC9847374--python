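# Methods

## Model and assumptions

The tool treats AuxRE prediction as evidence fusion over a two-element
frame of discernment: H1 — a candidate motif is an auxin-responsive
element; H2 — it is not; Θ = H1 ∪ H2 carries ignorance. Every candidate
is an exact forward-strand match of a canonical core hexamer (default
`TGTCTC`; variants configurable) in an upstream sequence. The working
assumptions are:

- the core is necessary but far from sufficient, so discrimination must
  come from the local sequence context and from set-level enrichment;
- the two evidence channels (discriminant, overrepresentation) are
  treated as distinct bodies of evidence, which Dempster's rule assumes
  to be independent — an approximation, since both observe the same
  sequence;
- upstream coordinates are purely relative: position −1 is the base
  immediately 5′ of whatever anchor the input FASTA was cut at (TSS or
  translation start); the tool preserves the input frame and never
  decides between the two.

Scanning is forward-strand by default because ARF binding-site
annotation conventions report the element on the stated strand;
reverse-complement scanning (`GAGACA`) is an opt-in flag.

## Evidence channels

**Discriminant (a₁, a₂).** Contexts are the 14-mers of 4-bp flanks
around the 6-bp core, one-hot encoded (4 × 14 = 56 indicators; `.`
padding and `N` encode as all-zero columns). A Fisher linear
discriminant is fitted from class sufficient statistics with
maximum-likelihood class covariances pooled by class size, so the fit is
exactly invariant to duplicating the training set. The pooled covariance
is shrunk toward its diagonal by `lda.shrinkage` (default 0.1) and
ridged by 1e−6 so the perfectly-separable limit (zero within-class
variance) yields finite, saturating scores rather than a singular solve.
a₂ = σ(a₁) is the logistic posterior for H1 under equal priors.

**Overrepresentation (b₁, b₂).** A property of the core word over the
analysed promoter set, shared by all its occurrences: observed is the
total overlapping forward-strand count, expected is Σ (L−5)·p(word)
under a background Markov model estimated from the promoters themselves
(order 0 default, order 1 via `background.order`; pseudocount 1 per
count). b₁ uses pseudocount 0.5 in both numerator and denominator to
avoid log 0; b₂ is the normal approximation to the binomial z-score.
Order-0 is the minimal defensible null; it ignores dinucleotide
composition, which order 1 partially recovers.

## Learning graphs and masses

Three graphs pair the features — defaults G1 = (a₁, b₁), G2 = (a₁, b₂),
G3 = (a₂, b₁), configurable via `graphs.pairs`. Axis edges sit at
empirical quantiles of the training points (`graphs.bins` = 4 cells per
axis; quantile rather than uniform binning so sparse tails do not
produce empty strips; an axis with too few distinct values drops bins
with a logged warning). Each cell's AuxRE fraction is Laplace-smoothed,
(n₊+1)/(n+2), so an empty cell sits at 0.5 — exact ignorance — and no
cell can reach total confidence P4 with fewer than 8 unanimous points.

Fractions map to graded propositions through bands (configurable via
`graphs.thresholds`): f ≥ 0.90 → P4(H1), 0.70–0.90 → P3(H1), 0.55–0.70
→ P2(H1), 0.45–0.55 → P1, mirrored below 0.45 toward H2. The band
thresholds are design choices of this implementation. The proposition
scale puts singleton mass 0 / 0.33 / 0.67 / 1 on the preferred
hypothesis for P1–P4, remainder on Θ, never anything on the
non-preferred singleton — that keeps every region mass normalised and
the preference strictly graded.

## Fuzzification

Each axis carries a trapezoidal partition of unity: a linear ramp of
total width `fuzzy.alpha` × (local bin width) is centred on every
interior edge, where the local width is the smaller adjacent inter-edge
gap — this guarantees neighbouring ramps never overlap for alpha ≤ 0.5,
so memberships sum to exactly 1 everywhere by construction. Outer
shoulders are flat to ±∞, so every query point receives a full unit of
membership and hence a valid mass. alpha = 0.25 by default; alpha = 0
reduces to crisp `(lo, hi]` regions (an edge belongs to the bin below
it). With a single interior edge there is no finite bin width; the ramp
falls back to unit scale. The per-graph mass is the membership-weighted
sum of region masses, which is automatically normalised and continuous
in the query point — the smooth-transition requirement made concrete.

## Fusion and decision

The three graph masses are folded with Dempster's orthogonal sum
(commutative and associative, so the fold order is irrelevant). Total
conflict (1 − K below 1e−9) degrades to the vacuous mass with a warning
instead of raising, so one pathological candidate cannot abort a run.
Decision scores: bel = m(H1), pl = m(H1) + m(Θ), BetP = m(H1) + m(Θ)/2;
the call is AuxRE iff BetP ≥ `decision.threshold` (default 0.5, with the
exact-ignorance boundary resolving to AuxRE — a detector should favour
sensitivity at perfect ignorance).

## Synthetic data: what it emulates, what it does not

`make_fixture_promoters` embeds the published canonical AuxRE sites of
six auxin-induced maize genes (30 coordinates, 15 flanked 14-mers) into
1-kb uniform-random backgrounds that are rejection-resampled until the
scan returns exactly the published hits and nothing else. Only the
default core is excluded from backgrounds; variant-core experiments must
generate their own fixtures. Fixture length is 1000 bp for all six genes
(uniform length beats per-gene minimal lengths; the deepest site at
−969 requires ≥ 973 bp).

`make_training_set` plants a controlled class contrast: positives are
canonical cores with C/T-rich flanks (composition 0.45/0.45/0.05/0.05
C/T/A/G at high separation, 0.27/0.27/0.23/0.23 at low); negatives mix
random non-canonical hexamer cores (70% at high separation, 10% at low)
with TGTC-prefixed decoys. Decoy composition is the separation lever: at
high separation decoys are half canonical-core, half TGTC-prefixed
non-canonical, so the classes are strongly separable while the model
still must learn flank context (every scanned candidate carries a
canonical core, so core identity alone cannot rank candidates); at low
separation all decoys are canonical-core and the flank bias is weak, so
the classes are nearly exchangeable and held-out accuracy sits near
chance. Any design in which negative cores differ systematically from
positive cores is linearly separable regardless of flank bias, which is
why the low-separation regime must reuse the canonical core.

`make_expression_table` draws planted induced genes uniformly on
(3, 10]-fold and the rest on (0.1, 3], never exactly at the threshold,
so strict >3-fold selection recovers the planted set exactly.

What passing tests on these fixtures show: the scanner, coordinate
frame, evidence computation, fuzzification and fusion are each correct,
and the pipeline recovers a planted context signal end-to-end. What they
do not show: performance on real promoters, where background composition
is non-uniform and autocorrelated, AuxRE context preferences are far
weaker and not simply C/T-biased, true labels are scarce, and coupling
modules (Aux/IAA repression, composite elements) matter. The fixture
reproduction validates bookkeeping, not biology.

## Problem sizes and numerical choices

Default analyses in the shipped tests use 6 × 1 kb fixture promoters,
200 + 200 training motifs, 40 planted promoters of 600 bp, and
10,000-pair randomised checks of the combination rule — sizes chosen so
the full suite replays in seconds while every statistical check retains
comfortable margins. Tolerances: mass normalisation 1e−9; Dempster
oracle equivalence and associativity 1e−12; quantile edges follow
numpy's default linear interpolation; ties at a bin edge go to the lower
bin, matching the crisp limit of the fuzzy partition.

## Known limitations

- Dempster's rule with the conflict-normalisation step is known to
  behave counterintuitively under high conflict; the vacuous-mass
  fallback only guards the degenerate limit. Alternative rules (Yager,
  Dubois–Prade) are out of scope.
- Overrepresentation is promoter-set-level: two occurrences of the same
  word in the same run always share (b₁, b₂).
- No PWM or degenerate-pattern scanning; candidates are exact hexamer
  matches only.
- The learning-graph region count is fixed by config, not selected from
  data, and regions are axis-aligned rectangles.
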