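# Methods

## The four-locus model

A full-sib F2 family descends from two F1 parents that are heterozygous at
every marker, in known coupling phase ABCD/abcd over each four-marker
window.  A meiosis in either parent yields one of 16 gametes; complementary
gametes (ABCD and abcd, ABCd and abcD, ...) are produced at equal rates and
are indistinguishable in their crossover content, so the model's parameter
is the 8-vector of gamete-type frequencies g = (g000, ..., g111), indexed by
the crossover indicators of the three intervals (A-B, B-C, C-D).  The vector
lives on the probability simplex; each type splits its mass g_t/2 over its
two complementary haplotypes.

All reported quantities are exact functions of g:

* the six pairwise recombination fractions are four-term sums of g (a
  gamete is recombinant between two markers iff the XOR of the intervening
  interval indicators is 1);
* the coincidence coefficients C1, C2, C3 (interval pairs) and C4 (the
  interval triple) are ratios of observed multi-recombinant mass to the
  product of the involved interval fractions.  C = 1 is the independence
  baseline; C < 1 positive interference; C > 1 negative interference.

Recombination fractions are reported exactly as the sums evaluate — they
are not truncated at 0.5, since repulsion/unlinked configurations can
legitimately push the sums above it and truncation would hide that.

Assumptions: error-free genotype calls, known coupling phase, and meioses
independent across individuals.  No map-distance function (Haldane/Kosambi)
is used anywhere: the analysis never converts between centimorgans and
recombination fractions.

## Estimation

**Testcross windows** (all four markers lm×ll or nn×np): each offspring's
calls, restricted to {2, 1}, decode uniquely to the informative parent's
gamete; type frequencies are counts over the family.  Calls of 0 are
impossible under the testcross and mark an inconsistent individual, which is
dropped with a warning.

**Intercross windows** (all four markers hk×hk): offspring genotypes take
values in {2,1,0}^4 — 81 identifiable classes — and each class probability
is a mixture of products g_s·g_t over the (maternal, paternal) gamete-type
pairs compatible with it, derived once by exhaustively enumerating the
16×16 ordered haplotype pairs.  A single shared g is estimated for both
parents (the symmetric products of the class table assume it; per-parent
vectors are supported by the simulator for asymmetric scenarios but not by
the estimator).  The EM iteration is standard for multinomial mixtures:
the E-step distributes each class count over its components in proportion
to current component probabilities; the M-step sets g_t to the expected
number of type-t gametes (maternal plus paternal) over 2n.  The
log-likelihood is non-decreasing by construction and is recorded per
iteration.

Mixed-segregation windows are skipped, not estimated: no likelihood is
defined here for windows mixing information content, and realistic maps
supply abundant same-type quadruples.

Numerical choices:

* initialisation: uniform (1/8 each), phase-agnostic; any explicit
  gamete-frequency vector (e.g. an independence product of rough interval
  fractions) can be supplied to accelerate convergence;
* convergence: max |Δg| < 1e-8 or 5,000 iterations, both configurable;
* degenerate data: if an observed class ever has model probability below
  1e-300, the estimate is re-initialised once with a seeded Dirichlet blend
  (unreachable from the uniform start, which keeps every class probability
  positive); boundary convergence (some ĝ_t = 0) is reported as-is —
  a zero estimate means complete interference of that crossover pattern and
  is meaningful, not an error;
* a coincidence coefficient with zero denominator is reported as 0 when its
  numerator is zero and as NaN ("undefined", excluded from all summaries,
  with exclusion counts reported) when positive.  The latter cannot occur
  for a valid g — the numerator types are contained in every involved
  interval's recombinant mass — so NaN only guards degenerate inputs.

No standard errors or likelihood-ratio tests are attached to the
coefficients; the scan is descriptive.

## Genome scan

Each linkage group is partitioned into consecutive disjoint four-marker
windows in map order (default; a stride-1 sliding scheme is available), the
trailing remainder of fewer than four markers being dropped.  Each window is
estimated independently and summarised by (r_AB..r_AD, C1..C4, method,
n_used).  A window that cannot be estimated yields a "skipped" record rather
than aborting the scan.  A window's representative position — used for
plots and region assignment — is the midpoint of its outer markers.  The
interference-strength measure exported downstream defaults to C4, the
triple-interval ("high-dimensional") coefficient, selectable to C1/C2/C3.

## Regional analysis

Each linkage group's map span is cut into three equal-length regions NO.1,
NO.2, NO.3 (half-open intervals, terminal point closed).  The difference
between two regions' strength distributions is delta, the L1 distance
between their histograms on shared bin edges: 10 equal-width bins spanning
the pooled values by default.  delta is symmetric, bounded in [0, 2],
zero iff the binned distributions coincide, and satisfies the triangle
inequality.  Because delta depends on the binning, the bin specification is
carried in every report.  An unnormalised variant (raw count differences)
is available behind a flag for the "difference sum" reading; the normalised
statistic is the default.  A region with no defined values makes the
comparison absent (NaN), never zero.

With few windows per region the binned L1 distance is biased upward (two
small samples rarely share bins even when identically distributed), so
genome-wide regional contrasts should pool windows across linkage groups
(`region_values` without `lg`); the per-lg difference ratios are reported
for completeness.

Chromosome summaries use quartiles by linear interpolation between order
statistics (the "type 7" rule — stated because IQR values are
convention-dependent), and the chromosome-level mean strength is regressed
on map length (max minus min marker position) by ordinary least squares,
separately for a caller-specified group of chromosomes and the remainder,
with caller-specified exclusions; slope, intercept and adjusted R² are
reported per group.

## The simulator

`simulate_study` generates a complete study — map TSV, genotype matrix,
truth JSON — emulating a full-sib mapping design: 19 linkage groups with
lengths spaced linearly over 130.26-530.03 cM, 408 offspring, and 40 evenly
spaced markers per group by default (desk-scale; the marker density of a
real RAD map is much higher but adds nothing to window-level validation).
Window segregation types cycle through hk_hk, lm_ll, nn_np so that every
estimation route is exercised.

Interference truth is set *per window*: each disjoint quadruple carries its
own g, specified as interval fractions plus coincidence coefficients and
inverted algebraically (g111 = C4·r_AB·r_BC·r_CD, g110 = C1·r_AB·r_BC −
g111, ...).  Not every (r, C) combination is a probability vector; an
infeasible combination is rejected naming the offending gamete type.  With
unit pairwise coefficients and r = 0.2 per interval the feasible C4 range
is [0, 5] — this algebraic cap, not a modelling preference, bounds the
interference levels used in validation scenarios.  The default truth is
r = (0.2, 0.2, 0.2) — the Haldane-scale fraction for the ~25 cM interval of
the default geometry — with all coefficients 1 (no interference); scenario
configs can make C4 rise linearly with linkage-group length and/or multiply
it in the middle third of each group, which is how region- and
length-dependent interference recovery is validated end to end.

What the simulator deliberately does not model: genotyping error and missing
data (calls are error-free, as the analysis assumes), correlation of
interference between windows, any continuous chiasma process along the
chromosome (windows are mutually independent — matching the scan's analysis
unit), and sex differences between the parents' gamete pools (supported by
`simulate_family`'s two-vector interface but not used by default).  Passing
recovery tests therefore validate the estimators and the pipeline's
plumbing under the model's own assumptions; they do not certify robustness
to genotyping error or model misspecification on real data.

## Validation problem sizes

Estimator recovery is checked at n = 50,000 offspring over 20 seeds
(tolerance 0.01 max-abs on ĝ, set by binomial sampling error at that n);
EM monotonicity on random families; the exact algebra against brute-force
16-gamete and 16×16-pair enumeration on 1,000 random g vectors; and the
full pipeline on 20 simulated 19-group studies of 408 offspring with
elevated mid-chromosome C4 and a length-dependent baseline, asking for the
directional ordering of regional deltas and the sign of the length-fit
slopes.

## Known limitations

* Mixed-segregation windows are skipped rather than partially exploited.
* Boundary EM estimates carry no uncertainty statement; near-zero interval
  fractions make C4 estimates unstable (tiny denominators), which is why
  published landscape tables can contain extreme coefficient values that no
  valid gamete distribution reproduces.
* delta depends on the histogram binning; comparisons are only meaningful
  at a fixed bin specification, and small per-region window counts inflate
  it.
* Phase is assumed known and in coupling for all four markers; repulsion
  phases must be recoded upstream.
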