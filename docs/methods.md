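# Methods

## Model

A DVI problem consists of `s` victims with known sex and genotypes at
independent autosomal markers, and `m` missing persons distributed over
reference families, each family a loop-free pedigree with at least one
genotyped reference. Markers are assumed independent and in Hardy–Weinberg
equilibrium (HWE); founder genotypes have probability `p_a²` (homozygote) or
`2 p_a p_b` (heterozygote) under the family's allele-frequency database.

A candidate solution — an *assignment* `a` — is a sex-consistent partial
injection from victims to missing persons. Its likelihood
`L(a) = P(PM and AM data | a)` is evaluated by substituting each paired
victim's genotypes into the missing person's pedigree slot; families are
independent, and unmatched victims contribute HWE singleton probabilities.
All likelihood ratios are reported against the empty assignment (likelihood
`L_0`). Two useful identities, both verified numerically in the test suite:

- **Reduced-problem identity.** The single-pairing ratio
  `LR_{i,j} = L(V_i = M_j)/L_0` computed on the full data equals the same
  ratio computed on the reduced problem containing only victim `i`'s data
  and family-of-`j`'s data. The pairwise matrix is therefore computed on
  reduced problems (much cheaper); the identity itself remains a test.
- **Telescoping.** The log-likelihood of an assignment equals the
  log-likelihood of any fixed sub-assignment plus the conditional LR steps
  of the remainder.

## Likelihood engine

Likelihoods are computed by pedigree peeling in an allele-level
formulation of the Elston–Stewart algorithm: every individual contributes a
paternal and a maternal allele variable; founders carry independent
frequency priors on both; each transmission is a factor
`P(child allele | parent's two alleles) = ½ m[a₁,·] + ½ m[a₂,·]` through
the mutation matrix `m`; typed individuals contribute an unordered-genotype
indicator. The factor product is summed out by greedy min-fill variable
elimination, which on a loop-free pedigree reproduces the nuclear-family
peeling sequence. Numerical safeguards:

- every elimination step rescales by its maximum, accumulating the scale in
  log space, so arbitrarily many markers and deep pedigrees cannot
  underflow;
- a zero intermediate short-circuits to log-likelihood `-inf`, which is a
  first-class value (downstream LRs become exactly 0);
- elimination orders are cached per pedigree structure, since they do not
  depend on the observation pattern.

Looped pedigrees (e.g. descendants of consanguineous matings) are detected
on the marriage graph and rejected; all supported analyses use loop-free
families. A brute-force oracle (explicit summation over all genotype
combinations of untyped members, guarded to ~2·10⁶ combinations per marker)
provides an independent cross-check and is exercised on randomized
pedigrees in the tests.

## Mutation model

Two transmission models are provided. `none` is strict Mendelian
transmission. `proportional` sets, per marker with frequency vector `p`,

    m[a][b] = γ·p_b   (b ≠ a),    m[a][a] = 1 − γ·(1 − p_a),
    γ = rate / Σ_a p_a (1 − p_a),

so the frequency-weighted expected mutation probability per transmission
equals `rate` and `p` is stationary (`p·M = p`). Stationarity is the reason
this model is used for validation across implementations; it is asserted to
1e-10 in the tests, as is the exact degeneration to the Mendelian model at
rate 0. Rates large enough to drive a diagonal entry negative are rejected
per marker. Mutation, when enabled, applies to every parent–child
transmission (reference families and simulated drops alike). Out of scope:
stepwise/geometric models, sex-specific rates, silent alleles and
theta-correction.

## Counting and enumeration

The number of sex-consistent assignments factorizes over sex classes:

    n(s_F, s_M, m_F, m_M) = n₀(s_F, m_F) · n₀(s_M, m_M),
    n₀(s, m) = Σ_{k=0}^{min(s,m)} C(s,k) C(m,k) k!

computed in exact integer arithmetic (the counts grow factorially and
overflow doubles long before they stop being useful as feasibility
estimates). Enumeration is recursive by victim index with candidates `*`
first and missing persons in input order — a fixed order so that written
outputs are stable; the empty assignment is always element 0. A
forbidden-pair set supports restriction to assignments avoiding zeros of a
pairwise matrix. An ignore-sex mode treats everyone as one sex class.

## Search algorithms

All three searches take an LR threshold `T > 1`.

1. **Sequential without updates** — repeatedly accept the largest entry of
   the static pairwise matrix if it reaches `T`, deleting its row and
   column.
2. **Sequential with updates** — identical, but after each acceptance the
   matrix is recomputed *conditional* on all accepted pairings (accepted
   victims become typed pedigree members).
3. **Combined** — Step 1 repeatedly fixes all *undisputed* pairings
   (entry ≥ `T`, all other entries in its row and column ≤ 1) and
   reconditions, until none is found. A relaxed variant replaces the limit
   1 by `entry/T`. Step 2 enumerates the remaining sex-consistent
   assignments, drops those containing a zero of the final conditioned
   matrix (a zero pairwise LR implies a zero joint likelihood), computes
   full joint log-likelihoods of the merged assignments and ranks them.

Tied maxima (log-likelihoods within 1e-9 absolute; threshold comparisons
use the same relative tolerance) branch into separate search paths, and all
distinct terminal assignments are reported — the spec of the stopping rule
when ties span several rows and columns is ambiguous, and exhaustive
branching is the conservative reading. The Step 2 enumeration is guarded by
a configurable cap (default 10⁶ a-priori assignments); exceeding it raises
with the advice to lower `T`, which fixes more pairings as undisputed and
shrinks the remainder.

## Posteriors

Posterior pairing probabilities use Bayes' theorem over an enumerated
assignment space with a prior `π(a)` (flat by default, user weights
renormalized internally); sums are log-sum-exp. Row normalization
`Σ_j q_{i,j} + q_{i,*} = 1` and the column bound `q_{i,j} + q_{i',j} ≤ 1`
are asserted in the tests; the bound is what makes threshold decisions
(`conclude V_i = M_j when q_{i,j} > α`) conflict-free for any `α ≥ 0.5`
with strict comparison.

When the combined search has fixed undisputed pairings before enumerating,
the ranked table's posteriors are by default *conditional* on those
pairings (the fixed pairings implicitly carry probability 1). The option
`posterior_space="full"` instead renormalizes over the complete a-priori
space — this reproduces the flat-prior posterior that a pure joint ranking
would report, at the cost of a full enumeration, and is the right choice
when the fixed pairings are themselves to be quantified rather than
assumed.

## Simulation

Gene dropping samples founders from HWE and transmits alleles through the
mutation matrix; one seeded generator drives an experiment, with a fixed
drop order (families in input order, founders before descendants, markers
in database order) so runs are bit-reproducible. Conditional simulation
under a true assignment merges paired victims into their missing persons'
slots before dropping, so their profiles carry the true relatedness, while
unmatched victims are independent singleton draws.

The true-positive-rate (TPR) experiment replays the three searches on
`n_reps` replicates per marker count. A replicate is a success when the
reported solution set is exactly the truth (`tpr`); a secondary column
(`tpr_member`) counts the truth being among tied solutions, since the
handling of ties in a TPR is a genuine design choice — both are reported,
and the strict reading is the default. For the combined search the
threshold applies to the top joint LR against the null; `alg3_best`
ignores the threshold and scores the most likely solution as such.

The bundled power experiment uses the grandmother-reference family
structure with a synthetic ten-marker panel (ten alleles per marker,
triangular frequency spectrum, expected heterozygosity ≈ 0.87 — comparable
to forensic STR panels) at 200 replicates and threshold 10,000. These
problem sizes keep the experiment small enough to re-run routinely while
leaving the Monte-Carlo error (±2 binomial SEs ≈ 0.07) well below the
observed separation between the joint and sequential strategies. What the
synthetic generator does *not* emulate: genotyping error and dropout,
population substructure, linked markers, duplicate victim samples and
uncertain sex — passing tests say nothing about robustness to those.

## Fixtures and synthetic case-shaped problems

The two built-in toy problems are single-marker problems whose every
number is checkable by hand; their topologies and genotypes are
over-determined by the complete set of likelihood ratios, log-likelihoods
and posteriors they must reproduce, which the test suite asserts in full.

Two generators produce synthetic problems of realistic dimensions: a
plane-crash shape (8 victims, 5 single-missing-person families with one
reference parent each, 15 markers) and a large-family shape (one
three-generation pedigree with 12 missing persons and 6 references, 5
victims, 13 markers, a-priori space 9847). They are synthetic stand-ins of
the same dimensions as published casework datasets whose genotypes are not
public, and exist to demonstrate scale, not to reproduce casework values.

## Degenerate inputs and numerical choices

- Frequencies must be positive and sum to 1 within 1e-6; an explicit
  renormalization option accepts deviations up to 1e-3 and never more.
- Missing genotypes (`-`) mean untyped-at-marker and contribute through
  marginalization, never deletion of the individual.
- A problem with no possible pairings ranks exactly one assignment: the
  empty one, LR 1.
- Display rounding (log-likelihood 2 d.p., LR 3 s.f. scientific when
  ≥ 1e5, posteriors 3 d.p.) applies only to written TSVs; the JSON
  companion and all in-memory tables keep full precision.
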