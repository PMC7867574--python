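# Methods

## Model and assumptions

The package analyses a symmetric two-player iterated survival game of fixed
length *n*. Per step, each player survives independently with probability
*a*, *b*, *c* or *d* according to the pair of behaviors (see README table),
or *a₀* once alone. Survival outcomes are independent across steps and
between players within a step; all five probabilities are constant for the
whole game and strictly inside (0, 1). We always assume *a > d* (C is the
more cooperative behavior), and the equilibrium analysis additionally
assumes the strict Prisoner's Dilemma conditions *c > a > d > b* and
*a² > bc*. Strategies are the *n* + 1 switch-once strategies *Sᵢ*; reactive
play, mixed strategies, opting out, and population dynamics are out of
scope.

The focal player's state follows a non-homogeneous absorbing Markov chain
over {paired, alone, dead}. Each behavior pair has a 3×3 row-stochastic
single-step matrix whose first row is [xy, x(1−y), 1−x] for the individual's
and partner's step survival probabilities (x, y); the lower rows are common
to all four matrices because the loner rate is strategy-independent and
death is absorbing. The overall payoff A(Sⱼ;Sᵢ) is the probability the
focal player is not absorbed after the three phase blocks (CC, then mixed,
then DD).

## Numerical choices

**One code path at the removable singularities.** Every closed form involves
quotients (x^k − y^k)/(x − y) that degenerate when a₀ coincides with a pair
eigenvalue (a², bc, d²). All of them are evaluated through
`geometric_ratio_sum(x, y, k) = Σ_{m<k} x^m y^{k−1−m}`, the exact continuous
extension, so no special-case branches are needed and the matrix-power,
payoff and one-step-gain formulas are exact at a₀ = a², bc, d². The O(k)
summation cost is negligible at the game lengths of interest (n ≤ a few
hundred).

**Payoff is closed-form, the oracle is a product.** `payoff` uses the phase
closed forms; `payoff_oracle` multiplies the n single-step matrices
explicitly and is kept in the public API because the equivalence of the two
routes (|Δ| < 1e-12 exhaustively for n ≤ 12, including engineered degenerate
a₀) is the package's core correctness guarantee.

**Cutoff existence is a value, not an error.** i_D, i_C, j_opt, J_opt, j*,
k* return `math.inf` when nonexistent; classification branches on existence
because nonexistence is a parameter regime, not a failure. When a₀ lies
within 1e-12 of a cutoff the threshold is reported nonexistent (the "≥"
side of the regime table); the boundary is measure-zero and the always-
defect reading there matches the limiting behavior of the payoff
difference.

**Ties.** The analysis assumes A(Sⱼ;Sᵢ) ≠ A(Sᵢ;Sᵢ) for j ≠ i. Any payoff
difference with |Δ| < 1e-12 raises `PayoffTieError` instead of silently
choosing a sign: near classification boundaries a silent choice would
corrupt the regime assignment. Stability tests use the scale-free bracket
of each gain (the a^{2(n−1)} factor removed) so the tie tolerance does not
shrink with n.

**i_D and i_C at a₀ = d².** The logarithm quotient in both cutoffs is 0/0 at
a₀ = d²; within 1e-9 of that point the exact limits
i_D = (c−a)/(a²−bc)·d/(1−d) and i_C = 1 + (d−b)/(bc−d²)·d/(1−d) are used, so
both functions are continuous (and monotone) through the junction.

**k\*(i) and j\*.** k*(i) (the defect-side step size) uses the direct
logarithmic formula; within 1e-6 of the cancellation-prone points a₀ = bc
and a₀ = a₀\* it switches to Brent root-finding on a regularized form of
the multi-step defection-gain bracket in which the (a₀−bc) and (a₀−d²)
cancellations are removed exactly via (x^k−1)/(x−1) ratios evaluated with
expm1. j\* is computed from the zero of the multi-step cooperation-gain
bracket, (a₀/d²)^{j*} = (bc−d²)(a₀−d)/[(bc−d²)(a₀−d) − (b−d)(a₀−d²)], which
satisfies the identity j\* = i_C − 1 exactly (a direct "weighted-average"
rewriting of this coefficient that circulates in one printed form of the
expression does not; the identity served as the arbiter).

**Best responses.** Brute force over the n+1 replies is canonical; the
analytic fast paths (reply = i inside a stable stretch, ⌊i_C⌋ above it,
i + ⌈k*(i)⌉ on the defect side) are assertions checked on every call by
default, not shortcuts. Inside a disequilibrium stretch both side-optima
apply and the assertion compares brute force against the better of the two.
The assertion is skipped when k*(i) sits within 1e-9 of an integer, where
its ceiling is ambiguous at machine precision. Walks always move along the
diagonal (both players adopt the same reply simultaneously); no
alternating-move variant is implemented.

**J_opt and root-finding.** J_opt compares the payoff at ⌊j_opt⌋ and
⌈j_opt⌉ directly rather than trusting curvature. The inverse problem
a₀ ↦ i_D(a₀) = target uses Brent's method on (0, a₀′), valid because i_D is
continuous and strictly increasing there from 0 to +∞.

**Finite n vs. idealized n.** At finite n the endpoint strategy Sₙ needs
only the cooperation condition, so Sₙ stays locally stable even in regimes
where additional defection is always favored in the idealized long game.
`stable_stretch` and `classify_incentives` take a `large_n` flag: with
`large_n=False` the stretch matches `{i : is_locally_stable}` exactly
(including that endpoint effect, with stretches capped at n); with
`large_n=True` the n-induced stability is excluded and the classification
matches the unbounded-game regime table. The survey classifies with
`large_n=True`.

## Monte-Carlo components

**Game simulation** (`itersurv.simulate`) replays the chain literally: per
step, pair-survival draws for both players while paired, loner draws after
the partner's death; the partner's own loner phase is not tracked because
it cannot affect the focal payoff. One seeded `numpy` generator per
estimate; the seed is recorded in the result. The estimator's 95% interval
uses the normal approximation 1.96·√(p̂(1−p̂)/reps). The simulation emulates
exactly the independence structure of the model — it cannot detect model
misspecification (e.g. correlated survival within a step), only errors in
the closed forms.

**Parameter-space census** (`itersurv.survey`). Four i.i.d. uniforms are
sorted into c > a > d > b, draws with a² ≤ bc are rejected and tallied, a₀
is drawn uniformly, and each retained game is classified with
`large_n=True`. The stock ranges are (0, 1) for all five probabilities
(full model) and (0.9, 1) for a, b, c, d with (0.7, 1) for a₀ (narrow
model). The census is vectorized; `sample_game` plus the scalar classifier
form an independent route, and the two are asserted to agree game-by-game
in the tests. Quantiles of i_D and i_C are reported conditioned on the
cutoff itself existing; because the conditioning event is ambiguous in
prose descriptions of such censuses, the union-event variant (nonexistent
values entering as +∞) is also reported in the summary metadata. At 10⁵
samples the binomial standard error of a 25% class is ≈ 0.14 percentage
points; the tests allow three standard errors.

Default problem sizes — 10⁵ census samples in the tests, 2×10⁵ in the
acceptance script, 10⁵–2×10⁵ simulation replicates — keep every stochastic
check well inside a second to a few seconds while leaving the Monte-Carlo
error an order of magnitude below the tolerances checked.

## Known limitations

- The equilibrium machinery requires the strict PD; the payoff engine and
  the single-step classifier cover all four game classes, but cutoff
  behavior outside the strict PD (e.g. Hawk-Dove with a² < bc) is exposed
  without guarantees or tests.
- Equality cases A(Sⱼ;Sᵢ) = A(Sᵢ;Sᵢ) are deliberately not analyzed; they
  raise ties rather than being resolved.
- Monotonicity of the payoff in n holds against an all-C partner and is
  tested there; it is *false* for general (i, j) — an added early
  cooperative step can raise survival against a heavy defector by opening
  an escape into a benign loner track — so no such general claim is made.
- The appendix-style monotonicity statements (J_opt, i_D, i_C increasing in
  a₀; behavior of ⌈k*(i)⌉) are verified numerically on grids, not proved
  symbolically.
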