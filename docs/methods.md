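# Methods

## Model

A screening experiment is modeled as repeated filtering of a variant
population. Surviving round t multiplies a variant's weight by
Q_t(S) ∝ exp(−α_t E(S)): α_t > 0 sets the round's selective pressure and
E(S) is a time-independent statistical energy, lower for fitter sequences.
Composing rounds gives the observation model for a sequenced round t:

    P_t(S) = exp(−β_t E(S) − G(S)) / Z_t,    β_t = Σ_{t'≤t} α_{t'},

with P_0(S) ∝ e^{−G(S)} the initial-library distribution. β_t is a
cumulative inverse temperature — the annealing picture: each round cools
the population toward the minima of E. G absorbs library composition bias
(codon usage, synthesis bias, a mutational cloud around a wild type); it
has no physical reading and is discarded after training, but leaving it out
would push library structure into E.

Both E and G are Potts energies over L aligned positions and q states
(21 = 20 amino acids + gap by default; gap is an ordinary state), either
independent-site (fields only) or pairwise (fields + couplings). Couplings
are stored as full symmetric (L, L, q, q) arrays with zero diagonal blocks;
the free parameters are the i < j blocks.

Assumptions worth stating: selection acts multiplicatively and
time-independently through E (concentration- or round-dependent selectivity
profiles violate this); sequenced rounds are treated as independent samples
of their P_t (defensible when overlap between samples is weak — the regime
the method targets); mutagenesis between rounds is *not* modeled in the
likelihood, only emulated by the simulator.

## Training

The fit maximizes the abundance-weighted log-pseudo-likelihood

    PL(θ, β) = Σ_{t∈τ} Σ_m w_t^m Σ_i log P_t(σ_i^m | S_{\i}^m) − R(θ),

where w_t^m = N_t^m / Σ N_t^{m'} are normalized read counts, the site
conditional is the softmax over states of β_t f_i^E(a; S) + f_i^G(a; S)
with local fields f_i(a; S) = h_i(a) + Σ_{j≠i} J_ij(a, σ_j), and
R = λ_h‖h‖² + λ_J‖J‖² (per parameter, both energies). Site conditionals
never need the partition function, and for independent-site energies they
coincide with the exact likelihood.

The (β, E) product leaves a scale freedom; it is removed by anchoring
β = 0 at the first sequenced round and β = 1 at the second. These two
values are excluded from the parameter vector, never penalized. β is left
otherwise unconstrained (no monotonicity is imposed: under constant
conditions pressures should decay, but the data decide) and the inferred
trajectory is reported per round.

The objective is separately concave in θ and in each β_t, so fitting
alternates:

1. θ-step: L-BFGS on all energetic parameters at fixed β (analytic
   gradients; the β = 0 round contributes nothing to E's gradient and its
   coupling matmuls are skipped).
2. β-step: each free β_t is a one-dimensional concave problem restricted
   to round t; a bounded scalar search on [−50, 50] (tolerance 1e−8), with
   the old value kept on ties so the objective never decreases.

The outer loop stops when max |Δθ| < 1e−4 and max |Δβ| < 1e−4, or after 50
iterations; the per-iteration objective trace is recorded and is
non-decreasing up to 1e−9. The whole fit is deterministic given data and
configuration.

Defaults: λ_h = 1e−4, λ_J = 1e−2 per parameter (standard pseudo-likelihood
DCA practice; both exposed, separately for G). β is initialized at the
0-based index of each sequenced round — a constant-pressure guess. All
softmaxes use log-sum-exp stabilization.

## Gauge and contact scores

Potts energies have reparameterization freedom; the zero-sum gauge (zero
row/column sums in every coupling block, zero-mean fields) is the canonical
form for reporting. Contact scores are Frobenius norms F_ij of the
gauge-fixed coupling blocks — gap state excluded by default, a DCA
convention rather than a derived fact — followed by the average product
correction F'_ij = F_ij − F_i·F_·j / F_··, with means over the full score
matrix so that rank-one (conservation-driven) structure cancels exactly.
Pairs are ranked by decreasing corrected score; output files use 1-based
residue numbers.

## Exact oracle

For q^L ≤ 10⁶ the package enumerates the sequence space (lexicographic,
site 0 most significant) and computes Z_t, P_t, and exact likelihoods by
brute force. This is test machinery: the pseudo-likelihood conditionals are
validated against enumerated conditionals to 1e−10, and the simulator's
round compositions against the closed-form P_t. It is never used in
production fitting.

## Simulator

`simulate_experiment` runs a Wright–Fisher-with-selection process: an
initial library of N individuals from P_0 (exact per-site sampling for
independent-site G, categorical over the enumerated space when feasible,
else Gibbs with a configurable burn-in of full sweeps), then per round
optional mutagenesis (each site replaced by a uniformly random different
state with probability μ — applied before selection, as in error-prone-PCR
protocols), survival reweighting p_v ∝ c_v e^{−α_t E(v)} in log space, and
a multinomial resample back to constant N. Sequencing is a further
multinomial draw of fixed depth. The multinomial noise model is the
simplest exchangeable choice; alternatives (Poisson thinning) change
variances, not expectations. A single seed spawns independent per-stage
streams (`SeedSequence.spawn`, fixed order), so stages are individually
reproducible.

With μ = 0 the expected round-t composition is exactly P_t with
β_t = Σ α_{t'} — the property the oracle checks. What the simulator does
*not* emulate: PCR amplification bias, sequencing errors, chimeras,
fitness-dependent population growth, round-to-round correlations of
mutations. Passing the synthetic suites therefore demonstrates correctness
of the inference machinery under the model's own assumptions, not
robustness to these real-data artifacts.

## Evaluation procedures

**Selectivity.** The empirical per-variant fitness proxy θ^m is the
ordinary-least-squares slope of log frequency against the experimental
round label (labels, not consecutive indices), with the regression standard
error as its uncertainty. Eligibility requires real reads in ≥ 2 rounds.
With a pseudocount (0.5 reads is customary) the regression series is
completed over all rounds, which also gives two-round variants a
non-degenerate uncertainty — without it their SE is exactly zero (no
residual degrees of freedom) and uncertainty ranking is meaningless for
them. A two-point log-ratio variant is exposed as `method="ratio"`.
Energy–selectivity agreement is the Pearson correlation of −E against θ
(lower energy = fitter, so the expected sign is positive), traced while
variants are pruned from most to least uncertain over a 10-point retained
fraction grid [0.1, 1.0].

**Classification.** Binder/background separation by selection energy,
lower E = predicted binder; ROC/AUC via the Mann–Whitney statistic with
ties counted 1/2.

**Contacts.** Positive predictive value at each rank of the corrected
coupling scores against a supplied true-contact pair list, with pairs
closer than 5 positions (sequence separation, a standard DCA convention)
removed from both prediction and truth.

## Reference protocol conditions

The quantitative acceptance checks run at these fixed conditions (chosen
once as realistic emulations of the three regimes, seeds aside):

* **Oracle/gradient**: random pairwise models, L ≤ 4, q ≤ 3, agreement to
  1e−10 / finite-difference step 1e−5.
* **Annealing recursion**: L = 4, q = 2, N = 10⁶, α = (1, 1, 1), μ = 0;
  total variation of the round-3 population against exact P₃ (measures
  multinomial drift only, ~3 × 10⁻³).
* **Pairwise recovery**: L = 10, q = 4, rounds (0, 1, 2) at 10⁵ reads,
  N = 10⁶, pairwise truth (field scale 0.5, coupling scale 0.25, 40% block
  density), mild independent-site G; fit E as Potts/G as fields on 4/5 of
  variants, Pearson against truth on 500 held-out variants. Four outer
  iterations suffice here; the θ sub-problem is convex and the anchored β
  make later refinements marginal.
* **Temperature recovery**: L = 6, q = 3, independent-site, depth 10⁵,
  true free β₂ = 2.
* **Classification**: L = 8, q = 4, samples at β = 0 (library) and β = 3
  (after three rounds), 2 × 10⁴ reads each; AUC on held-out variants.
* **DMS selectivity**: L = 8, q = 4, rounds (0, 1, 2) at 10⁵ reads, μ = 0.
  The background G is drawn at field scale 1.5 so the library concentrates
  on ~10⁴ variants read tens of times each — the coverage a mutational
  scanning library actually has, and the only regime where selectivity is a
  meaningful yardstick (a diffuse library at this depth yields ~1 read per
  variant and the selectivity estimate itself, not the model, becomes the
  bottleneck). Pseudocount 0.5.

## Numerical notes and limitations

Degenerate inputs: empty rounds, non-positive counts, unequal lengths and
out-of-alphabet characters raise typed errors (an opt-in permissive mode
maps unknown residues to the gap state with a warning). Duplicate variants
are merged by summing counts; row order is canonicalized lexicographically,
so ingestion is permutation-invariant. Enumeration is guarded at
q^L ≤ 10⁶. Ties in β search keep the incumbent value. Model files are JSON
with full float precision (bit-exact round trips).

Known limitations: couplings are only identifiable with sufficient sequence
variability and depth — with two sequenced rounds and shallow coverage the
pairwise E overfits toward the L2 prior; β values far outside [−50, 50] are
not searched; the pseudo-likelihood is a consistent but not efficient
surrogate, so energies near the data manifold are much better determined
than in unexplored corners of sequence space; and heavily gapped alignments
make the gap state absorb alignment artifacts into E.
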