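# Methods

## The kinetic model

A multi-step enzymatic reaction is a directed graph of enzymatic states
with first-order rate constants `k_ab` on its edges.  Writing `s` for the
normalized occupancy vector, the dynamics are the linear ODE system
`ds/dt = K s`, where the generator has `K[a, b] = k_ba` off the diagonal
and `K[a, a] = -Σ_g k_ag`; columns sum to zero, so total occupancy is
conserved and the kernel of `K` is the steady state.

The King-Altman (KA) construction gives that steady state combinatorially:
enumerate every *KA diagram* — a directed spanning tree with `n-1` edges in
which every non-terminal state has exactly one outgoing edge and all paths
converge on the terminal state — and weight each diagram by the product of
its rate constants, `κ_l = Π k_ij`.  Then

    s∞[a] = Σ_{l → a} κ_l / Σ_l κ_l .

`kinn.kinetics.enumerate_ka_diagrams` enumerates exhaustively (one
outgoing-edge choice per non-terminal state, cycle check); this is exact
and instantaneous at the 3–6 state scale the package targets, so the
incremental tree-growing algorithms used for large diagrams are not
needed.  Diagram weights are always computed in log space with
log-sum-exp, so rate ratios of many decades cannot overflow.

The observable is the *activity* `ν = Σ_{act} k̃_ab · s_a`, the production
flux through the designated measurable (activity) edges.  For Cas9
cleavage the canonical scheme is the 4-state cycle

    unbound ⇌ PAM-bound ⇌ R-loop ⇌ cut-competent → unbound (cut)

with a reversible backbone, an irreversible product ("cut") step closing
the cycle, and the binding rate scaled by the unbound-DNA reservoir
concentration `Du` (nMol).

Kinetic profiling assays do not watch a steady-state cycle: substrate
depletes.  The depleting-reservoir generator `K'` removes the return flux
of the cut edge (entry `(0, 3)` becomes 0 for the 4-state cycle);
`det K' ≠ 0` and the measured single-exponential cleavage rate is minus
the eigenvalue of `K'` closest to zero.  Two identities connect the two
pictures for the 4-state cycle: `det K'` equals the product of the four
forward-cycle rates, and the linear characteristic-polynomial coefficient
satisfies `a1(K) = a1(K') = Σ_l κ_l`.  Consequently, when the cut step is
rate-limiting, the slow eigen-rate is approximately `a0/a1` — exactly the
KA activity.  `char_poly_identities` verifies both sides; it computes the
coefficients over exact rationals (`fractions.Fraction`) because the
identities rest on algebraic cancellation that float64 LU factorization
only resolves to ~1e-9 relative when rates span decades.

Numerical conventions worth stating:

- `propagate` solves `ds/dt = K s` via `expm(K t) @ s0` — relaxation
  toward `s∞` with `K`'s non-positive spectrum.  (The compact closed form
  sometimes written with an explicit `e^{-Kt}` factor uses the opposite
  sign convention for `K`; this implementation is fixed by requiring it
  to satisfy the ODE itself.)
- The "slow eigen-rate" is the *nonzero* eigenvalue of smallest magnitude;
  numerically-zero modes (conserved subspaces of degenerate schemes) are
  excluded, ties in magnitude break toward the larger real part, and a
  complex slow mode triggers a warning with the real part returned.
- Irreversible steps are simply absent edges; no zero-rate placeholders
  exist anywhere, so diagrams requiring a missing edge are never
  generated.

## KINNs

A kinetically interpretable neural network maps an encoded guide-target
alignment to a cleavage rate through layers that are the kinetic theory:

1. one single-filter convolution per edge reads a window `[i, j)` with
   kernel size `d` and outputs `log k_ab` (with `d = 1` a positionwise
   additive free-energy model; with `d = j - i` a fully connected map);
2. a static binary matrix `B` (diagrams × edges) turns log rates into log
   diagram weights; a softmax over diagrams *grouped by terminal state*
   yields `s∞` — this grouped form equals the KA formula exactly, and
   reduces to a plain softmax when each state owns a single diagram;
3. the activity, or alternatively the slow eigen-rate of `K'`
   (`output_head="eigen_rate"`), passes through a small affine link head
   `y = σ_o(σ_ν(ν·Wt + bt)·Wo + bo)`.

Because no deep-learning framework is assumed, the package carries its own
compact reverse-mode autodiff over numpy (`kinn.autodiff`).  The eigen
head differentiates through the eigenvalue with first-order perturbation
theory, `dλ = l·dK·r` with matching left/right eigenvectors; the
contract — analytic gradients agree with central finite differences to
1e-4 relative — is enforced by tests for both heads rather than assumed
from the mechanism.

Training minimizes squared error on the log rate by default (labels span
decades).  With the default identity link the loss is evaluated on the
log-activity path directly, which is exact and unconditionally stable;
the affine head then remains at its identity initialization, so the
prediction *is* the activity.  Non-identity links (`softplus`,
`exponential`) are available by configuration and are trained through the
head with a clamped log.  The optimizer is Adam (default learning rate
1e-2 to 8e-2 depending on caller, full batch for the small in vitro
models), early-stopped on validation Pearson with the best epoch
restored.  Kernel weights initialize small and symmetric; biases start at
`log(median label)/n_edges` so initial rates sit near the label scale and
the KA softmax is unsaturated.

`extract_rates` exponentiates the per-edge outputs into a
`RateAssignment`, so a fitted KINN hands its mechanism straight back to
`kinn.kinetics` (`propagate`, `slow_eigen_rate`) — the interpretability
claim is a working code path, not a metaphor.

## Sequence encodings

Two deterministic encodings (`kinn.encoding`):

- **Pairing encoding** (`L × 4`, default `L = 50`): per position, a
  one-hot of the *pairing class* — complementary, or one of three
  mismatch identities given by the target base's rank among the
  non-complementary bases in A<C<G<T order.  This is the simulator's
  native representation.
- **In vivo 13-channel encoding** (`25 × 13`): columns are
  `[PAM(3) | guide(20) | insertion padding(2)]`, PAM-proximal first
  (the constituent blocks are standard; their order is this package's
  convention and every downstream window coordinate refers to it).
  Channels are guide one-hot (4), substitution one-hot (4), insertion
  one-hot (4) and a deletion bit.  The target is written
  protospacer-strand, so a substitution fires where target ≠ guide base;
  unused padding columns are all-zero ("N" columns); alignments needing
  more than the two insertion columns are rejected rather than truncated.
  `decode_invivo` inverts the encoding exactly on canonical alignments.

U and T are equivalent on the guide; everything is uppercased on input.

## The simulated benchmarks

**In vitro (Arrhenius)**.  Each of the seven rates of the 4-state cycle
is controlled by its own five-nucleotide window; the seven windows tile
the active region `[5, 40)` of a 50-nt pairing in scheme edge order
(k01, k10, k12, k21, k23, k32, k30) and are pairwise disjoint.  Rates
follow

    k_ab = k0 · exp(∓ (1/kBT) Σ_{i∈Ω_ab} ΔG(class_i)),

negative exponent for forward transitions (the cut step counts as
forward), positive for backward.  Free energies are dimensionless in kT
units, hence `kBT = 1` — ΔG values carry the scale.  Complementary pairs
contribute −1; each (transition, mismatch class) value is drawn once from
{−0.1, 0.1, 1} under the seed and frozen into the config, so a dataset is
perfectly reproducible from (config, seed) and rates regenerate exactly
from the sequences.  `k0 = 0.01 s⁻¹` (`s⁻¹ nMol⁻¹` on the binding edge,
whose effective rate carries `Du = 1 nMol`).  Labels are the slow
eigen-rate of `K'` (batched eigendecomposition); default library size is
20,000 sequences with i.i.d. uniform pairing classes, and only the active
region can influence a label.  Keying ΔG by the four pairing classes
(rather than all 16 base pairs) makes the ground truth exactly
representable by a `d = 1` KINN over the pairing encoding — the planted-
model recovery tests measure estimation quality, not representation
error.

**In vivo (synthetic)**.  Real in vivo compilations are external
downloads; the benchmark here is generated: random guides with
NGG-like PAMs, targets mutated at 15% per position plus 2% deletions
(insertions are supported by the encoder but not planted — they add
alignment bookkeeping without touching any property under test), encoded
25 × 13.  A planted KINN with anchored windows produces a log cleavage
rate; a known context effect — an additive per-guanine log-rate bonus
over the target, centered, echoing guanine-rich activation in cells —
plus Gaussian logit noise feeds a logistic link whose intercept is
calibrated by bisection so the expected positive fraction hits the
configured rare-positive rate (default 5%; real off-target compilations
are more extreme, ~1e-3, which at desk-scale n would leave too few
positives to score).  True per-record δ and log rate are stored for
recovery tests.  What passing these tests shows: the transfer machinery
recovers a context effect *of this planted form* on top of a correct
kinetic backbone; it does not certify performance on real cellular data,
where context effects are not additive in G-content and the kinetic model
itself is misspecified.

## Architecture search (PMBGA)

The probabilistic model-building genetic algorithm keeps one categorical
distribution per hyperparameter of every rate: window start `i` (support
`[φ(k) − w/2, φ(k) + w/2]`, default `w = 10`), window width `j − i`
(support `[1, 5]`) and kernel size `d` (support `[1, j−i]`, truncated
after the width is drawn).  The anchor function spreads the forward
rates uniformly along the input — `φ(k_{a,a+1}) = round(L·(a+1)/n)`, so
for a 4-state scheme on a 20-nt input: φ(k01) = 5, φ(k12) = 10,
φ(k23) = 15 — backward rates share their forward partner's anchor, and
the closing step's anchor (at `L`) is clamped onto the last valid start.
"Multinomial over an interval" is read as a uniform categorical on the
integers of that interval.

Each generation samples `m = 10` architectures, trains each briefly
(budgeted epochs, early stopping — a full 10×10 search runs in ~2 minutes
on one CPU at n ≈ 2000), and scores validation Pearson (constant
predictions score 0).  Architectures strictly above the generation mean
survive; if none do (all-equal fitness), the top half by fitness with
deterministic index tie-breaking survives instead, guaranteeing progress.
Survivors add one pseudo-count per choice to the corresponding Dirichlet
concentrations (uniform α₀ = 1 prior).  The generation mean is computed
from the current generation only, and the loop runs a fixed number of
generations (default 10) — both choices kept deliberately simple since
the search is insensitive to them at this scale.  Freezing the prior
(`update=False`) gives the matched-budget random-sampling baseline.

Two caveats the tests encode.  First, with this generator the
cleavage-rate label identifies the *cut-step* window sharply but
tolerates misplacement of the reversible-step windows (their signal can
be partially absorbed by neighbours), so posterior concentration is
asserted for the cut rate.  Second, the anchored prior is not
decoration: with a near-uniform prior over all starts, ten generations of
survivor counts cannot concentrate an 11-fold larger support, and the
posterior update only trades away the sampling diversity that a
matched-budget random search exploits — the method is built for
informative, expert-anchored priors, and that is the regime in which the
search-beats-random comparison is run.

## In vivo transfer learning

A frozen pretrained KINN supplies in vitro log rates `κ(x)`.  A trainable
convolutional backbone reads the same 25 × 13 encoding and emits one
modifier per rate; in vivo rates are `k' = exp(κ + δ)`, which flow
through the KINN's own KA and activity layers into a sigmoid over an
affine of the log activity.  Log activity (rather than raw) enters the
sigmoid for scale stability — activities span decades and the logit is
linear in log rate.  Gradients reach the backbone and heads only; the
freeze contract is enforced by SHA-256 hashing the frozen parameters
before and after every training run.

The backbone is assembled from a discrete menu per layer slot: first
convolution {k1, k3, k5, dilated, inception-like, linear}, second
convolution {same, identity}, dropout {0.1, 0.3, 0.5}, bidirectional
recurrent {32 units, 16 units, identity}, flatten {plain, attention,
dense-64}.  The inception-like option concatenates parallel kernels
{1, 3, 5}; the recurrent slot is a bidirectional tanh RNN (the slot's
contract is its hidden sizes and the identity option, not a specific
cell).  The δ head is a single affine map of the flattened backbone
output and starts at zero, so training begins exactly at the frozen KINN.
Training minimizes positive-class-weighted binary cross-entropy
(default weight `n_neg/n_pos`) with minibatch Adam, tracking validation
average precision (AUPR — the right metric under rare positives) with
best-epoch restore.

`select_model` runs a seeded random search over (backbone, candidate
KINN) combinations.  Random search is a deliberately simple, strong
baseline at this space size (~10³ combinations) and keeps the search
dependency-free; reinforcement-learning controllers address much larger
spaces.  It reports the best model by validation AUPR, per-slot selection
frequencies among the top models, and an optional ensemble whose
predictions are averaged probabilities (mean chosen over rank-averaging
for calibration).

## Problem sizes used in the test suite

The validation suite runs everything at sizes chosen to exercise the
statistics without waste: 1000 random schemes for the KA/null-space
oracle, 100 instances for the dynamics/identity/regime checks, 20 random
KINNs for the gradient contract, n = 2000 training (5000 for rate
extraction) for planted-model recovery, 10 generations × 10 architectures
× 5 seeds for search-vs-random, and n = 5000 × 5 seeds for the transfer
gain and its zero-effect negative control.

## Known limitations

- Linear (first-order) kinetics only: no concentration coupling,
  stochastic kinetics, or multi-substrate competition.
- Exhaustive diagram enumeration is exponential in principle; fine at
  ≤ 6 states, wrong tool at 20.
- The `a1(K) = a1(K')` identity is verified for the 4-state cycle
  topology only and the checker refuses other topologies.
- The synthetic in vivo benchmark plants an additive G-content effect;
  real cellular context (chromatin, repair, expression) is far richer.
- No GPU path; the autodiff engine is deliberately minimal and the
  models sized accordingly.
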