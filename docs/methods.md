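# Methods

## The classifier

S-dFasArt is a supervised, dynamic, fuzzy ART-family classifier for small
sets of normalized pattern vectors — here, physiological responses (pulse
rate, skin conductance level and response, respiration rate, skin
temperature) recorded under activities of graded difficulty and labeled
relax / medium / stress.  It is prototype-based and incremental: training is
a single pass over the samples in their temporal order, each sample either
refining an existing category or committing a new one.  Knowledge already
stored is never deleted or relabeled (stability); new patterns can always
recruit new categories (plasticity).

Each category *j* stores, per input feature *i*, a weight triple
`W_ji <= C_ji <= V_ji`.  The interval `[W, V]` is a plateau of full
membership; linear flanks of width `sigma` extend the support to
`[W - sigma, V + sigma]`.  A freshly committed category is a point
(`W = C = V = I`), so its membership is a triangle of half-width `sigma`
around the committing pattern.  The trapezoid-with-flanks form was chosen so
that a point category still accepts nearby inputs and `sigma` alone controls
how diffuse a category is.

### Dynamics

Activation of category *j* follows

    dT_j/dt = -A_T * T_j + B_T * prod_i eta_ji(I_i)

whose equilibrium `T_j* = (B_T/A_T) * prod_i eta_ji` is what classification
uses: under one-sample-at-a-time evaluation there is no need to integrate
the transient, so the closed form is the default and the explicit-Euler
integration is kept as a streaming mode and as the oracle the tests compare
against.

The dissimilarity ("category size") between input and category is

    l_i = max(V_i, I_i) - min(W_i, I_i)
    d   = sum_i l_i / (|2*C_i| + eps)

zero exactly when the input sits on a point category, and growing as the
input moves outside the plateau.  The reset level `R_j` is driven by `d`.
Three reset laws are selectable because the literal equation

    dR/dt = (-A_R*R + B_R*d) * (R_max - R)

has an equilibrium `min(B_R*d/A_R, R_max)` that *decreases* with `A_R`,
while the intended role of `A_R` is to *increase* category creation as it
grows.  The default law therefore factors the rate out of the whole drive,

    dR/dt = A_R * (-R + B_R*d) * (R_max - R),

and evaluates it at a finite horizon (explicit Euler, `dt = 0.01`, 100
steps, i.e. one time unit): the equilibrium is then independent of `A_R`
but the level *reached at the horizon* grows with it, which reproduces the
expected monotone proliferation trend.  The two printed forms
(`printed_steady_state`, `printed_finite_horizon`) remain available via
`NetworkParams.reset_law`.  Euler steps are clipped to `[0, R_max]`, which
also guards the rare overshoot when `d` is large (tiny `|2C| + eps`
denominators can make `d` big).

### Search, vigilance, match tracking

Per sample: activations and resets are computed once for all categories;
the search loop repeatedly takes the most active non-disabled category
(ties to the oldest) and

* resets it if `R_J >= vigilance` (it is too dissimilar to learn this
  sample),
* match-tracks if its label disagrees with the supervision label:
  vigilance is set to exactly `R_J`, the offender is disabled, and only
  categories strictly more similar than the offender stay eligible,
* otherwise resonates and learns.

If no category remains (or the maximum activation is at or below
`alpha = 1e-30`), a new category is fast-committed with `W = C = V = I`,
the supervision label, `T = 1`, `R = 0`.  Vigilance returns to the baseline
`h(rho) = 0.1` and disables are cleared before the next sample; match
tracking never persists across samples.  Termination is guaranteed: every
loop iteration either terminates or disables one category.

### Learning (fast commit / slow recode)

The resonating winner takes one discrete step towards the fixed points of
the weight dynamics:

    W <- W + A_W * (min(I, W) - W)
    C <- C + A_C * (I - C)
    V <- V + A_V * (max(I, V) - V)

so repeated presentation of the same input converges to
`W* = min(I, W0)`, `C* = I`, `V* = max(I, V0)`.  The gains are normalised
so these are the fixed points; with a literal unit gain on the `V` equation
and `A_V = 0.1` the maximum weight would grow without bound.  Because
`A_C > A_V`, a transient can push `C` past `V` (e.g. a point category at
0.5 presented with 1.0); ordering is restored after every step by widening
the plateau to contain `C` (`W <- min(W, C)`, `V <- max(V, C)`), which does
not move the fixed points.  Weights stay in `[0, 1]` whenever inputs do
(every update is a convex combination).

### Prediction

Test-time classification computes equilibrium activations only — no
vigilance, no learning — and returns the winner's label.  A probe outside
every category's support would otherwise be unclassifiable; the default
fallback is rejection-free: each category is scored by the product of
memberships with the flanks extended to the domain boundaries `[0, 1]`,
exact score ties break by Euclidean distance to the category centre and
then by age.  On point categories this behaves like a nearest-prototype
rule, which the tests verify.  A `strict=True` mode returns `None` for
such probes instead.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `A_T` | 0.01 | activation rate; with `B_T = 1`, equilibrium gain is 100 |
| `A_R` | tuned (0.05–2.15 working range) | reset growth speed; proliferation control |
| `sigma` | tuned (1e-4–1 working range) | membership flank width (diffuse character) |
| `A_W, A_C` | 0.8 | learning speed of minimum / central weights |
| `A_V` | 0.1 | learning speed of maximum weights |
| `eps` | 0.001 | guard in the category-size denominator |
| `alpha` | 1e-30 | activation threshold counting as "null" |
| `h(rho)` | 0.1 | baseline vigilance |
| `R_max` | 0.2 | reset ceiling |
| `B_T, B_R` | 1 | gains of the dynamic equations |
| `dt`, `horizon_steps` | 0.01, 100 | Euler controls for finite-horizon reset laws |

All features must be normalized to `[0, 1]` (per-feature min–max); the
membership geometry assumes a bounded domain.  Complement coding, common in
fuzzy-ARTMAP implementations, is deliberately absent: the interval weights
`(W, V)` already encode category extent.

## Evaluation protocol

* **LOOCV** — K folds, each holding out one sample; the training pass uses
  the remaining K−1 samples in their original order.  Success is the mean
  over folds.  Normalization statistics (and the PCA basis, when used) are
  refitted inside every fold on the training samples only; held-out values
  outside the training range are clipped to `[0, 1]`.  This is the
  non-leaking choice; whether the original analysis refit per fold is not
  documented.
* **Sweep** — LOOCV at every (A_R, sigma) pair, everything else at
  defaults.  The default reconstructed grid is 106 A_R values (0.05 to 2.15
  step 0.02) × 105 log-spaced sigma values on `[1e-4, 1]` = 11130
  configurations; log spacing was chosen because the empirically good sigma
  values cluster near the low end.  Argmax ties resolve to the lowest A_R,
  then the lowest sigma.
* **Proliferation study** — one full fit per A_R value (defaults
  elsewhere), recording the committed category count; used to pick the A_R
  working interval before sweeping.
* **PCA variants** — mean-centred projection onto the top *n* principal
  axes, per-component min–max rescaling back to `[0, 1]` (required by the
  membership geometry; a known deviation risk when comparing against
  analyses that rescale differently).

## Synthetic data

The generator emulates the reference study shape: 7 users × 3 classes × 5
samples (K = 105, 15 per user), 5 features in `[0, 1]`.  Class centres
follow the physiological direction of increasing stress (pulse, skin
conductance, respiration up; skin temperature down) with pairwise
separation ≥ 0.49; per-class scatter is Gaussian with sd 0.1; each user
carries a shared Gaussian baseline offset (sd 0.05) emulating inter-subject
variability; samples are ordered user by user and, within a user, by
activity block.  Label noise replaces a sample's label with a different
class; it is implemented with one fixed uniform draw and one fixed
alternative label per sample, so the flip sets are nested across noise
levels and accuracy degradation is monotone by construction of the
corruption (not of the classifier).

What the generator does **not** emulate: temporal autocorrelation within an
activity block, feature-specific noise distributions (e.g. skewed SCR
magnitudes), drift over the session, or sensor artifacts.  Passing tests on
this data therefore demonstrate the mechanics and the protocol, not
performance on real recordings.

## Problem sizes and numerical choices

The test suite and the acceptance script sweep a 5 × 5 (A_R, sigma) grid
and a 3 × 3 grid for the 3-component PCA variant on the K = 105 dataset —
dense enough to locate the high-success plateau on this synthetic data
while keeping a full run to a couple of minutes.  The full 11130-point grid
is constructed and checked for size, and remains available through
`sdfasart sweep` with its default grids.  The finite-horizon reset
integration is JIT-compiled when numba is importable; a pure-numpy path
with identical semantics (bitwise, both clipped per step) is the reference
and the fallback.

Degenerate inputs: constant features normalize to 0.5 with a warning; a
constant PCA component rescales the same way; an empty dataset, a
wrong-column CSV and a non-numeric feature cell raise format errors naming
the offending row.

## Known limitations

* The exact triangular membership parameterization, the reset law used for
  the published proliferation figure, and the normalization scheme of the
  original feature pipeline are reconstructed design choices; results on
  the original recordings may differ in detail.
* One-pass training is order-sensitive (inherent to ART): shuffling the
  presentation order can change the committed category set.  Determinism
  holds per order.
* No soft posteriors: the classifier outputs a single label (or `None` in
  strict mode).
* Vigilance baseline restoration is per sample; with single-epoch training
  a per-epoch variant would behave identically, but the distinction exists.
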