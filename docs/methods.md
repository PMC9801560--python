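# Methods

## The physical model

`pbdtss` treats double-stranded DNA as a Peyrard–Bishop–Dauxois (PBD) chain:
one continuous coordinate `y_n` (Å) per base pair, the stretching of the
hydrogen bonds relative to the closed ground state.  The configurational
energy of an `N`-pair chain is

```
U = V_1(y_1) + Σ_{i=2..N} [ V_i(y_i) + W(y_i, y_{i-1}) ]
```

with an on-site term per pair and a stacking coupling per ordered dimer:

```
V(y) = D (e^{-αy} − 1)²  +  Θ(y) · b y³ / cosh²[c(αy − d·ln 2)]
W(y, y') = ½ K (1 + ρ e^{−δ(y+y')}) (y − y')²
```

The Morse well `D (e^{-αy} − 1)²` models the hydrogen bonds (two for A·T,
three for G·C, hence `D_GC > D_AT` and `α_GC > α_AT`); the hump added for
`y > 0` is a solvent/entropy barrier that an open base must re-cross to close,
shaped so the `y³` factor leaves the well bottom untouched.  The stacking
stiffness drops from `K(1+ρ)` to `K` when either neighbour opens — the
nonlinearity responsible for sharp, cooperative melting.  Sequence enters
twice: through the pair type of each position and through the sixteen
dimer-specific `K` values.  All constants are the published parameterisation
calibrated against melting experiments and are exposed on `PBDParameters`;
none are re-fit here.

Temperature enters through `β = 1/(k_B T)` with `k_B = 8.617333×10⁻⁵ eV/K`,
matching the eV/Å units of the force field.

## What is computed

All observables are equilibrium averages in the *dsDNA ensemble*: the
configurational ensemble minus the fully denatured state (weight
`Z = Z_I − Z_II`, where `Z_II` restricts every coordinate above the opening
threshold).  A pair is "open" when `y > y0 = 1.5 Å`; the same threshold `ξ`
defines the constrained integrals (the model has exactly one physical
open/closed separation, so `ξ = y0`).

* `P(j closed) = Z(j closed) / (Z_I − Z_II)`, and the single-base opening
  probability is its complement.
* `P_bub(k, m)`: probability of a bubble of *exact* size `m` centred at `k` —
  a run of `m` open pairs flanked by closed pairs, with virtual closed pairs
  assumed beyond the chain ends; for even `m` the centre is the base directly
  left of the midpoint.  The size-`N` "bubble" is the excluded all-open state
  and has probability zero by construction.
* `P_part(k, m)`: probability that pair `k` sits inside a bubble of size at
  least `m`, obtained by summing `P_bub` over all sizes `m' ≥ m` and all
  centres whose bubble covers `k` (separate even/odd centre ranges; centres
  outside the chain contribute zero).  `P_part(k, 1)` is the plain opening
  probability `⟨θ_k⟩_μ`.

Because the chain is one-dimensional, every constrained partition function is
evaluated exactly by iterative one-dimensional quadrature ("transfer
integral"), linear in `N` and quadratic in the number of grid points.  The
bubble matrix needs the weight of *every* open run `[a, b]`; these are
obtained in a single sweep that advances all active runs with one matrix
product per chain position, so a full 300-base bubble matrix costs
`O(N² n²/2)` flops and runs in well under a second on one core at the
production grid.

## Numerical choices

* **Quadrature.** Gauss–Legendre on `y ∈ [−2, 50] Å` — the Morse wall
  extinguishes the integrand below ≈ −0.5 Å and the potential is flat long
  before 50 Å; the dsDNA-ensemble probabilities are insensitive to the upper
  cutoff because the all-open weight is subtracted.  The rule is a *composite
  of two panels joined exactly at the threshold* `ξ = 1.5 Å`: open/closed
  constraints then select whole panels of a smooth integrand instead of
  slicing a panel mid-node, which keeps constrained integrals spectrally
  convergent.  With the default 600 points, doubling the count changes no
  reported probability by more than 2×10⁻⁷ (the package asserts < 10⁻⁴).
  The classification pipeline uses 96 points, which is within ≈ 7×10⁻⁴ of the
  converged values at 345 K and ≈ 5×10⁻³ at 360 K — far below the feature
  differences that drive classification — and makes a 300-base profile cost
  ≈ 0.07 s.
* **Scaling.** Boltzmann weights over 300 bases span hundreds of orders of
  magnitude; every forward/backward vector and run column is renormalised per
  step with an accumulated log scale.  Probabilities are ratios and therefore
  exactly invariant to this bookkeeping.
* **Heaviside convention.** `Θ(0) = 1`; immaterial under quadrature (no node
  sits on the threshold, and the barrier vanishes at `y = 0` anyway).
* **Degenerate regime.** If `Z_II` approaches `Z_I` (fully melted chain, far
  above the temperatures used here) the dsDNA ensemble is empty and the code
  raises `NumericalRegimeError` instead of returning 0/0 noise.
* **Dimer orientation.** The stacking bond between pairs `i−1` and `i` is
  keyed by the dimer read 5'→3' on the given strand, `seq[i-1] + seq[i]`.
* **Chain ends.** Free boundaries (no periodic wrap); the virtual closed
  pairs beyond the ends exist only in the bubble bookkeeping.

## Windows and features

Candidate sites are described by two windows: 201 bases (`[−100, +100]`) for
the string kernels and 300 bases for the physics.  The printed interval
`[−150, 150]` spans 301 positions but the model takes 300 bases; the package
resolves the off-by-one as positions `−150 … +149` (site at 0-based index
150).  The first and last 50 probabilities of each 300-base profile are
discarded — free chain ends breathe anomalously — leaving 200 central values
as the feature vector.  The production feature is `P_part(k, 8)` ("bubbles of
size ≥ 8"), with `m = 1` (plain opening) also supported; 345 K is the default
temperature, where bubble contrast between AT-rich and mixed sequence is
largest in the 310–360 K sweep.

## Kernels and learning

* **Sequence view.** Weighted-degree (WD) kernel of order `d`: positionally
  anchored co-occurrence counts of k-mers, `k = 1..d`, weighted by
  `β_k = 2(d−k+1)/(d(d+1))` (the weights sum to 1).  The shifted variant
  (WDS) is provided with unit position weights and a constant shift range —
  the unspecified generalisations default to the simplest choice — but the
  pipeline's headline uses WD.
* **Physics view.** RBF kernel on the 200-dimensional profile, width
  `γ = 1/(200 · pooled feature variance)` by default.
* **Hybrid.** Equal-weight average of the two Grams *after* unit-diagonal
  (cosine) normalisation of each.  Without normalisation the WD component
  (magnitude ≈ L) would swamp the bounded RBF component.  For uniformity all
  Grams fed to the SVM are unit-diagonal normalised; for WD this divides by a
  constant (its self-similarity depends only on the window length), which the
  C grid absorbs, and it makes the hybrid with weights (1, 0) coincide
  exactly with the sequence-only route.
* **SVM.** Soft-margin dual on precomputed Grams, solved by the libsvm SMO
  engine (KKT tolerance 10⁻⁶); models keep dual coefficients, bias and
  support indices and can score from a cross-kernel block alone.  Convex
  combinations of PSD Grams are PSD up to round-off; an eigenvalue-clipping
  repair is available for matrices damaged beyond `−10⁻⁸·λ_max`.

## Protocol

Training data are undersampled to imbalance ratio 1:1 (all positives kept, a
seeded uniform subsample of the negatives).  Parameters are picked by
stratified 10-fold cross-validated auROC over the full grid — WD order
`d ∈ {6, 12, 24}` × `C ∈ {10⁻³ … 10³}` (21 combinations; the RBF view
searches the 7 C values at the heuristic γ) — with ties broken toward the
smallest `C`, then the smallest `d`.  The selected model is retrained on the
undersampled set and scored on a fixed held-out test split, mirroring a
train/test benchmark design rather than CV-only reporting.  The
undersampling is repeated (default 5 replicates) and metrics are reported as
mean ± 1.96·sd/√n, a normal-approximation 95 % interval over replicates.
Reported metrics: sensitivity, specificity, G-mean (threshold 0) and auROC
(tie-grouped threshold sweep; equals the Mann–Whitney pairwise statistic).

## The synthetic benchmark

Real TSS benchmarks cannot be bundled, so `make_synthetic` emulates their
*shape*: 201/300-base window pairs, ≈ 10:1 imbalance, and positives that are
separable through two partially complementary channels —

1. a degenerate promoter-like motif (default consensus `TATAAA` at offset
   −28 from the site, each position mutated with probability 0.15), visible
   to the WD kernel;
2. extra AT probability mass (`at_bias`, default 0.15) in the central ±30
   bases, which raises local breathing propensity and is visible to the
   physics view.

Negatives are uniform background.  The central AT excess of positives over
negatives then equals `at_bias` by construction (global composition matching
was deliberately not applied, so that the generator's documented bias is the
measured one).  Setting `at_bias = 0` and mutation rate 1 yields the null
configuration: positives statistically identical to negatives, driving every
downstream classifier to auROC ≈ 0.5.

What passing on this generator does **not** show: real promoters carry many
correlated signals (CpG islands, Inr/DPE elements, nucleosome positioning),
real negatives are gene-body sequence rather than uniform noise, and real
TSS labels are noisy.  Synthetic results validate the machinery — the
physics, the kernels, the protocol — not genomic performance; headline
numbers on the public ARTS/dbTSS benchmark require downloading that data and
running the same pipeline on it.

## Problem sizes

The default experiment configuration follows the benchmark-shaped study:
200 positives / 2000 negatives for training, a 100/1000 held-out split,
one temperature per run in the acceptance protocol (345 K), 5 undersampling
replicates, 10-fold CV, quadrature at 96 points.  A full signal experiment
completes in ≈ 5 minutes on one core; oracle comparisons (dense 2-D/3-D
quadrature) run in seconds.

## Known limitations

* Equilibrium statistics only — no Langevin/molecular dynamics, no kinetics.
* The PBD parameterisation is taken as given; no refitting to melting curves.
* Homopolymer poly(AT) at 345 K is close to its melting regime (mean opening
  ≈ 0.98), so AT-vs-GC ordering assertions there probe saturated as well as
  linear response.
* WDS position weights and shift ranges, and the undersampling replicate
  scheme behind ± intervals, are under-specified upstream; the defaults here
  (unit weights, constant shift, 5 replicates) are the simplest consistent
  choices.
* The default synthetic motif (6-mer, 15 % per-position mutation) makes the
  sequence view easier than real promoter data, where the best sequence-only
  classifiers sit well below perfect ranking; on synthetic data the hybrid
  therefore tracks rather than beats the sequence kernel.  Users probing
  hybrid gains should raise the motif mutation rate or lower `at_bias` to
  rebalance the two channels.
* MKL weight *learning* is out of scope; the hybrid uses fixed weights.
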