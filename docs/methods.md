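# Methods

## Model

`perinv` implements a stationary-renewal (counting) model of crossover
interference for chromosomes carrying a heterozygous pericentric
inversion.  Dummy events and chiasmata together form a homogeneous
Poisson process on the genetic map; each pair of successive chiasmata is
separated by an independent γ-distributed number of dummy events, so the
expected number of events in an interval of heterokaryotype length l′
Morgans is λ = 2 l′ Σ_s (s+1) γ_s (the factor 2 converts gamete Morgans
to bivalent chiasma counts).  The *phase* at a point — dummy events until
the next chiasma — is a Markov chain across intervals, with transition
matrices

* H[i,j]: no chiasma in the interval; i − j Poisson events, all dummy;
* G[i,j] = Σ_t b_t Σ_{s≥j} γ_s Pois(i+1+t+s−j; λ): at least one chiasma,
  where b_t (b₀ = 1, b_t = Σ_{a<t} b_a γ_{t−1−a}) counts renewal paths of
  t events between the first and last chiasma of the interval.

With no chromatid interference a chiasma reaches the sampled chromatid
with probability ½, and P(odd transmitted | c ≥ 1 chiasmata) = ½ exactly,
giving the interval matrices M(r=1) = ½G, M(r=0) = ½G + H and the chain
rule Pr(r) = Ω (∏ M_k) 1ᵀ.  The gamma-model parametrisation puts all γ
mass on ⌊q⌋ and ⌊q⌋+1; q = 0 is the no-interference (Haldane) limit, and
the stationary phase law is π_i = Σ_{s≥i} γ_s / Σ_s (s+1) γ_s.

Because the interference signal is blocked by the centromere and (by
hypothesis) at the breakpoints, the chromosome splits into four
independent regions evaluated outward/inward from the adjoining
breakpoint, each started with the phase law Ω of the hypothesis under
test (H0: Ω = π; H1: Ω = γ; H2: Ω from its own strength q_b).  A gamete
is balanced iff its crossover parity is equal in the two inner regions;
marker-pattern probabilities among surviving offspring are renormalised
over balanced outcomes.  Sterility has the closed form
ζ = p₁ + p₂ − 2p₁p₂ with p_k = ½(1 − Σ_s Ω_s P(Pois(λ_k) ≤ s)) for the
two inner regions (λ_k from I′ρ and I′(1−ρ)).

Out of scope by design: two-pathway chiasma mixtures, obligate chiasma,
chromatid interference, paracentric inversions (where the two breakpoint
interference fields meet mid-inversion), and explicit modelling of
negative pericentromeric interference — the latter is detected only
indirectly as fitted map inflation d_k = l′_k/l_k > 1 of the interval
holding both a breakpoint and the centromere.

## Numerical choices

* **Renewal-sum truncation.**  G's infinite t-sum is truncated at the
  first t where the Poisson tail P(X > t) < tol (default 1e-12): at step
  t the smallest count still to be added is t+1 and all coefficients are
  ≤ 1, so the tail bounds the neglected mass.  A hard cap
  t ≤ 10(m+1) + λ + 10√λ turns non-convergence into an explicit error.
  Tails are computed by reverse cumulative summation of the pmf vector;
  the naive 1 − cumsum cancels catastrophically below ~1e-12.
* **Phase support.**  m is fixed per analysis at ⌈q_max⌉ + 1 with the
  search bound q_max = 30, so gamma vectors are zero-padded to a common
  support and matrices stay conformable across hypotheses.
* **Linear-space probabilities.**  Matrices are small (≤ 32×32) and well
  scaled; the likelihood sums logs of pattern probabilities, flooring
  each at 1e-300.
* **Splits.**  Only one genetic length is fitted per marker interval;
  when a breakpoint or centromere falls strictly inside an interval the
  length is apportioned to the sub-pieces by fixed layout fractions
  (default ½, or thirds for a triple split).  These fractions are data,
  not parameters — they are exposed in the layout file for sensitivity
  analysis.
* **Outer regions** are truncated at the terminal markers: events beyond
  the outermost marker are unobservable and marginalise out through the
  all-ones terminal vector.
* **Optimisation.**  Nelder-Mead on transformed parameters (log lengths,
  logistic map of strengths onto [0, q_max]), objective tolerance 1e-8,
  best of n_restarts random starts (ties keep the first).  Starting
  lengths are Haldane-inverted observed recombinant fractions jittered by
  U[0.5, 2]; strengths start from U[0, 10].  Candidate lengths above
  5 Morgans per interval are rejected as out of domain.  Estimates within
  1% of q_max are flagged as boundary solutions.
* **Bootstrap.**  Parametric: multinomial resamples of size N from the
  fitted viable-pattern law, each refitted; resample b uses seed + b.
  "Discarding the most extreme 5%" is read two-sided: the 95% interval is
  the 2.5%/97.5% quantile pair of the resample estimates (flagged in the
  output).  Failed refits are dropped, with a warning above 5% loss.
* **lnL convention.**  The multinomial coefficient is omitted throughout;
  ΔAIC, the LRT statistic and all estimates are invariant to it.

## Identifiability notes

* The sterility surface depends on Ω only through the two inner-region
  recombination probabilities, so the H2 sterility fit has a ridge of
  global optima with LS equal to the H1 optimum; q_b is not separately
  identified by sterility data and the results object says so.
* Layouts whose inner regions are wholly contained in one marker interval
  (both breakpoints at the boundaries of the centromere interval) make
  that interval's length unidentifiable: its observable marker bit is
  forced to 0 among survivors and the four regions are independent.  The
  bundled study layouts do not have this geometry.
* At realistic sample sizes (thousands of offspring) the likelihood is
  quite flat in q jointly with the centromere-interval lengths; point
  estimates of q scatter visibly around the truth while the fitted
  pattern distribution is recovered to total-variation distance < 0.02.
  This is a property of the design, not the optimiser.
* Under strong interference (q ≈ 9) the apportioning of map length
  between the two intervals flanking a breakpoint is nearly
  unidentifiable at a few thousand offspring: chiasmata close to the
  breakpoint are rare, so the refit may move most of the length to one
  flanking interval at negligible likelihood cost.  Totals, q and the
  distal map still recover.
* The built-in scenarios place breakpoints and the centromere at the
  default split fractions (½, or thirds), because the true within-interval
  positions are not recoverable from the published tables.  The amount of
  H0-vs-H1 information in a cross is sensitive to these placements: the
  reconstructed 269 geometry discriminates the hypotheses strongly, the
  reconstructed 190 geometry barely at all.  Synthetic-scenario AIC
  comparisons therefore demonstrate the machinery, not the published
  effect sizes, and the script runs the full three-hypothesis comparison
  on the 269 scenario.

## Simulator

The Monte-Carlo simulator works directly in event space: chiasma
positions on the cumulative-λ axis are partial sums of Erlang gaps
(Ω-draw + 1 exponentials to the first chiasma, γ-draw + 1 between
chiasmata), binned by subinterval, then thinned binomially with
probability ½ per chiasma.  The four regions are simulated independently
and viability is decided by the inner parity rule; synthetic pattern
datasets use rejection sampling on viability, whose acceptance rate
equals 1 − ζ of the inner regions (a free cross-check).  Every analytic
probability in the package (pattern laws, viable-conditioned laws, ζ) is
tested against this simulator at 10⁶ gametes within binomial standard
errors.

What the generator emulates: multinomial sampling of viable-offspring
marker patterns, and sterility panels on the model surface with truncated
Gaussian observation noise.  What it does not emulate: viability or
scoring artefacts beyond the unbalanced-gamete rule, per-inversion
variation in chiasma suppression, position-dependent (pericentromeric)
negative interference, and phenotype-to-gamete ambiguity in real crosses.
Passing tests therefore demonstrate internal correctness of the model and
inference stack, not the adequacy of the model for any particular real
dataset.

## Study scenarios and problem sizes

`perinv.scenarios` encodes the three In(3LR) inversion crosses: the
marker map ve…ca (7 intervals, centromere in th-cu), each inversion's
breakpoint placements, the published H1 parameter regime (q = 2.92, 8.57,
3.92; the fitted heterokaryotype maps), and sample sizes 3100/4100/5300
chosen so that simulated log-likelihood magnitudes match the published
analyses.  The sterility panel generator draws 30 inversions with
I ~ U(0.1, 1.1) Morgans and ρ ~ U(0.15, 0.85), observes the H1 surface at
q = 3.72, d_I = 0.78, and adds Gaussian noise with sd 0.056 — the RMS
residual implied by an LS of ≈ 0.096 over 30 inversions.

The default test and acceptance runs use reduced problem sizes chosen as
a deliberate compute/precision trade-off: 8 random restarts for
simulation refits (100 remains the library default and is recommended for
real analyses), 20 bootstrap resamples × 2 restarts for the reduced-scale
interval check, and 10⁶-gamete simulator comparisons.

## Regime orderings

At q = 4 the three regimes order as ζ_H1 < ζ_none < ζ_H0 (and likewise
for the three-locus recombination rate, with H0 highest) for moderate
inversion lengths; all regimes saturate at ζ = ½ as I′ grows, and the
middle comparison can invert beyond I′ ≈ 0.8–1.2 Morgans depending on ρ.
ζ_H1 ≤ ζ_H0 holds everywhere, ζ(ρ) = ζ(1−ρ), and ζ ≤ ½ always.
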