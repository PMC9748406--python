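# Methods

## Model

`admixsmc` infers the time of the most recent population admixture event
from the binned heterozygosity track of a single diploid genome, together
with the quantities a PSMC-style analysis yields anyway: the scaled per-bin
mutation and recombination rates and a piecewise-constant history of
relative effective population size.

The genome is summarized as one symbol per 100-bp bin: heterozygous,
homozygous, or missing. A hidden Markov model runs along the bins. The
hidden state is the discretized time to the most recent common ancestor
(TMRCA) of the two alleles; coalescent time (units of 2·N0 generations) is
cut into n = 64 atomic intervals with log-uniform boundaries
b_i = 0.1·(exp((i/n)·ln(1 + 10·t_max)) − 1), t_max = 15, and the intervals
are tied into 28 free-parameter groups by the standard "4+25*2+4+6"
pattern. Each interval is represented by its conditional mean coalescent
time; the last, unbounded interval by its left edge plus one.

Emissions are the usual binned-heterozygosity probabilities
e(HET | t) = 1 − exp(−θt), e(HOM | t) = exp(−θt), e(MISSING | t) = 1, with
θ the scaled mutation rate per bin.

Transitions mix a self-transition with a recombination kernel,

    p(t | s) = (1 − e^{−ρs}) q′(t | s) + e^{−ρs} δ(t, s),

where ρ is the scaled per-bin recombination rate, s the representative time
of the current state, and δ the Kronecker delta on interval indices.

### Admixture-aware kernel

Two populations P1 and P2 with relative sizes λ_a(t) and λ_b(t) merge,
looking backwards, at time t_a. The relevant size is λ′(t) = λ_a(t) for
t > t_a and λ_a(t) + λ_b(t) for t ≤ t_a. Because only the sum is
observable below t_a, λ_b is reduced to a single scalar multiple,
λ_b = c·λ_a ("admix ratio" c; a merge of populations at size ratio r : 1
corresponds to c = 1/r). t_a is restricted to grid boundaries.

Conditional on a recombination event, the single-population kernel is

    q(t | s) = (1/λ(t)) ∫₀^{min(s,t)} (1/s) · exp(−∫_u^t dv/λ(v)) du ,

and the admixture-aware kernel q′ splits by where the new coalescence
lands:

* t > t_a — single population: q with λ_a (the hazard uses λ_a throughout,
  including below t_a);
* t ≤ t_a < s — the floating lineage may coalesce in either not-yet-merged
  population: q_a + q_b − 2·q_a·q_b, with q_a, q_b each evaluated with
  their own population size in both prefactor and hazard;
* t, s ≤ t_a — merged population: q with λ′ = (1 + c)·λ_a used
  consistently.

Discretized rows of q′ are renormalized before the mixture (the continuous
kernel integrates to one only in exact arithmetic, and the middle case is
not exactly normalized). The chain starts from the coalescent prior under
λ′, π_i = e^{−H(b_i)} − e^{−H(b_{i+1})} with H the cumulative hazard.

All integrals are evaluated in closed form per grid interval. With
g_k = e^{−H(b_k)}·∫₀^{b_k} e^{H(u)} du, the recurrence
g_{k+1} = g_k·e^{−ΔH_k} + λ_k·(1 − e^{−ΔH_k}) avoids overflow for any
λ ∈ [1e−3, 1e3]; every matrix entry is a short expression in g, interval
widths, and differences of H exponentiated with non-positive argument. An
independent numerical-quadrature oracle checks these closed forms in the
test suite.

Two structural properties of this kernel are worth recording:

* **It is not in detailed balance with its own prior.** Recent-TMRCA
  states are nearly absorbing (the per-bin recombination probability
  1 − e^{−ρs} vanishes with s), and the discrete chain's stationary law
  puts several times more mass on recent states than the coalescent prior
  does. The simulator calibration test therefore compares empirical
  heterozygosity against the exact average marginal (π Pˡ averaged over
  bins), not against π alone.
* **The middle case scales with 1/λ_b.** The cross-population term makes
  transitions into the merged epoch *stronger* when the admixed population
  is *smaller* (larger r, smaller c). Under self-consistent simulation
  this makes asymmetric merges easier to date than symmetric ones — see
  "Known limitations".

## Estimation

Parameters: θ, ρ, the 28 grouped λ_a values, c, and t_a. Estimation is
Baum–Welch EM with a staged treatment of the admixture pair, for a reason
that is itself a finding about the model: **(t_a, c) and a free grouped
size history are nearly collinear.** Once λ_a has adapted by EM to data
generated with an admixture event, the data likelihood is flat in (t_a, c)
to within a few log-units even at tens of megabases — a converged
single-population fit mimics the admixture kernel almost perfectly. Any
profile of (t_a, c) computed after the size history has converged (and any
profile computed on the expected complete-data log-likelihood, which is
even flatter) is blind. The admixture signature is only visible while the
size history is still uninformed. The fit is therefore staged:

1. **Warm-up** (2 iterations): EM updates of θ and ρ only, size history
   held flat at λ_a ≡ 1; the admixture time starts at 0.
2. **Admixture scan**: the data log-likelihood (one forward pass per
   candidate) is profiled over every boundary t_a and a ratio ladder
   c ∈ {1/4, 1/3, 1/2, 1}, against the flat-λ base model. The scan walks
   boundaries in increasing order and stops eight boundaries past the best
   candidate (the gain curve is unimodal in practice). The best candidate
   is accepted only if its gain exceeds an activation threshold of 2.5
   log-units, calibrated once on ten single-population pilot simulations
   at 10 Mb (maximal spurious gain observed: 1.7). The spurious gain is
   the maximum of a few dozen strongly correlated likelihood-ratio
   statistics and does not grow with sequence length, whereas a real
   signal grows linearly, so the threshold becomes conservative at larger
   scales. An accepted c is refined by a bounded one-dimensional search.
3. **Polish**: full EM on θ, ρ and the grouped λ_a with (t_a, c) frozen,
   until the relative log-likelihood change falls below `tol` or
   `max_iter` is reached.

Every M-step coordinate update (bounded Brent searches in log-space;
λ ∈ [1e−3, 1e3]) is accepted only on strict improvement of the expected
complete-data log-likelihood, and the scan only ever raises the data
likelihood, so the recorded log-likelihood trace is non-decreasing up to
numerical tolerance. θ is initialized from the observed heterozygous
fraction h as h/(1 − h); ρ at θ/5.

Physical units: N0 = θ/(4·μ·bin), years = t · 2·N0 · generation time. The
reported admixture time in years uses the *estimated* N0, as it would on
real data.

## Simulator

Sequences are generated from the model's own discrete kernel: the first
bin's TMRCA is drawn from the coalescent prior under λ′, subsequent bins
follow the one-bin transition matrix, and emissions are Bernoulli in the
state's heterozygosity probability. The true admixture time is inserted as
an extra grid boundary, so the generating demography changes size exactly
at the requested time; the fitted grid stays the standard one, which is
what produces the characteristic horizontal steps in estimated times.
Defaults are the human-analog study conditions: N0 = 1e5, 5
years/generation, μ = 2.5e-8, rec = 5e-9 per site and generation, 100-bp
bins (θ = 1.0 and ρ = 0.2 per bin).

Self-consistent simulation is deliberate: it isolates estimator behavior
from model misspecification, and it requires no external dependencies. It
does *not* emulate features of real data: hotspot recombination, variable
coverage and missingness, genotyping error, or the ways a physical
ancestral-recombination-graph process differs from this kernel (see below).
Passing recovery tests therefore demonstrates internal consistency of the
estimator, not field performance on real genomes.

## Study sizes and numerical choices

Desk-scale runs use 10 Mb per replicate (1e5 bins), EM capped at 10
iterations with relative tolerance 1e-5, and a handful of replicates per
grid cell; these sizes are the package's reduced-scale study conditions
and are what the bundled acceptance script and test suite run. The
forward/backward recursions are scaled-probability numba kernels; expected
transition counts use a single matrix product per sequence. Ties in
posterior decoding break toward the more recent interval. Degenerate
inputs: all-missing sequences have log-likelihood 0 and leave θ untouched
in the M-step; zero observed heterozygosity drives θ to its configured
lower bound.

## Known limitations

* **Identifiability at desk scale.** At 10 Mb the symmetric-merge (1:1)
  scan signal is only ~2–8 log-units against a noise floor of ~0–2, and
  the likelihood over neighboring boundaries is shallow; estimates
  scatter by one to two grid intervals (±10–25 kya) and occasionally the
  event is not detected at all. Tens of megabases per genome are the
  minimum for reliable symmetric-merge dating under this model; the
  original study design assumed genome-scale input.
* **Ratio ordering under self-consistent simulation.** Because of the
  1/λ_b scaling in the cross-population term, simulations *from the
  model's own kernel* make 4:1 merges easier to date than 1:1 merges —
  the reverse of what physical coalescent data produce, where a small
  admixed population leaves a weak signal. Accuracy comparisons across
  ratios from self-consistent simulations should be read with this in
  mind.
* One admixture event, two populations, equal θ and ρ across populations;
  no joint modeling of multiple individuals; no bootstrap intervals.
* The admixture time is reported on the grid (horizontal steps); its
  resolution near 20–80 kya is the local boundary spacing, ~10–15 kya at
  the default discretization and human-analog scaling.
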