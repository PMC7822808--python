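# Methods

## Model and state spaces

`cwfdual` works with `L` loci carrying `M_l ≥ 2` alleles each
(`MTOT = Σ M_l`).  A frequency state is a length-`MTOT` concatenation of
per-locus simplex vectors; a dual state is a nonnegative integer vector with
the same block structure.  The diffusion's coefficients are

* mutation drift `μ_i^(l) = Σ_j [u_ji x_j − u_ij x_i]` with
  `u_ij^(l) = (θ_l/2) P_ij^(l)`;
* selection drift `g = D(x)(h + Jx)` with the Wright–Fisher covariance
  blocks `d_ij^(l) = x_i (δ_ij − x_j)`;
* potential `V(x) = x'h + ½ x'Jx`; the fitness of haplotype `(i_1,…,i_L)`
  is `1 + Σ_l h_{i_l} + Σ_{l<r} J^{(lr)}_{i_l i_r}`, so the mean fitness
  under the product law of `x` is exactly `1 + V(x)` (a tested identity).

`h` and `J` are required nonnegative, `J` symmetric with zero diagonal
blocks, each `P^(l)` row-stochastic to 1e−12.  Negative selection parameters
are rejected rather than extrapolated: the dual branching rates would lose
their interpretation as nonnegative jump intensities.

Mutation regimes are all-or-none: either every `θ_l > 0` (with the
parent-independent case, `u_ij = u_j`, unlocking the explicit stationary
density) or every `θ_l = 0`.  Mixed regimes are rejected by the kernel
factory because no closed or integral form of the duality kernel covers
them.

## The dual process and a corrected rate constant

The dual is a pure jump process on count vectors with four families:
coalescence `n_i(n_i−1)/2 · k(n−e_i)/k(n)`, mutation
`n_i u_ji · k(n−e_i+e_j)/k(n)`, single-branching
`(n^(l) Σ_{k≠j} h_k + Σ_{r≠l} Σ_i n_i^(r) J_ji) · k(n+e_j)/k(n)`, and
double-branching at loci `l < r`

    (n^(l) + n^(r)) · ( Σ_{(k,m) ≠ (j,h)} J^{(lr)}_km ) · k(n+e_j+e_h)/k(n).

The double-branching selection weight sums `J` over **every allele pair
except the one being added**, i.e. `ΣJ − J_jh`.  This was fixed against a
symbolic (sympy) expansion of the generator applied to the duality monomial:
writing `−x_k x_m = −1 + Σ_{j,h}(1 − δ_jk δ_hm) x_j x_h` on the simplex
leaves exactly the coefficient `ΣJ − J_jh` on the degree-(+2) monomials.
The commonly seen "row-and-column" exclusion `Σ_{k≠j} Σ_{m≠h} J_km`
coincides with it for 2×2 diagonal coupling matrices (the standard worked
example) but differs — and breaks the generator identity — for general
couplings.  The package's test suite checks the identity against an
independent finite-difference oracle and at machine precision for the
explicit no-mutation rates.

The diagonal entry `q(n,n)` is evaluated from its explicit closed form
(kernel-free); the row-sum-zero identity `Σ q(n,·) = 0` is then a genuine
verification of the kernel, not a tautology.  Without mutation the identity
additionally requires every locus to carry at least one lineage; a state
with an empty locus cannot branch there (the factor `n_j`), while the
closed-form diagonal still counts that outflow.  The explicit no-mutation
table therefore uses minus-the-total as its diagonal, and the equality with
the closed form is asserted only on fully occupied states.

Coalescence out of `n_i = 1` deserves a note: the Theorem-form factor
`n_i(n_i−1)/2` vanishes there, but under the no-mutation Beta-product
kernel the ratio `k(n−e_i)/k(n)` simultaneously diverges (an allele type is
lost, `Γ(0)`), and the product has the finite limit `n_i(n^(l)−1)/2` — the
explicit no-mutation rate.  `rates_theorem1` evaluates this removable
singularity in the limit when the kernel declares itself Beta-product, so
the general and explicit tables coincide entrywise.  The duality function
is identically zero at states that have lost an allele type (`1/k = 0`
through the same `Γ(0)`), which is what makes the extinction jumps
invisible in moment space yet present in the process.

## Kernel backends

All dual rates consume `k` only through ratios, so every backend stores
`log k(n)` in a per-kernel cache (bit-identical on repeated evaluation).

* **no_mutation** — `k(n) = Π_l B(n^(l))`, `B(n) = Π Γ(n_i)/Γ(Σn_i)`, via
  `gammaln`; ratios are evaluated as exact integer Gamma-ratio products
  (Python rationals), which remain meaningful at boundary counts (ratio 0
  when adding an absent type, +inf when removing the last lineage of a
  type).  `k(0)` is not normalised to 1; counts with zero entries are
  rejected by `k` itself.
* **pim_quadrature** — `k(n) = (1/Z)∫ Π x^n π e^{2V}`.  For all-two-allele
  models the integral is computed by tensorised Gauss–Jacobi quadrature:
  the Jacobi weight absorbs the Dirichlet boundary factors exactly and the
  remaining integrand `e^{2V}` is entire, so convergence is spectral.  The
  default order is 48 nodes per axis, and every value is accepted only if
  it agrees with the order-64 result to the kernel tolerance (default
  1e−11), otherwise the evaluation raises.  For loci with `M_l ≥ 3` the
  backend switches to Dirichlet importance sampling (`X ~ Π Dir(2u)`,
  weight `e^{2V}`, default 2·10⁵ draws on a fixed seeded stream) and
  reports a delta-method standard error via `se(n)`.
* **kummer_1locus** — one locus, two alleles, PIM:
  `k(n) ∝ B(n₁+2u₁, n₂+2u₂)·₁F₁(n₁+2u₁, n₁+n₂+2u₁+2u₂, 2(h₁−h₂))`.
  `₁F₁` is `scipy.special.hyp1f1`; negative arguments go through the Kummer
  transformation `₁F₁(a,b,z) = e^z ₁F₁(b−a,b,−z)` so the series summed is
  positive-term.
* **series_2x2** — two loci, two alleles, `h = 0`, diagonal coupling
  `J^{(12)} = diag(J1, J2)`: `k(n) = I(n+2u)/I(2u)` with the coupling
  integral `I` expanded as an outer Pochhammer/power series with inner
  binomial sums of Beta·Kummer factors.  Every inner `₁F₁` with negative
  argument is transformed as above (which also cancels the `e^{2J₂}`
  prefactor), leaving the explicit alternating structure as the only sign
  oscillation.  Because terms alternate, truncation stops only after 20
  consecutive outer terms each contribute less than `tol` (default 1e−12)
  times the running sum, with a hard cap of 500 terms; non-convergence
  raises with the partial sums attached, rather than assuming the series
  converges for all couplings.  `J2 = 0` uses the separable-limit expansion
  `Σ (2J1)^n/n! B(a₁+n,a₂)B(b₁+n,b₂)`, whose first term alone is exact
  when `J1 = 0`.  Beta/Kummer factors are memoised globally; they recur
  heavily across `k` evaluations during Gillespie simulation.

Backends agree pairwise to better than 1e−6 (tested, typically ~1e−13)
wherever their domains overlap.  `make_kernel(spec)` picks the cheapest
applicable backend.

The normalising constant `Z` itself is available through the one-locus
Kummer closed form, the 2×2 series, Gauss–Jacobi quadrature, or Dirichlet
importance sampling (`Z = Π B(2u^(l)) · E_Dir[e^{2V}]`).

## Forward simulation

Euler–Maruyama with step `dt` (default 1e−3 diffusion-time units — an
empirical weak-error/cost balance on two-allele test models).  The per-locus
noise uses the multinomial-covariance factor
`B_ij = δ_ij √x_i − x_i √x_j`, which satisfies `BBᵀ = d` on the simplex
without a Cholesky factorisation that would fail at PSD-degenerate boundary
states.  After each step, negative coordinates are clipped to zero and each
locus block renormalised to sum one; this projection is applied uniformly
(including the `θ = 0` absorbing-boundary case, where vertices are exact
fixed points of the scheme).  Paths are vectorised across replicates and
reproducible from an integer seed.

The generator is applied to duality monomials analytically (the partial
derivatives of `Π x^n` are closed-form); no numerical differentiation is
used anywhere except as an independent oracle in the tests.

## Dual simulation

Gillespie's algorithm: exponential holding times with parameter equal to
the total outflow rate, jump selection by a single uniform draw against the
cumulative rates in a canonical enumeration order (coalescence < mutation <
single < double; locus-major, allele-minor), making paths reproducible.
Rate tables and kernel values are cached per visited state.  Branching is
at most linear and coalescence at least quadratic in the total count
(tested), so the process does not explode; nevertheless an operational
guard aborts any path whose total count exceeds `10‖n₀‖₁ + 50` (the path is
flagged and Monte-Carlo entries using it are marked inconclusive).  A
formal bounding chain is not implemented.

## Duality verification

* **Generator level.**  The residual
  `|LF(·,n)(x) − Σ_m q(n,m)[F(x,m) − F(x,n)]| / max(1, |LF|)` is zero in
  exact arithmetic iff the kernel is the true stationary-moment function,
  so it measures kernel accuracy: observed ≤1e−12 for the explicit
  no-mutation algebra, ~1e−13 for the Kummer and series kernels, ≤1e−8 for
  quadrature.
* **Process level.**  Both sides of
  `E[F(X(t),n)|x] = E[F(x,N(t))|n]` are estimated by Monte Carlo (forward
  Euler paths vs. Gillespie paths) and compared with a two-sample z-score
  with pooled standard errors; the pass surface is `|z| ≤ 3`.  Replicate
  counts (10⁴ per side at the checked horizons `t ∈ {0.1, 0.5}`) are chosen
  so Monte-Carlo error dominates the Euler discretisation bias; the forward
  side inherits that bias and the tests verify it stays inside the band
  rather than removing it.  The no-mutation moment form with Beta weights
  `Π B(n^(l))/B(N^(l)(t))` is checked the same way (weight zero once a type
  is lost), and requires all starting counts positive.

## Stationary sampler

A vectorised random-walk Metropolis chain on the reduced coordinates (last
frequency per locus dropped): 64 parallel walkers, Gaussian proposals of
scale 0.12, burn-in 1500 sweeps, thinning 5, all seeded.  A warning is
issued if the mean acceptance rate leaves (0.05, 0.95).  Thinned draws
retain some autocorrelation, so moment tests use 3 standard errors computed
at a conservative effective sample size (one tenth of the nominal draws)
rather than pretending independence.

## What the synthetic models do and do not show

Random fixture models draw `h`, `J` uniformly on `(0, magnitude)`
(symmetrised, zero diagonal blocks) and PIM rates uniformly on
`(0.2, 1.0)`; the packaged canonical two-locus model uses the standard
illustration parameters `u = 0.8`, `J1 = J2 ∈ {0, 2}`.  These exercise the
full algebraic structure (multi-allele loci, non-diagonal couplings,
selection–mutation interaction) at desk scale — `L ≤ 3`, `M_l ≤ 3`, sample
sizes ≲ 8, chosen so the exhaustive enumeration sweeps complete in seconds.
Passing tests certify the mathematical identities and the correctness of
the simulators at these scales; they say nothing about inference on real
sequence data (no data model, no likelihood machinery is included), about
parent-dependent mutation kernels (no closed form exists; only the
no-mutation and PIM regimes are covered), or about the tail behaviour of
the series backend for couplings far beyond the tested `J ≲ 3`.

## Known limitations

* No diploid models and no finite recombination rate: free recombination is
  a structural assumption, and inter-locus coupling is purely selective.
* The dual is the block-counting process only; lineage identities and the
  true/virtual branch distinction of a full ancestral graph are not
  represented.
* Transition-density expansions built on the duality (sample inversion) are
  out of scope.
* The quadrature backend requires two alleles per locus for deterministic
  error control; larger loci fall back to Monte Carlo with reported SEs.
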