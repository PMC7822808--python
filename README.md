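# cwfdual

Forward and backward views of multi-locus allele-frequency evolution under
pairwise inter-locus selection, and the numerical machinery to verify that
the two views are dual to each other.

## The model

In populations with very high homologous recombination (many bacteria, e.g.
*Streptococcus pneumoniae*), loci evolve almost independently and the
residual statistical coupling between loci is attributable to selection
rather than linkage.  `cwfdual` implements the corresponding *coupled
Wright–Fisher diffusion*: for `L` loci with `M_l` alleles each, the
concatenated frequency vector `X(t)` on a product of simplices solves

    dX = mu(X) dt + D(X) grad V(X) dt + D(X)^{1/2} dW,

where `mu` is the per-locus mutation drift (rates `u_ij = (theta_l/2) P_ij`),
`D` is the block-diagonal Wright–Fisher covariance
`d_ij = x_i (delta_ij − x_j)`, and the quadratic potential

    V(x) = x' h + (1/2) x' J x

carries one-locus selection (`h ≥ 0`) and pairwise inter-locus selection
(`J ≥ 0`, symmetric, zero diagonal blocks).  Under parent-independent
mutation (PIM) the stationary density is `p = pi e^{2V} / Z` with `pi` a
product of Dirichlet kernels.

The ancestral (dual) view is an integer-valued block-counting jump process
`N(t)` — one ancestral selection graph per locus, coupled through selection —
with four jump families: coalescence, mutation, single-branching and
double-branching (simultaneous virtual parents at two loci).  Every rate is
an explicit combinatorial factor times a ratio of the duality kernel

    k(n) = E[ prod_{l,i} (X~_i)^{n_i} ]   (stationary moment; PIM case)
    k(n) = prod_l B(n^(l))                (Beta products; no mutation)

and the two processes satisfy the moment duality

    E[F(X(t), n) | X(0) = x] = E[F(x, N(t)) | N(0) = n],
    F(x, n) = prod x_i^{n_i} / k(n).

The package provides: validated model specifications; the diffusion's drift,
covariance, generator action on monomials, and an Euler–Maruyama simulator;
four interchangeable kernel backends (no-mutation closed form, tensorised
Gauss–Jacobi quadrature / Dirichlet importance sampling, one-locus Kummer
`1F1` closed form, and the two-locus two-allele Beta–Kummer series); the
dual-process rate tables and a Gillespie simulator; a stationary-density
Metropolis sampler; and deterministic plus Monte-Carlo duality checks.

## Worked example

The packaged canonical model has two loci, two alleles each, no one-locus
selection, diagonal pairwise coupling `J1 = J2 = 2` and PIM rates
`u = 0.8` for every allele:

```python
>>> import cwfdual as cw
>>> spec = cw.fig1_model(coupled=True)
>>> cw.fitness_coefficient(spec, (0, 0)), cw.fitness_coefficient(spec, (0, 1))
(3.0, 1.0)
```

Haplotypes 11 and 22 are the fit combinations.  The duality kernel at a
two-lineage sample carrying one type-1 lineage at each locus:

```python
>>> kernel = cw.make_kernel(spec)        # Beta-Kummer series backend
>>> kernel.k([1, 0, 1, 0])
0.27949468356604884
```

i.e. the stationary probability that two independently drawn alleles (one
per locus) are both of type 1 is about 0.279 — above the 0.25 of the
uncoupled model, because selection pushes mass toward the (1,1)/(2,2)
corners.  The dual rate table out of that sample state:

```python
>>> table = cw.rates_theorem1(spec, [1, 0, 1, 0], kernel)
>>> for j in table.jumps: print(j.kind, j.target, round(j.rate, 4))
mutation (0, 1, 1, 0) 0.6312
mutation (1, 0, 0, 1) 0.6312
single_branching (2, 0, 1, 0) 1.3435
single_branching (1, 0, 2, 0) 1.3435
double_branching (2, 0, 2, 0) 1.8616
double_branching (2, 0, 1, 1) 1.6507
double_branching (1, 1, 2, 0) 1.6507
double_branching (1, 1, 1, 1) 0.4877
>>> round(table.diagonal, 4)             # rates + diagonal sum to zero
-9.6
```

(No coalescence — the two lineages sit at different loci — and no
single-branching toward the absent allele 2, because with `h = 0` its rate
carries the factor `n_2^(r) J_21 = 0` under the diagonal coupling.)

A two-sided Monte-Carlo check of the duality itself (forward diffusion paths
versus backward Gillespie paths):

```python
>>> r = cw.mc_duality_check(spec, [0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0],
...                         t=0.1, reps=10_000, seed=101, kernel=kernel)
>>> round(r.forward_mean, 3), round(r.dual_mean, 3), abs(r.z) <= 3
(0.905, 0.908, True)
```

Both sides estimate the same expectation `E[F]`; the two-sample z-score is
within the 3-sigma equality band.

A command-line interface mirrors the library (`cwfdual kfun`, `rates`,
`simulate-forward`, `simulate-dual`, `check-duality`, `density-grid`,
`make-model`); all commands take explicit `--seed` values.

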