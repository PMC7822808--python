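"""Machine checks of the duality between the diffusion and the jump process.

Two layers of verification:

* a deterministic *generator* check -- the generator applied to the monomial
  duality function must reproduce the jump-rate form exactly, so the relative
  residual measures only the accuracy of the kernel ``k``;
* a stochastic *process* check -- Monte-Carlo estimates of
  ``E[F(X(t), n) | X(0) = x]`` (forward paths) and
  ``E[F(x, N(t)) | N(0) = n]`` (dual paths) must agree within sampling error;
  a two-sample z-score with a 3-sigma pass threshold is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .diffusion import apply_generator_to_monomial, simulate_forward_final
from .dual import rates_corollary1, rates_theorem1, simulate_dual_final
from .kernels import KKernel
from .model import ModelSpec, validate_frequency_state, validate_sample_counts

__all__ = [
    "generator_duality_residual",
    "mc_duality_check",
    "mc_moment_duality_theta0",
    "MCDualityResult",
    "DualityReport",
]


def generator_duality_residual(spec: ModelSpec, x, n, kernel: KKernel) -> float:
    """Relative residual of the generator identity at ``(x, n)``.

    ``| L F(., n)(x) - sum_{m != n} q(n, m) [F(x, m) - F(x, n)] | / max(1, |L F|)``

    with the generator applied analytically and the rates from the dual
    process (the explicit no-mutation table when theta = 0).  For exact
    kernels the residual is at the level of floating-point roundoff; for
    quadrature/series kernels it is bounded by their tolerance.
    """
    x = validate_frequency_state(spec, x)
    n = validate_sample_counts(spec, n)
    lhs = apply_generator_to_monomial(spec, x, n, kernel)
    if spec.is_no_mutation:
        table = rates_corollary1(spec, n)
    else:
        table = rates_theorem1(spec, n, kernel)
    Fn = kernel.duality_F(x, n)
    rhs = 0.0
    for jump in table.jumps:
        rhs += jump.rate * (kernel.duality_F(x, jump.target) - Fn)
    return abs(lhs - rhs) / max(1.0, abs(lhs))


@dataclass
class MCDualityResult:
    """Two-sided Monte-Carlo comparison of one duality expectation."""

    t: float
    n: tuple
    x: tuple
    forward_mean: float
    forward_se: float
    dual_mean: float
    dual_se: float
    reps: int
    dt: float
    seed: int
    n_capped: int = 0

    @property
    def z(self) -> float:
        pooled = math.hypot(self.forward_se, self.dual_se)
        if pooled == 0.0:
            return 0.0
        return (self.forward_mean - self.dual_mean) / pooled

    def passed(self, z_max: float = 3.0) -> bool:
        return self.n_capped == 0 and abs(self.z) <= z_max

    @property
    def inconclusive(self) -> bool:
        return self.n_capped > 0

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "n": list(self.n),
            "x": list(self.x),
            "forward_mean": self.forward_mean,
            "forward_se": self.forward_se,
            "dual_mean": self.dual_mean,
            "dual_se": self.dual_se,
            "z": self.z,
            "reps": self.reps,
            "dt": self.dt,
            "seed": self.seed,
            "n_capped": self.n_capped,
        }


def _mean_se(vals: np.ndarray) -> tuple[float, float]:
    return float(np.mean(vals)), float(np.std(vals, ddof=1) / math.sqrt(len(vals)))


def _monomials(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """``prod_i x_i^{n_i}`` row-wise for a batch of frequency vectors."""
    pos = n > 0
    if not np.any(pos):
        return np.ones(x.shape[0])
    xs = x[:, pos]
    out = np.where(
        np.all(xs > 0.0, axis=1),
        np.exp(np.log(np.maximum(xs, 1e-300)) @ n[pos]),
        np.prod(xs ** n[pos], axis=1),
    )
    return out


def mc_duality_check(
    spec: ModelSpec,
    x,
    n,
    t: float,
    reps: int = 10_000,
    dt: float = 1e-3,
    seed: int = 0,
    kernel: KKernel | None = None,
) -> MCDualityResult:
    """Two-sided Monte-Carlo check of ``E[F(X(t),n)|x] = E[F(x,N(t))|n]``.

    The forward side runs ``reps`` Euler-Maruyama paths and evaluates
    ``F(X(t), n)``; the dual side runs ``reps`` Gillespie paths and evaluates
    ``F(x, N(t))``.  Both sides share the duality kernel.  Exploded dual
    paths (size cap hit) are counted and render the entry inconclusive.
    """
    x = validate_frequency_state(spec, x)
    n = validate_sample_counts(spec, n)
    if kernel is None:
        from .kernels import make_kernel

        kernel = make_kernel(spec)
    if t == 0.0:
        F0 = kernel.duality_F(x, n)
        return MCDualityResult(
            t, tuple(n), tuple(x), F0, 0.0, F0, 0.0, reps, dt, seed
        )
    xt = simulate_forward_final(spec, x, t, dt=dt, seed=seed, n_paths=reps)
    fwd_vals = np.array([kernel.duality_F(row, n) for row in xt])
    nt, n_capped = simulate_dual_final(
        spec, n, t, kernel, seed=seed + 1, n_paths=reps
    )
    dual_vals = np.array([kernel.duality_F(x, row) for row in nt])
    fm, fs = _mean_se(fwd_vals)
    dm, ds = _mean_se(dual_vals)
    return MCDualityResult(
        t, tuple(n), tuple(x), fm, fs, dm, ds, reps, dt, seed, n_capped
    )


def _log_multivariate_beta(nb: np.ndarray) -> float:
    """``log B(n)`` for a positive integer block; +inf if any entry is 0."""
    if np.any(nb <= 0):
        return math.inf
    return float(np.sum(special.gammaln(nb)) - special.gammaln(nb.sum()))


def mc_moment_duality_theta0(
    spec: ModelSpec,
    x,
    n,
    t: float,
    reps: int = 10_000,
    dt: float = 1e-3,
    seed: int = 0,
) -> MCDualityResult:
    """No-mutation moment duality by two-sided Monte Carlo:

    ``E[prod X(t)^n | x]  =  E[ prod_l B(n^(l)) / B(N^(l)(t)) * prod x^{N(t)} | n ]``

    Requires theta = 0 and every ``n_i^(l) >= 1`` (the Beta weight of a
    dual state that has lost an allele type is zero -- the monomial moment
    of an extinct configuration).
    """
    if not spec.is_no_mutation:
        raise ValueError("moment duality in this form requires theta = 0")
    x = validate_frequency_state(spec, x)
    n = validate_sample_counts(spec, n)
    if np.any(n < 1):
        raise ValueError("all n_i^(l) must be >= 1 for the Beta-weighted form")
    log_Bn = sum(_log_multivariate_beta(b) for b in spec.split(n))
    if t == 0.0:
        v = float(np.prod(x**n))
        return MCDualityResult(t, tuple(n), tuple(x), v, 0.0, v, 0.0, reps, dt, seed)
    xt = simulate_forward_final(spec, x, t, dt=dt, seed=seed, n_paths=reps)
    fwd_vals = _monomials(xt, n)
    nt, n_capped = simulate_dual_final(spec, n, t, None, seed=seed + 1, n_paths=reps)
    dual_vals = np.empty(reps)
    logx = np.log(np.maximum(x, 1e-300))
    for p in range(reps):
        row = nt[p]
        log_BN = sum(_log_multivariate_beta(b) for b in spec.split(row))
        if math.isinf(log_BN):
            dual_vals[p] = 0.0
        elif np.any((row > 0) & (x == 0.0)):
            dual_vals[p] = 0.0
        else:
            dual_vals[p] = math.exp(log_Bn - log_BN + float(row @ logx))
    fm, fs = _mean_se(fwd_vals)
    dm, ds = _mean_se(dual_vals)
    return MCDualityResult(
        t, tuple(n), tuple(x), fm, fs, dm, ds, reps, dt, seed, n_capped
    )


@dataclass
class DualityReport:
    """Collected generator residuals and Monte-Carlo duality entries."""

    model_digest: str
    generator_entries: list = field(default_factory=list)
    mc_entries: list[MCDualityResult] = field(default_factory=list)
    residual_tol: float = 1e-8
    z_max: float = 3.0

    def add_generator(self, x, n, residual: float) -> None:
        self.generator_entries.append(
            {"x": list(np.asarray(x)), "n": list(np.asarray(n)), "residual": residual}
        )

    def add_mc(self, entry: MCDualityResult) -> None:
        self.mc_entries.append(entry)

    @property
    def passed(self) -> bool:
        gen_ok = all(e["residual"] <= self.residual_tol for e in self.generator_entries)
        mc_ok = all(e.passed(self.z_max) for e in self.mc_entries)
        return gen_ok and mc_ok

    def to_dict(self) -> dict:
        return {
            "model_digest": self.model_digest,
            "residual_tol": self.residual_tol,
            "z_max": self.z_max,
            "generator_entries": self.generator_entries,
            "mc_entries": [e.to_dict() for e in self.mc_entries],
            "passed": self.passed,
        }
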