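"""The duality kernel k(n), stationary density and normalising constant.

Under parent-independent mutation (PIM) the diffusion has the stationary
density ``p = (1/Z) pi(x) exp(2 V(x))`` with ``pi`` a product of Dirichlet
factors ``prod_i x_i^{2 u_i - 1}`` per locus.  The duality kernel is the
stationary monomial moment

    k(n) = E[ prod_{l,i} (X~_i^(l))^{n_i^(l)} ],

which enters every dual-process rate as a ratio.  Without mutation no such
stationary density exists and ``k`` is instead a product of multivariate Beta
functions ``k(n) = prod_l B(n^(l))`` (not normalised to ``k(0) = 1``).

Four interchangeable backends evaluate ``k``:

``no_mutation``
    closed-form Beta products (theta = 0 everywhere);
``pim_quadrature``
    direct integration of the stationary density -- tensorised adaptive
    quadrature when every locus has two alleles, Dirichlet importance
    sampling otherwise;
``kummer_1locus``
    the one-locus two-allele closed form via the confluent hypergeometric
    (Kummer) function 1F1;
``series_2x2``
    the two-locus two-allele Beta--Kummer series for the diagonal-coupling
    model (J^{(12)} = diag(J1, J2), h = 0).

All kernels cache ``log k`` per count vector and expose exact-as-possible
ratio evaluation, since the dual rates only ever consume ratios.
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import special

from .model import ModelSpec, potential, validate_sample_counts

__all__ = [
    "KKernel",
    "NoMutationKernel",
    "PIMQuadratureKernel",
    "Kummer1LocusKernel",
    "Series2x2Kernel",
    "make_kernel",
    "kummer_1f1",
    "I_series_2x2",
    "log_unnormalized_density",
    "normalising_constant",
    "sample_stationary",
    "SeriesConvergenceError",
]


class SeriesConvergenceError(RuntimeError):
    """Raised when the Beta-Kummer series fails the truncation test."""

    def __init__(self, msg, partial_sums=None):
        super().__init__(msg)
        self.partial_sums = partial_sums


@lru_cache(maxsize=200_000)
def _betaln_cached(a: float, b: float) -> float:
    return float(special.betaln(a, b))


@lru_cache(maxsize=200_000)
def _hyp1f1_cached(a: float, b: float, z: float) -> float:
    return float(special.hyp1f1(a, b, z))


def kummer_1f1(a: float, b: float, z: float) -> float:
    """Kummer's confluent hypergeometric function 1F1(a; b; z).

    For negative arguments the Kummer transformation
    ``1F1(a,b,z) = e^z 1F1(b-a, b, -z)`` turns the alternating series into a
    positive-term one, avoiding cancellation.
    """
    if z < 0:
        return math.exp(z) * float(special.hyp1f1(b - a, b, -z))
    return float(special.hyp1f1(a, b, z))


# ---------------------------------------------------------------------------
# kernel backends
# ---------------------------------------------------------------------------


class KKernel:
    """Base class: cached evaluation of ``log k`` plus derived quantities."""

    backend = "abstract"

    def __init__(self, spec: ModelSpec, tol: float = 1e-10):
        self.spec = spec
        self.tol = tol
        self._cache: dict[tuple, float] = {}

    # subclasses implement _log_k(n_tuple) -> float
    def _log_k(self, n: tuple) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def log_k(self, n) -> float:
        n = validate_sample_counts(self.spec, n, allow_zero=True)
        key = tuple(int(v) for v in n)
        if key not in self._cache:
            self._cache[key] = self._log_k(key)
        return self._cache[key]

    def k(self, n) -> float:
        return math.exp(self.log_k(n))

    def ratio(self, n, target) -> float:
        """``k(target) / k(n)``; subclasses may override with exact forms."""
        return math.exp(self.log_k(target) - self.log_k(n))

    def duality_F(self, x, n) -> float:
        """Duality function ``F(x, n) = prod x_i^{n_i} / k(n)``."""
        n = np.asarray(n, dtype=np.int64)
        x = np.asarray(x, float)
        pos = n > 0
        if np.any(x[pos] == 0.0):
            return 0.0
        logmono = float(np.sum(n[pos] * np.log(x[pos])))
        return math.exp(logmono - self.log_k(n))


class NoMutationKernel(KKernel):
    """Beta-product kernel ``k(n) = prod_l B(n^(l))`` for theta = 0.

    ``B(n^(l)) = prod_i Gamma(n_i) / Gamma(n^(l))`` requires every count to
    be positive; states that have lost an allele type carry a formally
    infinite ``k``, so the duality function is zero there and rates into them
    are evaluated as limits by the rate code.  ``k(0)`` is *not* normalised
    to one (there is no stationary moment to normalise by).
    """

    backend = "no_mutation"
    handles_removable_coalescence = True

    def __init__(self, spec: ModelSpec, tol: float = 1e-10):
        if not spec.is_no_mutation:
            raise ValueError("no_mutation backend requires theta_l = 0 for all l")
        super().__init__(spec, tol)

    def _log_k(self, n: tuple) -> float:
        arr = np.asarray(n, dtype=np.int64)
        if np.any(arr < 1):
            raise ValueError(
                "Beta-product kernel undefined for counts with zero entries "
                f"(n = {n}); the dual rates never require such evaluations"
            )
        out = 0.0
        for nb in self.spec.split(arr):
            out += float(np.sum(special.gammaln(nb)) - special.gammaln(nb.sum()))
        return out

    def duality_F(self, x, n) -> float:
        """F is identically zero once an allele type is lost (k formally
        infinite through the Gamma(0) factor)."""
        if np.any(np.asarray(n) < 1):
            return 0.0
        return super().duality_F(x, n)

    def ratio(self, n, target) -> float:
        """Exact ``k(target)/k(n)`` by integer Gamma-ratio products.

        ``Gamma(b)/Gamma(a)`` for integers is the product ``a (a+1) ... (b-1)``
        (or its reciprocal), which is exact rational arithmetic and remains
        meaningful when individual counts touch zero: a count dropping from 1
        to 0 contributes a factor 0 in the denominator-Gamma sense (ratio
        +inf) and a count rising from 0 to 1 contributes factor 0.
        """
        n = np.asarray(n, dtype=np.int64)
        t = np.asarray(target, dtype=np.int64)
        num = Fraction(1)
        factors = []
        for nb, tb in zip(self.spec.split(n), self.spec.split(t)):
            for a, b in zip(nb.tolist(), tb.tolist()):
                factors.append(_int_gamma_ratio(a, b))
            # the per-locus 1/Gamma(n^(l)) normalisation, inverted
            factors.append(_int_gamma_ratio(int(tb.sum()), int(nb.sum())))
        inf_count = sum(1 for f in factors if f is None)
        if inf_count:  # a count fell to zero: k(target) is formally infinite
            return math.inf
        for f in factors:
            if f == 0:
                return 0.0
            num *= f
        return float(num)


def _int_gamma_ratio(a: int, b: int) -> Fraction | None:
    """``Gamma(b)/Gamma(a)`` for nonnegative integers as an exact Fraction.

    Returns ``Fraction(0)`` when the value is 0, ``None`` when it is +inf,
    treating ``Gamma(0) = +inf`` (so e.g. Gamma(1)/Gamma(0) = 0).
    """
    if a == b:
        return Fraction(1)
    if b > a:
        p = 1
        for v in range(a, b):
            p *= v
        return Fraction(p)  # p == 0 iff a == 0
    p = 1
    for v in range(b, a):
        p *= v
    if p == 0:
        return None
    return Fraction(1, p)


class PIMQuadratureKernel(KKernel):
    """Direct integration of the stationary density.

    For models where every locus has two alleles, ``k(n) Z`` is an
    ``L``-dimensional integral of a product-Beta weight times the entire
    function ``exp(2V)`` over the unit cube; it is evaluated with tensorised
    Gauss-Jacobi quadrature (the Jacobi weight absorbs the Beta boundary
    factors exactly, so convergence in the number of nodes is spectral; the
    result at ``quad_order`` nodes per axis is accepted only if it agrees
    with ``quad_order + 16`` to within ``tol``).  For loci with three or
    more alleles the kernel switches to Dirichlet importance sampling: with
    ``X ~ prod Dir(2 u^(l))`` and weights ``w = exp(2V)``,

        k(n) = E[w prod X^n] / E[w],

    estimated on a fixed, seeded draw so that repeated evaluations are
    bit-identical.  ``se(n)`` reports the Monte-Carlo standard error.
    """

    backend = "pim_quadrature"

    def __init__(
        self,
        spec: ModelSpec,
        tol: float = 1e-11,
        mc_draws: int = 200_000,
        seed: int = 0,
        quad_order: int = 48,
    ):
        if not spec.is_parent_independent:
            raise ValueError("pim_quadrature backend requires parent-independent mutation")
        if np.any(spec.theta <= 0):
            raise ValueError("pim_quadrature backend requires theta_l > 0 for all l")
        super().__init__(spec, tol)
        self._alpha = [2.0 * spec.pim_rates(l) for l in range(spec.L)]
        self._all_two = all(m == 2 for m in spec.M)
        self._mc_draws = mc_draws
        self._seed = seed
        self._mc_state = None
        self.quad_order = quad_order
        self._rule_cache: dict[tuple, tuple] = {}
        if self._all_two:
            self._log_I0 = self._log_integral(np.zeros(spec.MTOT, dtype=np.int64))

    # -- tensorised Gauss-Jacobi quadrature (all loci two-allele) --------
    def _jacobi_rule(self, a1: float, a2: float, order: int):
        """Nodes/weights for int_0^1 x^{a1-1} (1-x)^{a2-1} f(x) dx."""
        key = (round(a1, 12), round(a2, 12), order)
        rule = self._rule_cache.get(key)
        if rule is None:
            t, w = special.roots_jacobi(order, a2 - 1.0, a1 - 1.0)
            x = 0.5 * (t + 1.0)
            w = w * 2.0 ** (1.0 - a1 - a2)
            rule = (x, w)
            self._rule_cache[key] = rule
        return rule

    def _tensor_value(self, n: np.ndarray, order: int) -> float:
        spec = self.spec
        nodes, wts = [], []
        for l in range(spec.L):
            a = self._alpha[l] + n[spec.block_slice(l)]
            x, w = self._jacobi_rule(a[0], a[1], order)
            nodes.append(x)
            wts.append(w)
        grids = np.meshgrid(*nodes, indexing="ij")
        pts = np.empty(grids[0].shape + (spec.MTOT,))
        for l in range(spec.L):
            sl = spec.block_slice(l)
            pts[..., sl.start] = grids[l]
            pts[..., sl.start + 1] = 1.0 - grids[l]
        v = pts @ spec.h + 0.5 * np.einsum("...i,ij,...j->...", pts, spec.J, pts)
        integrand = np.exp(2.0 * v)
        wgrid = np.ones(grids[0].shape)
        for l, w in enumerate(wts):
            shape = [1] * spec.L
            shape[l] = -1
            wgrid = wgrid * w.reshape(shape)
        return float(np.sum(wgrid * integrand))

    def _log_integral(self, n: np.ndarray) -> float:
        v1 = self._tensor_value(n, self.quad_order)
        v2 = self._tensor_value(n, self.quad_order + 16)
        if abs(v1 - v2) > self.tol * abs(v2):
            raise RuntimeError(
                f"Gauss-Jacobi quadrature did not converge at order "
                f"{self.quad_order} (rel diff {abs(v1 / v2 - 1):.2e}); "
                "increase quad_order"
            )
        return math.log(v2)

    # -- Dirichlet importance sampling (general M_l) ---------------------
    def _ensure_mc(self):
        if self._mc_state is not None:
            return
        rng = np.random.default_rng(self._seed)
        spec = self.spec
        draws = np.empty((self._mc_draws, spec.MTOT))
        for l in range(spec.L):
            draws[:, spec.block_slice(l)] = rng.dirichlet(
                self._alpha[l], size=self._mc_draws
            )
        v = draws @ spec.h + 0.5 * np.einsum("ki,ij,kj->k", draws, spec.J, draws)
        w = np.exp(2.0 * v)
        self._mc_state = (draws, w, np.log(np.maximum(draws, 1e-300)))

    def _log_k(self, n: tuple) -> float:
        arr = np.asarray(n, dtype=np.int64)
        if arr.sum() == 0:
            return 0.0
        if self._all_two:
            return self._log_integral(arr) - self._log_I0
        self._ensure_mc()
        draws, w, logdraws = self._mc_state
        mono = np.exp(logdraws @ arr)
        return math.log(float(np.sum(w * mono) / np.sum(w)))

    def se(self, n) -> float:
        """Monte-Carlo standard error of ``k(n)`` (0 for the quadrature path)."""
        if self._all_two:
            return 0.0
        arr = validate_sample_counts(self.spec, n, allow_zero=True)
        self._ensure_mc()
        draws, w, logdraws = self._mc_state
        mono = np.exp(logdraws @ arr)
        wbar = np.mean(w)
        khat = np.mean(w * mono) / wbar
        # delta-method SE for the ratio estimator
        resid = (w * mono - khat * w) / wbar
        return float(np.std(resid, ddof=1) / math.sqrt(len(w)))


class Kummer1LocusKernel(KKernel):
    """One locus, two alleles, PIM: closed form via the Kummer function.

    ``k(n) = B(n1+2u1, n2+2u2) 1F1(n1+2u1, n1+n2+2u1+2u2, 2(h1-h2)) / Z'``
    with ``Z' = B(2u1, 2u2) 1F1(2u1, 2u1+2u2, 2(h1-h2))`` (the common factor
    ``e^{2 h2}`` cancels in the normalised kernel).
    """

    backend = "kummer_1locus"

    def __init__(self, spec: ModelSpec, tol: float = 1e-12):
        if spec.L != 1 or spec.M != (2,):
            raise ValueError("kummer_1locus backend requires L = 1, M = (2,)")
        if not spec.is_parent_independent:
            raise ValueError("kummer_1locus backend requires parent-independent mutation")
        super().__init__(spec, tol)
        u = spec.pim_rates(0)
        self._a0 = 2.0 * u[0]
        self._b0 = 2.0 * u[1]
        self._z = 2.0 * (spec.h[0] - spec.h[1])
        self._log_norm = float(
            special.betaln(self._a0, self._b0)
        ) + math.log(kummer_1f1(self._a0, self._a0 + self._b0, self._z))

    def _log_k(self, n: tuple) -> float:
        n1, n2 = n
        a = n1 + self._a0
        b = n2 + self._b0
        return (
            float(special.betaln(a, b))
            + math.log(kummer_1f1(a, a + b, self._z))
            - self._log_norm
        )


def I_series_2x2(
    a1: float,
    a2: float,
    b1: float,
    b2: float,
    J1: float,
    J2: float,
    tol: float = 1e-12,
    max_terms: int = 500,
) -> float:
    """Beta-Kummer series for the two-locus two-allele coupling integral

        I(a1,a2,b1,b2) = int_0^1 int_0^1 x^{a1-1}(1-x)^{a2-1} y^{b1-1}(1-y)^{b2-1}
                           exp(2[J1 x y + J2 (1-x)(1-y)]) dx dy.

    The outer series in ``n`` runs over Pochhammer-weighted powers
    ``(-2 J2)^n / n!`` with an inner binomial sum of Beta and Kummer factors;
    each inner 1F1 with negative argument is evaluated through the Kummer
    transformation, so the only sign oscillation left is the explicit
    alternating outer/inner structure.  Because terms alternate, truncation
    stops only after 20 consecutive outer terms each contribute less than
    ``tol`` times the running sum.

    ``J2 = 0`` is handled by the (exactly separable-limit) expansion
    ``I = sum_n (2 J1)^n / n! B(a1+n, a2) B(b1+n, b2)``, whose ``n = 0`` term
    alone gives the fully separable case ``J1 = J2 = 0`` to machine precision.
    """
    if min(a1, a2, b1, b2) <= 0:
        raise ValueError("Beta parameters must be positive")
    if J2 == 0.0:
        s = 0.0
        log_coef = 0.0  # log((2 J1)^n / n!) accumulated iteratively
        small = 0
        for n in range(max_terms):
            term = math.exp(
                log_coef + _betaln_cached(a1 + n, a2) + _betaln_cached(b1 + n, b2)
            )
            s += term
            if J1 == 0.0:
                return s
            small = small + 1 if abs(term) <= tol * abs(s) else 0
            if small >= 20:
                return s
            log_coef += math.log(2.0 * J1) - math.log(n + 1)
        raise SeriesConvergenceError(
            f"J2=0 series did not converge in {max_terms} terms", partial_sums=s
        )

    c = -(J1 + J2) / J2

    def inner_factor(k: int) -> float:
        # e^{2 J2} B(k+b1,b2) 1F1(k+b1, k+b1+b2, -2 J2)
        #   = B(k+b1,b2) 1F1(b2, k+b1+b2, 2 J2)   (Kummer transform)
        return math.exp(_betaln_cached(k + b1, b2)) * _hyp1f1_cached(
            b2, k + b1 + b2, 2.0 * J2
        )

    s = 0.0
    partials = []
    poch_ratio = 1.0  # [a1]_n / [a1+a2]_n
    pow_coef = 1.0  # (-2 J2)^n / n!
    small = 0
    for n in range(max_terms):
        inner = 0.0
        binom = 1.0
        cpow = 1.0
        for k in range(n + 1):
            inner += binom * cpow * inner_factor(k)
            binom = binom * (n - k) / (k + 1)
            cpow *= c
        term = poch_ratio * pow_coef * inner
        s += term
        partials.append(s)
        small = small + 1 if abs(term) <= tol * max(abs(s), 1e-300) else 0
        if small >= 20:
            break
        poch_ratio *= (a1 + n) / (a1 + a2 + n)
        pow_coef *= -2.0 * J2 / (n + 1)
    else:
        raise SeriesConvergenceError(
            f"Beta-Kummer series did not converge in {max_terms} terms",
            partial_sums=partials,
        )
    return math.exp(float(special.betaln(a1, a2))) * s


def _check_2x2_shape(spec: ModelSpec) -> tuple[float, float]:
    """Verify the diagonal-coupling two-locus two-allele shape; return (J1, J2)."""
    if spec.L != 2 or spec.M != (2, 2):
        raise ValueError("series_2x2 backend requires L = 2, M = (2, 2)")
    if np.any(spec.h != 0):
        raise ValueError("series_2x2 backend requires h = 0")
    B = spec.J_block(0, 1)
    if B[0, 1] != 0 or B[1, 0] != 0:
        raise ValueError(
            "series_2x2 backend requires diagonal coupling J^(12) = diag(J1, J2)"
        )
    return float(B[0, 0]), float(B[1, 1])


class Series2x2Kernel(KKernel):
    """Two loci, two alleles, diagonal coupling, h = 0, PIM.

    ``k(n) = I(n + 2u) / I(2u)`` with ``I`` the Beta-Kummer series above.
    """

    backend = "series_2x2"

    def __init__(self, spec: ModelSpec, tol: float = 1e-12, max_terms: int = 500):
        self._J1, self._J2 = _check_2x2_shape(spec)
        if not spec.is_parent_independent:
            raise ValueError("series_2x2 backend requires parent-independent mutation")
        if np.any(spec.theta <= 0):
            raise ValueError("series_2x2 backend requires theta_l > 0")
        super().__init__(spec, tol)
        self.max_terms = max_terms
        u1 = spec.pim_rates(0)
        u2 = spec.pim_rates(1)
        self._alpha = np.concatenate([2.0 * u1, 2.0 * u2])
        self._log_I0 = math.log(self.I(*self._alpha))

    def I(self, a1, a2, b1, b2) -> float:
        return I_series_2x2(
            a1, a2, b1, b2, self._J1, self._J2, tol=self.tol, max_terms=self.max_terms
        )

    def _log_k(self, n: tuple) -> float:
        a = self._alpha + np.asarray(n, float)
        return math.log(self.I(*a)) - self._log_I0


_BACKENDS = {
    "no_mutation": NoMutationKernel,
    "pim_quadrature": PIMQuadratureKernel,
    "kummer_1locus": Kummer1LocusKernel,
    "series_2x2": Series2x2Kernel,
}


def make_kernel(spec: ModelSpec, backend: str = "auto", **kwargs) -> KKernel:
    """Construct a kernel, choosing the cheapest exact backend when ``auto``.

    Mixed mutation regimes (some loci with ``theta = 0``, others without) are
    rejected: no closed or integral form of ``k`` covers them.
    """
    some_zero = bool(np.any(spec.theta == 0))
    if some_zero and not spec.is_no_mutation:
        raise ValueError(
            "mixed mutation regimes (some theta_l = 0, some > 0) are not supported"
        )
    if backend != "auto":
        return _BACKENDS[backend](spec, **kwargs)
    if spec.is_no_mutation:
        return NoMutationKernel(spec, **kwargs)
    if spec.L == 1 and spec.M == (2,) and spec.is_parent_independent:
        return Kummer1LocusKernel(spec, **kwargs)
    try:
        _check_2x2_shape(spec)
        if spec.is_parent_independent:
            return Series2x2Kernel(spec, **kwargs)
    except ValueError:
        pass
    return PIMQuadratureKernel(spec, **kwargs)


# ---------------------------------------------------------------------------
# stationary density, normalising constant, sampler
# ---------------------------------------------------------------------------


def _complete(spec: ModelSpec, xbar: np.ndarray) -> np.ndarray:
    """Lift reduced coordinates (last frequency per locus dropped) to the
    full simplex vector."""
    xbar = np.asarray(xbar, float)
    batch = xbar.shape[:-1]
    x = np.empty(batch + (spec.MTOT,))
    j = 0
    for l in range(spec.L):
        sl = spec.block_slice(l)
        m = spec.M[l]
        xb = xbar[..., j : j + m - 1]
        x[..., sl.start : sl.stop - 1] = xb
        x[..., sl.stop - 1] = 1.0 - xb.sum(axis=-1)
        j += m - 1
    return x


def log_unnormalized_density(spec: ModelSpec, xbar) -> float:
    """``log pi(xbar) + 2 V(x)`` on the reduced simplex (PIM, theta > 0).

    ``pi`` is the product of Dirichlet(2u) kernels per locus.
    """
    if not spec.is_parent_independent:
        raise ValueError("stationary density requires parent-independent mutation")
    if np.any(spec.theta <= 0):
        raise ValueError("stationary density requires theta_l > 0")
    x = _complete(spec, xbar)
    if np.any(x <= 0.0):
        raise ValueError("x must be strictly interior")
    out = 2.0 * potential(spec, x)
    for l in range(spec.L):
        a = 2.0 * spec.pim_rates(l)
        xb = x[spec.block_slice(l)]
        out += float(np.sum((a - 1.0) * np.log(xb)))
    return out


def normalising_constant(
    spec: ModelSpec, method: str = "auto", tol: float = 1e-10, mc_draws: int = 400_000, seed: int = 0
) -> float:
    """The constant ``Z = int pi e^{2V}`` over the reduced simplex.

    ``method`` is one of ``auto``, ``kummer_1locus``, ``series_2x2``,
    ``quadrature``, ``mc``.  The one-locus closed form is
    ``Z = e^{2 h2} B(2u1, 2u2) 1F1(2u1, 2u1+2u2, 2(h1-h2))``.
    """
    if not spec.is_parent_independent or np.any(spec.theta <= 0):
        raise ValueError("Z requires a PIM model with theta_l > 0")
    if method == "auto":
        if spec.L == 1 and spec.M == (2,):
            method = "kummer_1locus"
        else:
            try:
                _check_2x2_shape(spec)
                method = "series_2x2"
            except ValueError:
                method = "quadrature" if all(m == 2 for m in spec.M) else "mc"
    if method == "kummer_1locus":
        u = spec.pim_rates(0)
        a, b = 2.0 * u[0], 2.0 * u[1]
        z = 2.0 * (spec.h[0] - spec.h[1])
        return (
            math.exp(2.0 * spec.h[1] + float(special.betaln(a, b)))
            * kummer_1f1(a, a + b, z)
        )
    if method == "series_2x2":
        J1, J2 = _check_2x2_shape(spec)
        a = np.concatenate([2.0 * spec.pim_rates(0), 2.0 * spec.pim_rates(1)])
        return I_series_2x2(*a, J1, J2, tol=tol)
    if method == "quadrature":
        if not all(m == 2 for m in spec.M):
            raise ValueError("quadrature Z requires two alleles at every locus")
        kern = PIMQuadratureKernel(spec, tol=tol)
        return math.exp(kern._log_I0)
    if method == "mc":
        rng = np.random.default_rng(seed)
        draws = np.empty((mc_draws, spec.MTOT))
        log_beta = 0.0
        for l in range(spec.L):
            a = 2.0 * spec.pim_rates(l)
            draws[:, spec.block_slice(l)] = rng.dirichlet(a, size=mc_draws)
            log_beta += float(np.sum(special.gammaln(a)) - special.gammaln(a.sum()))
        v = draws @ spec.h + 0.5 * np.einsum("ki,ij,kj->k", draws, spec.J, draws)
        return math.exp(log_beta) * float(np.mean(np.exp(2.0 * v)))
    raise ValueError(f"unknown method {method!r}")


def sample_stationary(
    spec: ModelSpec,
    n_samples: int,
    seed: int = 0,
    n_walkers: int = 64,
    burn: int = 1500,
    thin: int = 5,
    step: float = 0.12,
) -> np.ndarray:
    """Metropolis random-walk draws from the stationary density (PIM).

    Runs ``n_walkers`` chains in parallel on the reduced simplex with
    Gaussian proposals of scale ``step``; returns ``n_samples`` completed
    frequency vectors (shape ``(n_samples, MTOT)``) after burn-in and
    thinning.  Warns when the mean acceptance rate leaves (0.05, 0.95).
    """
    if not spec.is_parent_independent or np.any(spec.theta <= 0):
        raise ValueError("stationary sampler requires a PIM model with theta_l > 0")
    rng = np.random.default_rng(seed)
    dim = spec.MTOT - spec.L
    alpha = [2.0 * spec.pim_rates(l) for l in range(spec.L)]

    def log_target(xbar: np.ndarray) -> np.ndarray:
        x = _complete(spec, xbar)
        bad = np.any(x <= 0.0, axis=-1)
        xs = np.where(x <= 0.0, 0.5, x)  # placeholder, masked below
        v = xs @ spec.h + 0.5 * np.einsum("ki,ij,kj->k", xs, spec.J, xs)
        out = 2.0 * v
        for l in range(spec.L):
            out += np.sum(
                (alpha[l] - 1.0) * np.log(xs[:, spec.block_slice(l)]), axis=-1
            )
        out[bad] = -np.inf
        return out

    # start walkers at the Dirichlet mean of each locus
    start = np.concatenate(
        [(a / a.sum())[:-1] for a in alpha]
    )
    xbar = np.tile(start, (n_walkers, 1)) + 0.01 * rng.standard_normal(
        (n_walkers, dim)
    )
    lp = log_target(xbar)
    n_rounds = burn + thin * math.ceil(n_samples / n_walkers)
    accepted = 0
    total = 0
    out = []
    for it in range(n_rounds):
        prop = xbar + step * rng.standard_normal(xbar.shape)
        lp_prop = log_target(prop)
        accept = np.log(rng.random(n_walkers)) < lp_prop - lp
        xbar[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        accepted += int(accept.sum())
        total += n_walkers
        if it >= burn and (it - burn) % thin == 0:
            out.append(_complete(spec, xbar.copy()))
    rate = accepted / total
    if not 0.05 < rate < 0.95:
        warnings.warn(
            f"Metropolis acceptance rate {rate:.3f} outside (0.05, 0.95); "
            "adjust the proposal scale 'step'",
            RuntimeWarning,
        )
    return np.concatenate(out, axis=0)[:n_samples]
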