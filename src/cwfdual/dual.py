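"""The dual jump process: coupled ancestral selection graphs, block-counted.

The process N(t) lives on nonnegative integer block vectors and jumps by

* coalescence      ``n -> n - e_i^(l)``             (two lineages merge),
* mutation         ``n -> n - e_i^(l) + e_j^(l)``   (type change, one locus),
* single-branching ``n -> n + e_j^(l)``             (a virtual parent, one locus),
* double-branching ``n -> n + e_j^(l) + e_h^(r)``   (virtual parents at two loci),

with rates that are explicit combinatorial factors times ratios of the
duality kernel ``k``.  Without mutation the kernel ratios collapse to
rational functions of the counts and the rates become fully explicit
(``rates_corollary1``).  Trajectories are drawn with Gillespie's algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .kernels import KKernel
from .model import ModelSpec, validate_sample_counts

__all__ = [
    "Jump",
    "RateTable",
    "DualPath",
    "rates_theorem1",
    "rates_corollary1",
    "rates_asg_1locus",
    "simulate_dual",
    "simulate_dual_final",
    "COALESCENCE",
    "MUTATION",
    "SINGLE_BRANCHING",
    "DOUBLE_BRANCHING",
]

COALESCENCE = "coalescence"
MUTATION = "mutation"
SINGLE_BRANCHING = "single_branching"
DOUBLE_BRANCHING = "double_branching"


class Jump(NamedTuple):
    target: tuple
    rate: float
    kind: str


@dataclass
class RateTable:
    """All jumps out of ``origin`` plus the diagonal entry ``q(n, n)``.

    Jumps are enumerated in a canonical order (kind-major:
    coalescence < mutation < single < double; within a kind locus-major,
    allele-minor), which fixes tie-breaking in the Gillespie sampler.
    Zero-rate jumps are not emitted.
    """

    origin: tuple
    jumps: list[Jump]
    diagonal: float

    @property
    def total_rate(self) -> float:
        return sum(j.rate for j in self.jumps)

    def row_sum_residual(self) -> float:
        """Relative deviation from the row-sum-zero identity."""
        tot = self.total_rate
        scale = max(abs(self.diagonal), abs(tot), 1e-300)
        return abs(tot + self.diagonal) / scale


def _diagonal(spec: ModelSpec, n: np.ndarray) -> float:
    """The explicit diagonal entry ``q(n, n)`` (kernel-free)."""
    out = 0.0
    for l in range(spec.L):
        nb = n[spec.block_slice(l)]
        nl = int(nb.sum())
        out += 0.5 * nl * (nl - 1)
        u = spec.u(l)
        out += float(np.sum(nb[:, None] * u) - np.sum(nb * np.diag(u)))
        hb = spec.h[spec.block_slice(l)]
        out += float(nb.sum() * hb.sum() - np.sum(nb * hb))
        for r in range(spec.L):
            if r != l:
                out += nl * float(spec.J_block(l, r).sum())
    return -out


def rates_theorem1(spec: ModelSpec, n, kernel: KKernel) -> RateTable:
    """Dual-process rates in the general (kernel-ratio) form.

    Coalescence carries the factor ``n_i (n_i - 1) / 2``; with the
    no-mutation Beta-product kernel the jump out of ``n_i = 1`` is a
    removable 0 * inf singularity whose limit ``n_i (n^(l) - 1) / 2`` is the
    explicit no-mutation coalescence rate, and is evaluated as such so that
    the table coincides with ``rates_corollary1``.
    """
    n = validate_sample_counts(spec, n)
    jumps: list[Jump] = []
    off = spec._offsets
    nb = spec.split(n)
    n_loc = [int(b.sum()) for b in nb]
    limit_coal = getattr(kernel, "handles_removable_coalescence", False)

    # coalescence
    for l in range(spec.L):
        for i in range(spec.M[l]):
            ni = int(nb[l][i])
            if ni >= 2:
                t = n.copy()
                t[off[l] + i] -= 1
                rate = 0.5 * ni * (ni - 1) * kernel.ratio(n, t)
                jumps.append(Jump(tuple(map(int, t)), rate, COALESCENCE))
            elif ni == 1 and limit_coal and n_loc[l] >= 2:
                t = n.copy()
                t[off[l] + i] -= 1
                jumps.append(
                    Jump(tuple(map(int, t)), 0.5 * ni * (n_loc[l] - 1), COALESCENCE)
                )
    # mutation
    for l in range(spec.L):
        u = spec.u(l)
        for i in range(spec.M[l]):
            ni = int(nb[l][i])
            if ni < 1:
                continue
            for j in range(spec.M[l]):
                if j == i or u[j, i] == 0.0:
                    continue
                t = n.copy()
                t[off[l] + i] -= 1
                t[off[l] + j] += 1
                rate = ni * u[j, i] * kernel.ratio(n, t)
                jumps.append(Jump(tuple(map(int, t)), rate, MUTATION))
    # single-branching
    for l in range(spec.L):
        hb = spec.h[spec.block_slice(l)]
        for j in range(spec.M[l]):
            coeff = n_loc[l] * float(hb.sum() - hb[j])
            for r in range(spec.L):
                if r == l:
                    continue
                coeff += float(nb[r] @ spec.J_block(l, r)[j, :])
            if coeff == 0.0:
                continue
            t = n.copy()
            t[off[l] + j] += 1
            rate = coeff * kernel.ratio(n, t)
            if rate > 0.0:
                jumps.append(Jump(tuple(map(int, t)), rate, SINGLE_BRANCHING))
    # double-branching: the selection weight sums J over every allele pair
    # except the one being added, sum_{(k,m) != (j,h)} J_km = tot - J_jh
    for l in range(spec.L):
        for r in range(l + 1, spec.L):
            B = spec.J_block(l, r)
            tot = float(B.sum())
            if tot == 0.0:
                continue
            for j in range(spec.M[l]):
                for h in range(spec.M[r]):
                    coeff = (n_loc[l] + n_loc[r]) * float(tot - B[j, h])
                    if coeff == 0.0:
                        continue
                    t = n.copy()
                    t[off[l] + j] += 1
                    t[off[r] + h] += 1
                    rate = coeff * kernel.ratio(n, t)
                    if rate > 0.0:
                        jumps.append(Jump(tuple(map(int, t)), rate, DOUBLE_BRANCHING))
    return RateTable(tuple(map(int, n)), jumps, _diagonal(spec, n))


def rates_corollary1(spec: ModelSpec, n) -> RateTable:
    """Fully explicit rates for the no-mutation regime (theta = 0).

    Coalescence ``n_i (n^(l)-1)/2`` (any ``n_i >= 1``); single-branching
    ``n_j sum_{k!=j} h_k + (n_j / n^(l)) sum_r sum_i n_i^(r) J_ji``;
    double-branching ``(n^(l)+n^(r)) (n_j n_h)/(n^(l) n^(r))
    sum_{(k,m) != (j,h)} J_km``; no mutation jumps.  The diagonal is minus
    the total outflow.
    """
    if not spec.is_no_mutation:
        raise ValueError("rates_corollary1 requires theta_l = 0 for all l")
    n = validate_sample_counts(spec, n)
    jumps: list[Jump] = []
    off = spec._offsets
    nb = spec.split(n)
    n_loc = [int(b.sum()) for b in nb]

    for l in range(spec.L):
        for i in range(spec.M[l]):
            ni = int(nb[l][i])
            rate = 0.5 * ni * (n_loc[l] - 1)
            if rate > 0.0:
                t = n.copy()
                t[off[l] + i] -= 1
                jumps.append(Jump(tuple(map(int, t)), rate, COALESCENCE))
    for l in range(spec.L):
        hb = spec.h[spec.block_slice(l)]
        for j in range(spec.M[l]):
            nj = int(nb[l][j])
            if nj == 0:
                continue
            rate = nj * float(hb.sum() - hb[j])
            for r in range(spec.L):
                if r == l:
                    continue
                rate += (nj / n_loc[l]) * float(nb[r] @ spec.J_block(l, r)[j, :])
            if rate > 0.0:
                t = n.copy()
                t[off[l] + j] += 1
                jumps.append(Jump(tuple(map(int, t)), rate, SINGLE_BRANCHING))
    for l in range(spec.L):
        for r in range(l + 1, spec.L):
            B = spec.J_block(l, r)
            if not B.any() or n_loc[l] == 0 or n_loc[r] == 0:
                continue
            tot = float(B.sum())
            for j in range(spec.M[l]):
                nj = int(nb[l][j])
                if nj == 0:
                    continue
                for h in range(spec.M[r]):
                    nh = int(nb[r][h])
                    if nh == 0:
                        continue
                    rate = (
                        (n_loc[l] + n_loc[r])
                        * (nj * nh / (n_loc[l] * n_loc[r]))
                        * float(tot - B[j, h])
                    )
                    if rate > 0.0:
                        t = n.copy()
                        t[off[l] + j] += 1
                        t[off[r] + h] += 1
                        jumps.append(Jump(tuple(map(int, t)), rate, DOUBLE_BRANCHING))
    total = sum(j.rate for j in jumps)
    return RateTable(tuple(map(int, n)), jumps, -total)


def rates_asg_1locus(spec: ModelSpec, n, kernel: KKernel | None = None) -> RateTable:
    """One-locus two-allele ancestral-selection-graph rates.

    Coalescence ``n_i (n_i - 1)/2 k(n - e_i)/k(n)``; mutation
    ``u_i n_i k(n + e_{j(i)} - e_i)/k(n)``; branching
    ``h_{j(i)} n k(n + e_i)/k(n)`` where ``j(i)`` is the opposite allele.
    The diagonal is ``-(n(n-1)/2 + sum n_i u_{j(i)} + sum n_{j(i)} h_i)``.
    """
    if spec.L != 1 or spec.M != (2,):
        raise ValueError("rates_asg_1locus requires L = 1, M = (2,)")
    if not spec.is_parent_independent:
        raise ValueError("rates_asg_1locus requires parent-independent mutation")
    if kernel is None:
        from .kernels import Kummer1LocusKernel

        kernel = Kummer1LocusKernel(spec)
    n = validate_sample_counts(spec, n)
    u = spec.pim_rates(0)
    h = spec.h
    jumps: list[Jump] = []
    ntot = int(n.sum())
    for i in (0, 1):
        ji = 1 - i
        if n[i] >= 2:
            t = n.copy()
            t[i] -= 1
            jumps.append(
                Jump(tuple(map(int, t)), 0.5 * n[i] * (n[i] - 1) * kernel.ratio(n, t), COALESCENCE)
            )
        if n[i] >= 1 and u[i] > 0:
            t = n.copy()
            t[i] -= 1
            t[ji] += 1
            jumps.append(Jump(tuple(map(int, t)), u[i] * n[i] * kernel.ratio(n, t), MUTATION))
        if h[ji] > 0:
            t = n.copy()
            t[i] += 1
            jumps.append(
                Jump(tuple(map(int, t)), h[ji] * ntot * kernel.ratio(n, t), SINGLE_BRANCHING)
            )
    diag = -(
        0.5 * ntot * (ntot - 1)
        + float(n[0] * u[1] + n[1] * u[0])
        + float(n[1] * h[0] + n[0] * h[1])
    )
    return RateTable(tuple(map(int, n)), jumps, diag)


@dataclass
class DualPath:
    """A Gillespie trajectory: states visited, jump times and kinds."""

    times: list[float]
    states: list[tuple]
    kinds: list[str]
    seed: int
    capped: bool = False


class _RateCache:
    """Per-state rate tables with precomputed cumulative rates."""

    def __init__(self, spec: ModelSpec, kernel: KKernel | None):
        self.spec = spec
        self.kernel = kernel
        self._tab: dict[tuple, tuple] = {}

    def get(self, key: tuple):
        hit = self._tab.get(key)
        if hit is None:
            n = np.asarray(key, dtype=np.int64)
            if self.kernel is None or self.spec.is_no_mutation:
                table = rates_corollary1(self.spec, n)
            else:
                table = rates_theorem1(self.spec, n, self.kernel)
            targets = [j.target for j in table.jumps]
            kinds = [j.kind for j in table.jumps]
            cum = np.cumsum([j.rate for j in table.jumps])
            total = float(cum[-1]) if len(cum) else 0.0
            hit = (targets, kinds, cum, total)
            self._tab[key] = hit
        return hit


def simulate_dual(
    spec: ModelSpec,
    n0,
    t_end: float,
    kernel: KKernel | None = None,
    seed: int = 0,
    size_cap: int | None = None,
    _cache: _RateCache | None = None,
    _rng=None,
) -> DualPath:
    """Simulate one dual-process trajectory by Gillespie's algorithm.

    Holding times are exponential with parameter ``|q(n, n)|`` (equivalently
    the total jump rate); the jump is chosen proportionally to the rates in
    canonical order.  ``size_cap`` (default ``10 ||n0||_1 + 50``) aborts a
    path whose total count explodes; the returned path is flagged ``capped``.
    """
    n0 = validate_sample_counts(spec, n0)
    if size_cap is None:
        size_cap = 10 * int(n0.sum()) + 50
    cache = _cache if _cache is not None else _RateCache(spec, kernel)
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    t = 0.0
    state = tuple(int(v) for v in n0)
    times = [0.0]
    states = [state]
    kinds: list[str] = []
    capped = False
    while True:
        targets, jkinds, cum, total = cache.get(state)
        if total <= 0.0:
            break  # absorbed
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        idx = int(np.searchsorted(cum, rng.random() * total, side="right"))
        idx = min(idx, len(targets) - 1)
        state = targets[idx]
        times.append(t)
        states.append(state)
        kinds.append(jkinds[idx])
        if sum(state) > size_cap:
            capped = True
            break
    return DualPath(times, states, kinds, seed, capped)


def simulate_dual_final(
    spec: ModelSpec,
    n0,
    t_end: float,
    kernel: KKernel | None = None,
    seed: int = 0,
    n_paths: int = 1,
    size_cap: int | None = None,
):
    """Final states of ``n_paths`` independent trajectories (shared rate
    cache).  Returns ``(states, n_capped)`` with states an int array of shape
    ``(n_paths, MTOT)``."""
    n0 = validate_sample_counts(spec, n0)
    cache = _RateCache(spec, kernel)
    rng = np.random.default_rng(seed)
    out = np.empty((n_paths, spec.MTOT), dtype=np.int64)
    n_capped = 0
    for p in range(n_paths):
        path = simulate_dual(
            spec, n0, t_end, kernel, size_cap=size_cap, _cache=cache, _rng=rng
        )
        out[p] = path.states[-1]
        n_capped += path.capped
    return out, n_capped
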