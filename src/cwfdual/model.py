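"""Model parameters and state spaces for the coupled Wright-Fisher diffusion.

The model describes ``L`` loci with ``M_l`` alleles each, evolving under
mutation and selection but free recombination, so the only coupling between
loci is selective.  Selection is encoded by a quadratic potential

    V(x) = x^T h + (1/2) x^T J x,

where ``h`` holds one-locus selection coefficients and the symmetric block
matrix ``J`` (zero diagonal blocks) holds pairwise inter-locus interactions.
Mutation acts independently per locus at total rate ``theta_l / 2`` with a
row-stochastic transition matrix ``P^(l)``, giving per-type rates
``u_ij^(l) = (theta_l / 2) P_ij^(l)``.

States live on the product of probability simplices: a frequency vector ``x``
is the concatenation of per-locus blocks summing to one.  The dual jump
process lives on nonnegative integer count vectors ``n`` with the same block
structure.  Throughout the package indices are 0-based internally; user-facing
labels (CLI, error messages) are 1-based.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "validate_model",
    "potential",
    "fitness_coefficient",
    "mutation_rate_matrices",
    "validate_frequency_state",
    "validate_sample_counts",
    "enumerate_haplotypes",
]

_ROW_TOL = 1e-12
_PIM_TOL = 1e-12
_SIMPLEX_TOL = 1e-10


@dataclass
class ModelSpec:
    """Parameters defining both the diffusion and its dual jump process.

    Parameters
    ----------
    M : sequence of int
        Alleles per locus, each >= 2.  ``MTOT = sum(M)``.
    h : array, shape (MTOT,)
        One-locus selection coefficients, nonnegative, in per-locus blocks.
    J : array, shape (MTOT, MTOT)
        Pairwise selection block matrix; symmetric with zero diagonal blocks.
    theta : array, shape (L,)
        Per-locus total mutation rates (the locus-l mutation rate is
        ``theta_l / 2``).
    P : sequence of arrays
        Per-locus row-stochastic mutation transition matrices.
    pim_u : sequence of arrays, optional
        Parent-independent mutation rates ``u_j^(l)``.  When given they must
        be consistent with ``theta``/``P`` (every row of ``u^(l)`` equal to
        ``pim_u[l]``).  May also be given *instead of* theta/P, in which case
        ``theta_l = 2 * sum(u^(l))`` and ``P^(l)`` has identical rows
        proportional to ``u^(l)``.
    """

    M: tuple[int, ...]
    h: np.ndarray
    J: np.ndarray
    theta: np.ndarray = None
    P: tuple[np.ndarray, ...] = None
    pim_u: tuple[np.ndarray, ...] | None = None
    _offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.M = tuple(int(m) for m in np.atleast_1d(self.M))
        mtot = sum(self.M)
        self.h = np.zeros(mtot) if self.h is None else np.asarray(self.h, float).ravel()
        self.J = (
            np.zeros((mtot, mtot)) if self.J is None else np.asarray(self.J, float)
        )
        if self.pim_u is not None:
            self.pim_u = tuple(np.asarray(u, float).ravel() for u in self.pim_u)
        if self.theta is None and self.pim_u is not None:
            # Derive theta/P from parent-independent rates.
            self.theta = np.array([2.0 * u.sum() for u in self.pim_u])
            P = []
            for l, u in enumerate(self.pim_u):
                tot = u.sum()
                row = u / tot if tot > 0 else np.full(self.M[l], 1.0 / self.M[l])
                P.append(np.tile(row, (self.M[l], 1)))
            self.P = tuple(P)
        else:
            self.theta = np.asarray(self.theta, float).ravel()
            self.P = tuple(np.asarray(p, float) for p in self.P)
        self._offsets = np.concatenate([[0], np.cumsum(self.M)])

    # -- block structure -------------------------------------------------
    @property
    def L(self) -> int:
        return len(self.M)

    @property
    def MTOT(self) -> int:
        return int(self._offsets[-1])

    def block_slice(self, l: int) -> slice:
        """Index slice of locus ``l`` (0-based) within a length-MTOT vector."""
        return slice(int(self._offsets[l]), int(self._offsets[l + 1]))

    def split(self, v: np.ndarray) -> list[np.ndarray]:
        """Split a length-MTOT vector into its per-locus blocks."""
        v = np.asarray(v)
        return [v[..., self.block_slice(l)] for l in range(self.L)]

    def J_block(self, l: int, r: int) -> np.ndarray:
        return self.J[self.block_slice(l), self.block_slice(r)]

    # -- mutation --------------------------------------------------------
    def u(self, l: int) -> np.ndarray:
        """Mutation rate matrix ``u^(l) = (theta_l/2) P^(l)``."""
        return 0.5 * self.theta[l] * self.P[l]

    @property
    def is_parent_independent(self) -> bool:
        """True when every mutation matrix has identical rows (u_ij = u_j)."""
        if self.pim_u is not None:
            return True
        for l in range(self.L):
            u = self.u(l)
            if np.max(np.abs(u - u[0])) > _PIM_TOL:
                return False
        return True

    def pim_rates(self, l: int) -> np.ndarray:
        """Parent-independent rates u_j^(l); raises if the model is not PIM."""
        if self.pim_u is not None:
            return self.pim_u[l]
        u = self.u(l)
        if np.max(np.abs(u - u[0])) > _PIM_TOL:
            raise ValueError(
                f"locus {l + 1}: mutation is parent dependent (rows of u differ)"
            )
        return u[0].copy()

    @property
    def is_no_mutation(self) -> bool:
        return bool(np.all(self.theta == 0.0))

    # -- misc ------------------------------------------------------------
    def digest(self) -> str:
        """Stable hex digest of the parameters (for logging/reports)."""
        payload = json.dumps(
            {
                "M": list(self.M),
                "h": self.h.tolist(),
                "J": self.J.tolist(),
                "theta": self.theta.tolist(),
                "P": [p.tolist() for p in self.P],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            M=self.M,
            h=self.h.copy(),
            J=self.J.copy(),
            theta=self.theta.copy(),
            P=tuple(p.copy() for p in self.P),
            pim_u=None if self.pim_u is None else tuple(u.copy() for u in self.pim_u),
        )


def validate_model(spec: ModelSpec) -> list[str]:
    """Return a list of invariant violations (empty when the spec is valid).

    Checks dimensions, symmetry and zero diagonal blocks of ``J``,
    nonnegativity of ``h``/``J``/``theta``, row-stochasticity of each
    ``P^(l)``, and consistency of ``pim_u`` with the derived rates.
    """
    errs: list[str] = []
    L, mtot = spec.L, spec.MTOT
    if L < 1:
        errs.append("L must be >= 1")
    for l, m in enumerate(spec.M):
        if m < 2:
            errs.append(f"locus {l + 1}: M_l = {m} < 2")
    if spec.h.shape != (mtot,):
        errs.append(f"h has shape {spec.h.shape}, expected ({mtot},)")
        return errs
    if spec.J.shape != (mtot, mtot):
        errs.append(f"J has shape {spec.J.shape}, expected ({mtot}, {mtot})")
        return errs
    if np.any(spec.h < 0):
        errs.append("h has negative entries")
    if np.any(spec.J < 0):
        errs.append("J has negative entries")
    if np.any(spec.theta < 0):
        errs.append("theta has negative entries")
    if not np.allclose(spec.J, spec.J.T, atol=1e-12, rtol=0):
        errs.append("J is not symmetric")
    for l in range(L):
        if np.any(spec.J_block(l, l) != 0):
            errs.append(f"diagonal block J^({l + 1},{l + 1}) is nonzero")
    if len(spec.theta) != L:
        errs.append(f"theta has length {len(spec.theta)}, expected {L}")
    if len(spec.P) != L:
        errs.append(f"P has {len(spec.P)} matrices, expected {L}")
        return errs
    for l in range(L):
        p = spec.P[l]
        if p.shape != (spec.M[l], spec.M[l]):
            errs.append(f"P^({l + 1}) has shape {p.shape}")
            continue
        if np.any(p < 0):
            errs.append(f"P^({l + 1}) has negative entries")
        bad = np.abs(p.sum(axis=1) - 1.0) > _ROW_TOL
        if np.any(bad):
            rows = ", ".join(str(i + 1) for i in np.nonzero(bad)[0])
            errs.append(f"locus {l + 1}: rows {rows} of P do not sum to 1")
    if spec.pim_u is not None:
        for l in range(L):
            if len(spec.pim_u[l]) != spec.M[l]:
                errs.append(f"pim_u^({l + 1}) has wrong length")
                continue
            u = spec.u(l)
            if np.max(np.abs(u - spec.pim_u[l][None, :])) > _PIM_TOL:
                errs.append(
                    f"locus {l + 1}: pim_u inconsistent with theta/P "
                    "(rows of u differ from pim_u)"
                )
    return errs


def potential(spec: ModelSpec, x: np.ndarray) -> float:
    """Quadratic selection potential ``V(x) = x^T h + (1/2) x^T J x``."""
    x = np.asarray(x, float).ravel()
    if x.shape != (spec.MTOT,):
        raise ValueError(f"x has shape {x.shape}, expected ({spec.MTOT},)")
    return float(x @ spec.h + 0.5 * x @ spec.J @ x)


def fitness_coefficient(spec: ModelSpec, haplotype: Sequence[int]) -> float:
    """Fitness of a haplotype (one 0-based allele index per locus).

    ``w = 1 + sum_l h_{i_l}^(l) + sum_{l<r} J^{(lr)}_{i_l i_r}``.
    """
    hap = list(haplotype)
    if len(hap) != spec.L:
        raise ValueError(f"haplotype has {len(hap)} loci, expected {spec.L}")
    for l, i in enumerate(hap):
        if not 0 <= i < spec.M[l]:
            raise IndexError(
                f"locus {l + 1}: allele index {i + 1} out of range 1..{spec.M[l]}"
            )
    w = 1.0
    off = spec._offsets
    for l, i in enumerate(hap):
        w += spec.h[off[l] + i]
    for l in range(spec.L):
        for r in range(l + 1, spec.L):
            w += spec.J[off[l] + hap[l], off[r] + hap[r]]
    return w


def mutation_rate_matrices(spec: ModelSpec) -> list[np.ndarray]:
    """Per-locus mutation rate matrices ``u^(l) = (theta_l/2) P^(l)``.

    When ``pim_u`` is present, consistency (all rows equal to ``pim_u[l]``)
    is asserted.
    """
    mats = [spec.u(l) for l in range(spec.L)]
    if spec.pim_u is not None:
        for l, u in enumerate(mats):
            if np.max(np.abs(u - spec.pim_u[l][None, :])) > _PIM_TOL:
                raise ValueError(
                    f"locus {l + 1}: rows of u^(l) differ from pim_u beyond tolerance"
                )
    return mats


def validate_frequency_state(spec: ModelSpec, x: np.ndarray, tol: float = _SIMPLEX_TOL) -> np.ndarray:
    """Check that ``x`` lies on the product of simplices; return it as array."""
    x = np.asarray(x, float).ravel()
    if x.shape != (spec.MTOT,):
        raise ValueError(f"x has shape {x.shape}, expected ({spec.MTOT},)")
    if np.any(x < -tol) or np.any(x > 1 + tol):
        raise ValueError("frequencies outside [0, 1]")
    for l, xb in enumerate(spec.split(x)):
        if abs(xb.sum() - 1.0) > tol:
            raise ValueError(f"locus {l + 1}: frequencies sum to {xb.sum()}, not 1")
    return x


def validate_sample_counts(
    spec: ModelSpec, n: np.ndarray, allow_zero: bool = False
) -> np.ndarray:
    """Check that ``n`` is a nonnegative integer block vector; return int array."""
    n = np.asarray(n)
    if n.shape != (spec.MTOT,):
        raise ValueError(f"n has shape {n.shape}, expected ({spec.MTOT},)")
    if np.any(n < 0) or np.any(n != np.round(n)):
        raise ValueError("n must have nonnegative integer entries")
    n = n.astype(np.int64)
    if not allow_zero and n.sum() == 0:
        raise ValueError("n must be nonzero for a dual-process state")
    return n


def enumerate_haplotypes(spec: ModelSpec):
    """Yield all haplotypes (tuples of 0-based allele indices, one per locus)."""
    import itertools

    yield from itertools.product(*(range(m) for m in spec.M))
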