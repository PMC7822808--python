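"""Forward-in-time simulation and generator of the coupled diffusion.

The diffusion solves, on the product of simplices,

    dX = mu(X) dt + D(X) grad V(X) dt + D(X)^{1/2} dW,

with per-locus mutation drift ``mu``, selection drift ``g = D grad V`` and the
Wright-Fisher covariance blocks ``d_ij = x_i (delta_ij - x_j)``.  The
generator acts on monomials analytically, which is what the duality checks
use; path simulation is Euler-Maruyama with projection back onto the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelSpec, validate_frequency_state, validate_sample_counts

__all__ = [
    "drift_mutation",
    "drift_selection",
    "diffusion_blocks",
    "generator_terms",
    "apply_generator_to_monomial",
    "simulate_forward",
    "simulate_forward_final",
    "PathSample",
]


@dataclass
class PathSample:
    """A recorded Euler-Maruyama path bundle.

    ``states`` has shape ``(len(times), n_paths, MTOT)``.
    """

    times: np.ndarray
    states: np.ndarray
    seed: int
    dt: float


def drift_mutation(spec: ModelSpec, x: np.ndarray) -> np.ndarray:
    """Mutation drift ``mu_i^(l) = sum_j [u_ji x_j - u_ij x_i]`` per locus."""
    x = np.asarray(x, float)
    out = np.empty_like(x)
    for l in range(spec.L):
        sl = spec.block_slice(l)
        u = spec.u(l)
        xb = x[..., sl]
        out[..., sl] = xb @ u - xb * u.sum(axis=1)
    return out


def diffusion_blocks(spec: ModelSpec, x: np.ndarray) -> list[np.ndarray]:
    """Per-locus covariance blocks ``d^(l)(x^(l))`` with entries
    ``x_i (delta_ij - x_j)``."""
    blocks = []
    for xb in spec.split(np.asarray(x, float)):
        blocks.append(np.diag(xb) - np.outer(xb, xb))
    return blocks


def drift_selection(spec: ModelSpec, x: np.ndarray) -> np.ndarray:
    """Selection drift ``g(x) = D(x) (h + J x)`` evaluated blockwise."""
    x = np.asarray(x, float)
    htilde = spec.h + spec.J @ x
    out = np.empty_like(x)
    for l in range(spec.L):
        sl = spec.block_slice(l)
        xb = x[sl]
        hb = htilde[sl]
        # d^(l) @ hb without forming the matrix: x_i (hb_i - x . hb)
        out[sl] = xb * (hb - xb @ hb)
    return out


def generator_terms(spec: ModelSpec, x: np.ndarray):
    """Return ``(mu, g, d_blocks)`` at ``x`` (the generator's coefficients)."""
    return drift_mutation(spec, x), drift_selection(spec, x), diffusion_blocks(spec, x)


def apply_generator_to_monomial(spec: ModelSpec, x, n, kernel) -> float:
    """Apply the diffusion generator to ``F(., n) = prod x_i^{n_i} / k(n)``.

    The first and second partials of the monomial are closed-form
    (``dF/dx_i = n_i/x_i F`` etc.), so the result is exact up to the accuracy
    of ``k(n)`` supplied by ``kernel``:

        L F = [ sum_i (mu_i + g_i) n_i / x_i
                + (1/2) sum_l ( sum_i (1 - x_i) n_i (n_i - 1) / x_i
                                - (n^(l)^2 - sum_i n_i^2) ) ] * F(x, n).

    Raises on boundary points where a positive exponent meets a zero
    frequency.  Returns 0 for the constant monomial ``n = 0``.
    """
    x = validate_frequency_state(spec, x)
    n = validate_sample_counts(spec, n, allow_zero=True)
    if n.sum() == 0:
        return 0.0
    pos = n > 0
    if np.any(x[pos] <= 0.0):
        raise ValueError("generator undefined: n_i >= 1 at a zero frequency")
    F = kernel.duality_F(x, n)
    if F == 0.0:
        return 0.0
    mu = drift_mutation(spec, x)
    g = drift_selection(spec, x)
    coeff = float(np.sum((mu[pos] + g[pos]) * n[pos] / x[pos]))
    for l in range(spec.L):
        sl = spec.block_slice(l)
        nb = n[sl]
        xb = x[sl]
        p = nb > 0
        nl = nb.sum()
        diag = np.sum((1.0 - xb[p]) * nb[p] * (nb[p] - 1) / xb[p])
        coeff += 0.5 * (diag - (nl * nl - np.sum(nb * nb)))
    return coeff * F


def _project_simplex(spec: ModelSpec, x: np.ndarray) -> np.ndarray:
    """Clip negatives to zero and renormalise each locus block to sum one."""
    np.clip(x, 0.0, None, out=x)
    for l in range(spec.L):
        sl = spec.block_slice(l)
        s = x[..., sl].sum(axis=-1, keepdims=True)
        x[..., sl] /= s
    return x


def _euler_step(spec: ModelSpec, x: np.ndarray, dt: float, rng) -> np.ndarray:
    """One vectorised Euler-Maruyama step for a batch ``x`` of shape
    ``(n_paths, MTOT)``.

    The diffusion square root uses the multinomial-covariance factor
    ``B_ij = delta_ij sqrt(x_i) - x_i sqrt(x_j)`` per locus, which satisfies
    ``B B^T = d`` on the simplex and degrades gracefully at the boundary.
    """
    htilde = spec.h[None, :] + x @ spec.J.T
    drift = np.empty_like(x)
    noise = np.empty_like(x)
    xi = rng.standard_normal(x.shape)
    for l in range(spec.L):
        sl = spec.block_slice(l)
        u = spec.u(l)
        xb = x[:, sl]
        hb = htilde[:, sl]
        mu = xb @ u - xb * u.sum(axis=1)
        g = xb * (hb - np.sum(xb * hb, axis=1, keepdims=True))
        drift[:, sl] = mu + g
        sq = np.sqrt(xb)
        z = xi[:, sl]
        noise[:, sl] = sq * z - xb * np.sum(sq * z, axis=1, keepdims=True)
    x = x + drift * dt + noise * np.sqrt(dt)
    return _project_simplex(spec, x)


def simulate_forward(
    spec: ModelSpec,
    x0,
    t_end: float,
    dt: float = 1e-3,
    seed: int = 0,
    n_paths: int = 1,
    record_every: int = 1,
) -> PathSample:
    """Simulate Euler-Maruyama paths of the diffusion, recording states.

    ``record_every`` thins the stored grid (the stepper always uses ``dt``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x0 = validate_frequency_state(spec, x0)
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    x = np.tile(x0, (n_paths, 1))
    times = [0.0]
    states = [x.copy()]
    for step in range(1, n_steps + 1):
        x = _euler_step(spec, x, dt, rng)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite state at step {step}")
        if step % record_every == 0 or step == n_steps:
            times.append(step * dt)
            states.append(x.copy())
    return PathSample(
        times=np.array(times), states=np.array(states), seed=seed, dt=dt
    )


def simulate_forward_final(
    spec: ModelSpec,
    x0,
    t_end: float,
    dt: float = 1e-3,
    seed: int = 0,
    n_paths: int = 1,
) -> np.ndarray:
    """Final states only, shape ``(n_paths, MTOT)`` (memory-light variant)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    x0 = validate_frequency_state(spec, x0)
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    x = np.tile(x0, (n_paths, 1))
    for step in range(n_steps):
        x = _euler_step(spec, x, dt, rng)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite state at final step")
    return x
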