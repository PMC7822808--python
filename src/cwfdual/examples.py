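"""Canonical example models and random fixture generation.

The packaged two-locus two-allele models (``fig1_model``) are the standard
illustration of selective coupling: parent-independent mutation with
``u = 0.8`` for every allele and diagonal pairwise coupling ``J1 = J2``
(either 0, independent loci, or 2, favouring the haplotype pairs (1,1) and
(2,2)).  ``random_model`` draws valid specs for property tests.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .model import ModelSpec

__all__ = ["fig1_model", "random_model"]


def fig1_model(coupled: bool = True) -> ModelSpec:
    """The packaged two-locus two-allele example (J1 = J2 = 2 or 0)."""
    from .io import load_model

    name = "fig1_coupled.json" if coupled else "fig1_independent.json"
    with resources.as_file(resources.files("cwfdual.data") / name) as path:
        return load_model(path)


def random_model(
    L: int,
    M,
    regime: str = "pim_selection",
    magnitude: float = 0.5,
    seed: int = 0,
) -> ModelSpec:
    """Draw a random valid model.

    ``regime`` is one of

    * ``neutral`` -- h = 0, J = 0, positive PIM mutation;
    * ``pim_selection`` -- random h, J, positive PIM mutation;
    * ``no_mutation`` -- random h, J, theta = 0.

    Selection entries are Uniform(0, magnitude); J is symmetrised with zero
    diagonal blocks; PIM rates are Uniform(0.2, 1.0).  Deterministic under
    ``seed``.
    """
    if regime not in ("neutral", "pim_selection", "no_mutation"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    M = tuple(int(m) for m in np.atleast_1d(M))
    if len(M) != L:
        raise ValueError("len(M) must equal L")
    mtot = sum(M)
    offsets = np.concatenate([[0], np.cumsum(M)])
    if regime == "neutral":
        h = np.zeros(mtot)
        J = np.zeros((mtot, mtot))
    else:
        h = rng.uniform(0, magnitude, size=mtot)
        J = np.zeros((mtot, mtot))
        for l in range(L):
            for r in range(l + 1, L):
                block = rng.uniform(0, magnitude, size=(M[l], M[r]))
                J[offsets[l] : offsets[l + 1], offsets[r] : offsets[r + 1]] = block
                J[offsets[r] : offsets[r + 1], offsets[l] : offsets[l + 1]] = block.T
    if regime == "no_mutation":
        theta = np.zeros(L)
        P = tuple(np.eye(m) for m in M)
        return ModelSpec(M=M, h=h, J=J, theta=theta, P=P)
    pim_u = tuple(rng.uniform(0.2, 1.0, size=m) for m in M)
    return ModelSpec(M=M, h=h, J=J, pim_u=pim_u)
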