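"""Density-fitting tensors in MO-blocked form.

The four-center two-electron integrals ``(ia|jb)`` are factorized through an
auxiliary basis as ``K = J J^T`` with ``J_ia^P = sum_Q I_ia^Q (V^-1/2)_QP``,
where ``I`` are three-center and ``V`` two-center Coulomb integrals.  Under
the core-valence separation only four MO blocks of ``J`` are ever contracted:
core-core, core-inactive, core-virtual and inactive-virtual.  No stored block
carries two virtual indices, which is what keeps the memory footprint at
``O(n_aux * n_occ * max(n_occ, n_virt))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ShapeMismatchError

__all__ = ["DFTensors", "metric_inverse_sqrt", "fit_coefficients"]

#: Canonical block names, in bundle serialization order.
BLOCK_NAMES = ("J_CC", "J_CO", "J_CV", "J_OV")


@dataclass
class DFTensors:
    """Blockwise density-fitting coefficients ``J_pq^P``.

    Axis convention: ``[aux, first MO index, second MO index]``.

    Attributes
    ----------
    J_CC : (n_aux, n_act, n_act) array
        Active-core x active-core block; symmetric in the two core indices.
    J_CO : (n_aux, n_act, n_inact) array
        Active-core x inactive-occupied block.
    J_CV : (n_aux, n_act, n_virt) array
        Active-core x virtual block.
    J_OV : (n_aux, n_inact, n_virt) array
        Inactive-occupied x virtual block.
    """

    J_CC: np.ndarray
    J_CO: np.ndarray
    J_CV: np.ndarray
    J_OV: np.ndarray

    @property
    def n_aux(self) -> int:
        return self.J_CC.shape[0]

    @property
    def n_act(self) -> int:
        return self.J_CC.shape[1]

    @property
    def n_inact(self) -> int:
        return self.J_CO.shape[2]

    @property
    def n_virt(self) -> int:
        return self.J_CV.shape[2]

    def __post_init__(self):
        for name in BLOCK_NAMES:
            block = getattr(self, name)
            arr = np.ascontiguousarray(np.asarray(block, dtype=np.float64))
            setattr(self, name, arr)
            if arr.ndim != 3:
                raise ShapeMismatchError(f"{name} must be 3-dimensional, got {arr.ndim}")
        P, A = self.J_CC.shape[0], self.J_CC.shape[1]
        if self.J_CC.shape[2] != A:
            raise ShapeMismatchError("J_CC must be square in its core indices")
        for name in ("J_CO", "J_CV", "J_OV"):
            block = getattr(self, name)
            if block.shape[0] != P:
                raise ShapeMismatchError(f"{name} auxiliary dimension {block.shape[0]} != {P}")
        if self.J_CO.shape[1] != A or self.J_CV.shape[1] != A:
            raise ShapeMismatchError("core dimension of J_CO/J_CV disagrees with J_CC")
        if self.J_OV.shape[1] != self.J_CO.shape[2]:
            raise ShapeMismatchError("inactive dimension of J_OV disagrees with J_CO")
        if self.J_OV.shape[2] != self.J_CV.shape[2]:
            raise ShapeMismatchError("virtual dimension of J_OV disagrees with J_CV")

    def blocks(self) -> dict[str, np.ndarray]:
        """Inventory of materialized blocks, keyed by canonical name."""
        return {name: getattr(self, name) for name in BLOCK_NAMES}

    def pair_matrix(self, left: str, right: str) -> np.ndarray:
        """Reconstructed two-electron block ``(pq|rs) = sum_P J_pq^P J_rs^P``.

        ``left``/``right`` name stored blocks (e.g. ``"J_OV"``).  The result
        is indexed ``[pq-pair, rs-pair]`` with pairs flattened row-major.
        """
        L = getattr(self, left).reshape(self.n_aux, -1)
        R = getattr(self, right).reshape(self.n_aux, -1)
        return L.T @ R


def metric_inverse_sqrt(V: np.ndarray, drop_threshold: float = 1e-10) -> np.ndarray:
    """Inverse square root of the two-center Coulomb metric.

    Eigenvectors with eigenvalue at or below ``drop_threshold`` are dropped,
    the standard conditioning guard for near-linearly-dependent auxiliary
    sets.  Returns ``W`` of shape ``(n_aux, n_retained)`` such that
    ``W.T @ V @ W`` is the identity on the retained space.
    """
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ShapeMismatchError(f"metric must be square, got shape {V.shape}")
    if drop_threshold < 0:
        raise ValueError("drop_threshold must be non-negative")
    asym = np.max(np.abs(V - V.T)) if V.size else 0.0
    if asym > 1e-10 * max(1.0, np.max(np.abs(V))):
        raise ValueError(f"metric is not symmetric (max asymmetry {asym:.3e})")
    evals, evecs = np.linalg.eigh(0.5 * (V + V.T))
    keep = evals > drop_threshold
    if not np.any(keep):
        raise ValueError("all metric eigenvalues fall below the drop threshold")
    return evecs[:, keep] / np.sqrt(evals[keep])


def fit_coefficients(
    I3c: dict[str, np.ndarray] | None = None,
    W: np.ndarray | None = None,
    **named_blocks: np.ndarray,
) -> DFTensors:
    """Contract raw three-center integrals with the metric inverse square root.

    Parameters
    ----------
    I3c : mapping of block name -> (n_aux, n1, n2) array
        Raw three-center Coulomb integrals ``I_pq^Q`` for the four CVS blocks,
        keyed ``J_CC``/``J_CO``/``J_CV``/``J_OV`` (the names the fitted blocks
        will take).  Blocks may also be passed as keyword arguments.
    W : (n_aux, n_retained) array
        Output of :func:`metric_inverse_sqrt`.

    Only the four CVS blocks are materialized; a virtual-virtual block is
    structurally impossible to request.
    """
    blocks = dict(I3c or {})
    blocks.update(named_blocks)
    unknown = set(blocks) - set(BLOCK_NAMES)
    if unknown:
        raise ShapeMismatchError(f"unknown DF block(s): {sorted(unknown)}")
    missing = set(BLOCK_NAMES) - set(blocks)
    if missing:
        raise ShapeMismatchError(f"missing DF block(s): {sorted(missing)}")
    if W is None:
        raise ValueError("metric inverse square root W is required")
    W = np.asarray(W, dtype=np.float64)
    fitted = {}
    for name in BLOCK_NAMES:
        raw = np.asarray(blocks[name], dtype=np.float64)
        if raw.ndim != 3 or raw.shape[0] != W.shape[0]:
            raise ShapeMismatchError(
                f"{name}: expected (n_aux={W.shape[0]}, *, *), got {raw.shape}"
            )
        # J_pq^P = sum_Q I_pq^Q W_QP ; retained aux index comes first.
        fitted[name] = np.einsum("qij,qp->pij", raw, W, optimize=True)
    return DFTensors(**fitted)
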