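"""Iterative CVS-IP-ADC(2): the folded, energy-dependent eigenproblem.

The ADC(2) ionization energies solve the nonlinear equation
``A(omega) c = omega c`` in the active-core singles space, where folding the
2h1p block into the singles block makes the effective Jacobian depend on its
own eigenvalue.  Each sigma-vector evaluation is

    sigma_I = -eps_I c_I
              - sum_{KQ} J_IK^Q sum_{ja} J_ja^Q (2 c_{K,ja} - c_{Ka,j})
              - sum_{kQ} J_Ik^Q sum_{Ja} J_Ja^Q (2 c_{Ja,k} - c_{J,ka})

with vector-contracted couplings ``V_{K,ja} = -sum_{LQ} J_LK^Q c_L J_ja^Q``
and ``V_{Ka,j} = -sum_{LQ} J_Ka^Q J_Lj^Q c_L`` and doubles coefficients
``c = V / (eps_K + eps_j - eps_a + omega)`` evaluated at the current
ionization energy.  Spin scaling replaces the ``(2c - c')`` combination by
``c_os*c + c_ss*(c - c')`` channelwise.

Because the core-valence separation shrinks the singles space to a handful
of core orbitals, the solver builds the small effective matrix explicitly
(one sigma application per unit vector) and diagonalizes it densely inside a
plain fixed-point loop on omega, with root homing by eigenvector-overlap
continuity — mathematically identical to a Davidson treatment of the same
folded problem, and exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cis_d import IPResult, _check_df, _denominators, _partition_energies
from .df import DFTensors
from .exceptions import ConvergenceError, PartitionError, ShapeMismatchError
from .partition import OrbitalPartition
from .reference import ScfReference
from .scaling import ScalingSpec

__all__ = [
    "EffectiveMatrix",
    "SolverOptions",
    "sigma_apply",
    "build_effective_matrix",
    "solve_adc2",
]


@dataclass
class EffectiveMatrix:
    """The folded Jacobian evaluated at a fixed fold-in energy.

    Symmetric to tight tolerance for a real reference; built column-by-column
    from sigma applications to unit vectors and explicitly symmetrized.
    """

    M: np.ndarray
    omega: float


@dataclass
class SolverOptions:
    """Self-consistency controls for the fixed-point iteration on omega."""

    omega_tol: float = 1e-6  # Hartree
    max_macro_iterations: int = 50
    damping: float = 0.0  # mixing of the previous omega into the update
    root_selection: str = "max-overlap"
    raise_on_nonconvergence: bool = True

    def __post_init__(self):
        if self.omega_tol <= 0:
            raise ValueError("omega_tol must be positive")
        if not (0.0 <= self.damping < 1.0):
            raise ValueError("damping must lie in [0, 1)")
        if self.max_macro_iterations < 1:
            raise ValueError("max_macro_iterations must be >= 1")


def sigma_apply(
    c: np.ndarray,
    omega: float,
    df: DFTensors,
    eps_core: np.ndarray,
    eps_inact: np.ndarray,
    eps_virt: np.ndarray,
    scaling: ScalingSpec,
) -> np.ndarray:
    """One matrix-vector product with the folded Jacobian at energy ``omega``.

    Cost is ``O(n_act * n_inact * n_virt * n_aux)``, the same scaling as the
    perturbative correction; no array with two virtual indices appears.
    """
    c = np.asarray(c, dtype=np.float64).ravel()
    if c.size != df.n_act:
        raise ShapeMismatchError(f"singles vector length {c.size} != n_act {df.n_act}")
    if not np.any(c):
        raise ValueError("singles vector must be nonzero")
    eps_core = np.asarray(eps_core, dtype=np.float64)
    eps_inact = np.asarray(eps_inact, dtype=np.float64)
    eps_virt = np.asarray(eps_virt, dtype=np.float64)

    sigma = -eps_core * c
    if scaling.is_koopmans_limit():
        return sigma

    # vector-contracted couplings; J_CC is symmetric in its two core indices
    V1 = -np.einsum("qk,qja->kja", np.einsum("qlk,l->qk", df.J_CC, c), df.J_OV, optimize=True)
    V2 = -np.einsum("qka,qj->kaj", df.J_CV, np.einsum("qlj,l->qj", df.J_CO, c), optimize=True)

    D = _denominators(eps_core, eps_inact, eps_virt, float(omega))
    c1 = V1 / D
    c2 = V2 / D.transpose(0, 2, 1)

    g1 = scaling.c_os * c1 + scaling.c_ss * (c1 - c2.transpose(0, 2, 1))
    g2 = scaling.c_os * c2 + scaling.c_ss * (c2 - c1.transpose(0, 2, 1))

    U1 = np.einsum("qja,kja->qk", df.J_OV, g1, optimize=True)
    sigma -= np.einsum("qik,qk->i", df.J_CC, U1, optimize=True)
    U2 = np.einsum("qja,jak->qk", df.J_CV, g2, optimize=True)
    sigma -= np.einsum("qik,qk->i", df.J_CO, U2, optimize=True)
    return sigma


def build_effective_matrix(
    omega: float,
    df: DFTensors,
    eps_core: np.ndarray,
    eps_inact: np.ndarray,
    eps_virt: np.ndarray,
    scaling: ScalingSpec,
) -> EffectiveMatrix:
    """Assemble the dense folded Jacobian at ``omega`` by unit-vector sigmas."""
    n = df.n_act
    if n < 1:
        raise PartitionError("active core set is empty")
    M = np.empty((n, n))
    eye = np.eye(n)
    for k in range(n):
        M[:, k] = sigma_apply(eye[:, k], omega, df, eps_core, eps_inact, eps_virt, scaling)
    asym = float(np.max(np.abs(M - M.T))) if n > 1 else 0.0
    if asym > 1e-8:
        warnings.warn(
            f"effective Jacobian asymmetry {asym:.3e} exceeds 1e-8 "
            "(is the core-core DF block symmetric?)",
            stacklevel=2,
        )
    return EffectiveMatrix(M=0.5 * (M + M.T), omega=float(omega))


def solve_adc2(
    ref: ScfReference,
    partition: OrbitalPartition,
    df: DFTensors,
    scaling: ScalingSpec,
    opts: SolverOptions | None = None,
) -> list[IPResult]:
    """Self-consistent CVS-IP-ADC(2) energies, one root per active core.

    Root ``m`` starts from the Koopmans guess ``omega = -eps_m`` and iterates
    ``omega <- (1 - damping) * lambda_m(M(omega)) + damping * omega``, where
    the eigenpair is chosen by maximal overlap with the previous iterate's
    eigenvector (the unit guess on the first pass) under a one-to-one
    root-to-eigenpair matching, until successive omegas agree within
    ``omega_tol`` for every root.
    """
    from scipy.optimize import linear_sum_assignment

    opts = opts or SolverOptions()
    _check_df(partition, df)
    eps_core, eps_inact, eps_virt = _partition_energies(ref, partition)
    n = partition.n_act

    # All roots iterate together.  Each root keeps its own fold-in energy and
    # eigenvector; at every macro iteration the eigenpairs of M(omega_m) are
    # assigned to roots by a maximum-overlap bipartite matching, so two roots
    # entering a near-degenerate core block can never collapse onto the same
    # eigenstate (independent per-root argmax homing can, once their fold-in
    # energies drift together).
    omegas = -np.asarray(eps_core, dtype=np.float64).copy()
    vecs = np.eye(n)  # column m: current eigenvector of root m
    deltas = np.full(n, np.inf)
    n_iter = 0
    for n_iter in range(1, opts.max_macro_iterations + 1):
        cand_vals = np.empty((n, n))  # row m: eigenvalues of M(omega_m)
        cand_vecs = np.empty((n, n, n))
        overlap = np.empty((n, n))
        for m in range(n):
            eff = build_effective_matrix(
                omegas[m], df, eps_core, eps_inact, eps_virt, scaling
            )
            evals, evecs = np.linalg.eigh(eff.M)
            cand_vals[m], cand_vecs[m] = evals, evecs
            overlap[m] = np.abs(vecs[:, m] @ evecs)
        rows, cols = linear_sum_assignment(-overlap)
        new_omegas = np.empty(n)
        for m, k in zip(rows, cols):
            lam = cand_vals[m, k]
            v = cand_vecs[m][:, k]
            if v @ vecs[:, m] < 0:  # fix the arbitrary eigenvector sign
                v = -v
            vecs[:, m] = v
            new_omegas[m] = (1.0 - opts.damping) * lam + opts.damping * omegas[m]
        deltas = np.abs(new_omegas - omegas)
        omegas = new_omegas
        if np.all(deltas < opts.omega_tol):
            break
    converged = bool(np.all(deltas < opts.omega_tol))

    results = []
    for pos, idx in enumerate(partition.active_core):
        result = IPResult(
            omega=float(omegas[pos]),
            method_tag=f"ip-adc(2)/{scaling.provenance}",
            orbital_index=idx,
            epsilon=float(eps_core[pos]),
            singles_vector=vecs[:, pos].copy(),
            converged=converged,
            iterations=n_iter,
            correction=float(omegas[pos] + eps_core[pos]),
        )
        results.append(result)
    if not converged and opts.raise_on_nonconvergence:
        raise ConvergenceError(
            f"omega self-consistency not reached in {opts.max_macro_iterations} "
            f"iterations (residual max |delta omega| = {deltas.max():.3e} Eh)",
            diagnostics=results,
        )
    return results
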