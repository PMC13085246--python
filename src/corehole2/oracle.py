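"""Dense spin-orbital brute-force reference implementations.

The production solvers are spin-adapted and density-fitted; this module
rebuilds the same physics the slow, explicit way and serves as the
independent check for every contraction:

* the full symmetric Hamiltonian over the CVS-restricted (n-1)-electron
  configuration space — one core hole (1h) plus core-hole/valence-hole/
  particle triples (2h1p) — is assembled in spin orbitals from
  antisymmetrized four-center integrals;
* its eigenvalues are the self-consistent folded-solver energies by the
  block-elimination identity, without any omega iteration;
* the diagonal second-order self-energy at a frozen frequency reproduces the
  perturbative (D) correction.

Agreement between the spatial ``(2c - c')`` contractions and this spin-orbital
path is a genuine cross-check of the spin adaptation and of the
opposite-spin/same-spin split: here the channels are scaled by weighting the
*spin cases* of the coupling block (the opposite-spin cases carry
``sqrt(c_os)``, the same-spin case ``sqrt(c_ss)``), not by reusing the
production decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .df import DFTensors
from .exceptions import SingularDenominatorError

__all__ = [
    "DenseCvsProblem",
    "spatial_integrals_from_df",
    "oracle_solve_linear",
    "oracle_self_energy_diag",
]


def spatial_integrals_from_df(df: DFTensors) -> tuple[np.ndarray, np.ndarray]:
    """Four-center spatial integrals reconstructed from DF blocks.

    Returns ``(g_ckja, g_cajk)`` with ``g_ckja[I,K,j,a] = (IK|ja)`` and
    ``g_cajk[I,a,j,K] = (Ia|jK)``.  Dense rank-4 arrays — oracle-sized
    systems only.
    """
    g_ckja = np.einsum("pik,pja->ikja", df.J_CC, df.J_OV, optimize=True)
    g_cajk = np.einsum("pia,pkj->iajk", df.J_CV, df.J_CO, optimize=True)
    return g_ckja, g_cajk


@dataclass
class DenseCvsProblem:
    """Symmetric Hamiltonian over the spin-orbital 1h + 2h1p CVS space.

    Layout: the first ``n_act`` rows are the 1h configurations (one beta core
    hole per active core orbital).  The remaining rows are 2h1p
    configurations enumerated as (spin case, I, j, a) with three spin cases
    per spatial triple: (I-beta, j-beta -> a-beta) — the same-spin case —
    then (I-beta, j-alpha -> a-alpha) and (I-alpha, j-beta -> a-alpha), the
    opposite-spin cases.  The singles block is ``diag(-eps_I)``, the doubles
    block is diagonal with ``-(eps_I + eps_j - eps_a)``, and the coupling
    block carries the antisymmetrized integrals ``<Ij||aK>`` spin-resolved,
    consistent with the spatial coupling ``V_{ia,j} = -(ia|jk)``.
    """

    H: np.ndarray
    n_act: int
    doubles_diag: np.ndarray  # view of the 2h1p diagonal, for folding

    @classmethod
    def build(
        cls,
        eps_core: np.ndarray,
        eps_inact: np.ndarray,
        eps_virt: np.ndarray,
        g_ckja: np.ndarray,
        g_cajk: np.ndarray,
        c_os: float = 1.0,
        c_ss: float = 1.0,
    ) -> "DenseCvsProblem":
        """Assemble the dense problem from explicit four-center integrals.

        ``g_ckja[I,K,j,a] = (IK|ja)`` and ``g_cajk[I,a,j,K] = (Ia|jK)`` may
        come from :func:`spatial_integrals_from_df` or from an exact
        four-center construction.  ``c_os``/``c_ss`` scale the opposite- and
        same-spin coupling cases by their square roots, so folded
        contributions scale linearly; negative factors are rejected.
        """
        if c_os < 0 or c_ss < 0:
            raise ValueError("channel factors must be non-negative for the dense oracle")
        eps_core = np.asarray(eps_core, dtype=np.float64)
        eps_inact = np.asarray(eps_inact, dtype=np.float64)
        eps_virt = np.asarray(eps_virt, dtype=np.float64)
        nC, nO, nV = eps_core.size, eps_inact.size, eps_virt.size
        n2 = 3 * nC * nO * nV
        dim = nC + n2
        H = np.zeros((dim, dim))
        H[:nC, :nC] = np.diag(-eps_core)

        # doubles diagonal: -(eps_I + eps_j - eps_a), identical per spin case
        d_spatial = -(
            eps_core[:, None, None] + eps_inact[None, :, None] - eps_virt[None, None, :]
        )
        doubles_diag = np.tile(d_spatial.ravel(), 3)
        H[nC:, nC:] = np.diag(doubles_diag)

        # coupling <I_s1 j_s2 || a_s3 K_beta> resolved into the three spin cases
        # (direct term (Ia|jK) needs s1==s3, s2==beta; exchange (IK|ja) needs
        # s1==beta, s2==s3)
        s_ss, s_os = np.sqrt(c_ss), np.sqrt(c_os)
        # case (b, b -> b): (Ia|jK) - (IK|ja)
        C1 = s_ss * (g_cajk.transpose(0, 2, 1, 3) - g_ckja.transpose(0, 2, 3, 1))
        # case (b, a -> a): -(IK|ja)
        C2 = s_os * (-g_ckja.transpose(0, 2, 3, 1))
        # case (a, b -> a): (Ia|jK)
        C3 = s_os * g_cajk.transpose(0, 2, 1, 3)
        # each C*[I,j,a,K]; stack into the (config, K) coupling block
        coupling = np.concatenate(
            [C.reshape(nC * nO * nV, nC) for C in (C1, C2, C3)], axis=0
        )
        H[:nC, nC:] = coupling.T
        H[nC:, :nC] = coupling
        return cls(H=H, n_act=nC, doubles_diag=doubles_diag)


def oracle_solve_linear(problem: DenseCvsProblem, target: int) -> float:
    """Ionization energy for the state dominated by the target 1h config.

    Diagonalizes the full symmetric Hamiltonian and returns the eigenvalue
    whose eigenvector has maximal weight on 1h configuration ``target``.
    By the block-elimination identity this equals the self-consistent
    eigenvalue of the folded omega-dependent problem.
    """
    evals, evecs = np.linalg.eigh(problem.H)
    weights = evecs[target, :] ** 2
    return float(evals[int(np.argmax(weights))])


def oracle_self_energy_diag(problem: DenseCvsProblem, target: int, omega: float) -> float:
    """Diagonal second-order self-energy element at a frozen frequency.

    Returns the (target, target) element of
    ``A_12 (omega*1 - D_0)^{-1} A_21`` from the dense blocks; adding it to
    the Koopmans value at ``omega = -eps_target`` gives the perturbative
    second-order ionization energy.
    """
    n1 = problem.n_act
    coupling = problem.H[target, n1:]
    denom = omega - problem.doubles_diag
    bad = np.abs(denom) <= 1e-6
    if np.any(bad):
        raise SingularDenominatorError(
            f"omega = {omega:.6f} Eh hits a doubles diagonal within 1e-6 Eh"
        )
    return float(np.sum(coupling**2 / denom))
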