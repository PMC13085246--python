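"""Core-level IP-CIS and the perturbative CVS-(D) second-order correction.

At the IP-CIS level the ionization energy from a core orbital ``K`` is the
Koopmans value ``omega_K = -eps_K`` — for a Kohn-Sham reference just as for
Hartree-Fock, since exchange-correlation contributions enter only through
the reference orbitals.  The (D) correction adds the second-order doubles
contribution evaluated non-iteratively at that frequency:

    omega_K^(D) = sum_{Ija} V_{I,ja}^K (2 c_{I,ja} - c_{Ia,j})
                + sum_{Ija} V_{Ia,j}^K (2 c_{Ia,j} - c_{I,ja})

with the two coupling classes built from density-fitting blocks,

    V_{I,ja}^K = -sum_Q J_IK^Q J_ja^Q,    V_{Ia,j}^K = -sum_Q J_Ia^Q J_jK^Q,

and doubles coefficients ``c = V / (eps_I + eps_j - eps_a + omega)``.  Under
the core-valence separation with a frozen chemical core the ground-state
doubles amplitudes drop out, so these two classes are the entire correction.
This equals the diagonal, frequency-independent second-order self-energy
evaluated at the Koopmans pole (the "delta-MP2" view), which the dense
oracle checks independently.

The opposite-spin / same-spin split used for spin scaling is
``OS = sum V*c`` and ``SS = sum V*(c - c')`` with ``c'`` the
exchange-permuted coefficient, so (1, 1) recovers the expression above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .df import DFTensors
from .exceptions import PartitionError, ShapeMismatchError, SingularDenominatorError
from .partition import OrbitalPartition
from .reference import HARTREE_TO_EV, ScfReference
from .scaling import ScalingSpec

__all__ = [
    "VIntermediates",
    "DoublesBlock",
    "IPResult",
    "ip_cis",
    "build_v_perturbative",
    "doubles_coefficients",
    "d_correction",
    "cis_d_ionization",
]

#: Doubles denominators below this magnitude (Hartree) raise a hard error.
DENOMINATOR_GUARD = 1e-6


@dataclass
class VIntermediates:
    """The two coupling classes of the second-order correction.

    ``V_cja[I, j, a]`` holds ``V_{I,ja}^K`` and ``V_caj[I, a, j]`` holds
    ``V_{Ia,j}^K``.  ``target_K`` is the active-core position the couplings
    refer to, or ``"vector"`` when they were contracted with a singles
    vector (the iterative ADC case).
    """

    V_cja: np.ndarray
    V_caj: np.ndarray
    target_K: int | str = 0

    def __post_init__(self):
        self.V_cja = np.asarray(self.V_cja, dtype=np.float64)
        self.V_caj = np.asarray(self.V_caj, dtype=np.float64)
        if self.V_cja.ndim != 3 or self.V_caj.ndim != 3:
            raise ShapeMismatchError("V intermediates must be rank-3")
        if self.V_cja.shape != (
            self.V_caj.shape[0],
            self.V_caj.shape[2],
            self.V_caj.shape[1],
        ):
            raise ShapeMismatchError(
                f"V_cja {self.V_cja.shape} and V_caj {self.V_caj.shape} are inconsistent"
            )
        if not (np.all(np.isfinite(self.V_cja)) and np.all(np.isfinite(self.V_caj))):
            raise ValueError("V intermediates must be finite")


@dataclass
class DoublesBlock:
    """2h1p coefficients ``c_{I,ja}`` / ``c_{Ia,j}`` at a fixed frequency.

    The two blocks are independent; no antisymmetry is assumed.
    ``omega_used`` records the energy the denominators were evaluated at.
    """

    c_cja: np.ndarray
    c_caj: np.ndarray
    omega_used: float

    def exchange_permuted(self) -> tuple[np.ndarray, np.ndarray]:
        """(c'_cja, c'_caj): each block reindexed to the other's layout."""
        return self.c_caj.transpose(0, 2, 1), self.c_cja.transpose(0, 2, 1)


@dataclass
class IPResult:
    """One converged ionization energy with diagnostics."""

    omega: float  # Hartree
    method_tag: str
    orbital_index: int  # spatial-orbital index in the full MO range
    epsilon: float  # Hartree, the targeted orbital energy
    singles_vector: np.ndarray = field(default_factory=lambda: np.ones(1))
    converged: bool = True
    iterations: int = 0
    correction: float = 0.0  # second-order part, Hartree

    @property
    def omega_ev(self) -> float:
        return self.omega * HARTREE_TO_EV


def _partition_energies(ref: ScfReference, partition: OrbitalPartition):
    eps = ref.orbital_energies
    return (
        eps[list(partition.active_core)],
        eps[list(partition.inactive_occ)],
        eps[list(partition.virtual)],
    )


def _check_df(partition: OrbitalPartition, df: DFTensors) -> None:
    if (df.n_act, df.n_inact, df.n_virt) != (
        partition.n_act,
        partition.n_inact,
        partition.n_virt,
    ):
        raise ShapeMismatchError(
            f"DF blocks sized (act={df.n_act}, inact={df.n_inact}, virt={df.n_virt}) "
            f"disagree with partition ({partition.n_act}, {partition.n_inact}, "
            f"{partition.n_virt})"
        )


def ip_cis(ref: ScfReference, partition: OrbitalPartition) -> list[IPResult]:
    """Koopmans-level ionization energies: one state per active core orbital,
    ``omega = -eps_K``, unit singles vectors.  Valid for HF and KS references
    alike; nothing beyond the orbital energies is touched."""
    if not partition.active_core:
        raise PartitionError("active core set is empty")
    results = []
    for pos, idx in enumerate(partition.active_core):
        vec = np.zeros(partition.n_act)
        vec[pos] = 1.0
        eps_k = float(ref.orbital_energies[idx])
        results.append(
            IPResult(
                omega=-eps_k,
                method_tag="ip-cis",
                orbital_index=idx,
                epsilon=eps_k,
                singles_vector=vec,
            )
        )
    return results


def build_v_perturbative(df: DFTensors, K: int) -> VIntermediates:
    """Couplings ``V_{I,ja}^K`` and ``V_{Ia,j}^K`` for target core ``K``.

    ``K`` is the position of the target within the active-core block.
    Cost is ``O(n_act * n_inact * n_virt * n_aux)``.
    """
    if not (0 <= K < df.n_act):
        raise PartitionError(f"target K={K} outside active-core block of size {df.n_act}")
    V_cja = -np.einsum("pi,pja->ija", df.J_CC[:, :, K], df.J_OV, optimize=True)
    V_caj = -np.einsum("pia,pj->iaj", df.J_CV, df.J_CO[:, K, :], optimize=True)
    return VIntermediates(V_cja=V_cja, V_caj=V_caj, target_K=K)


def _denominators(eps_core, eps_inact, eps_virt, omega: float) -> np.ndarray:
    """D[I, j, a] = eps_I + eps_j - eps_a + omega, with the singularity guard."""
    D = (
        eps_core[:, None, None]
        + eps_inact[None, :, None]
        - eps_virt[None, None, :]
        + omega
    )
    bad = np.abs(D) <= DENOMINATOR_GUARD
    if np.any(bad):
        I, j, a = (int(x) for x in np.argwhere(bad)[0])
        raise SingularDenominatorError(
            f"doubles denominator |D| <= {DENOMINATOR_GUARD:g} Eh at (core={I}, "
            f"inactive={j}, virtual={a}): D = {D[I, j, a]:.3e} Eh at omega = {omega:.6f} Eh",
            triple=(I, j, a),
        )
    return D


def doubles_coefficients(
    V: VIntermediates,
    eps_core: np.ndarray,
    eps_inact: np.ndarray,
    eps_virt: np.ndarray,
    omega: float,
) -> DoublesBlock:
    """Elementwise ``c = V / D`` for both coupling classes at energy ``omega``."""
    D = _denominators(
        np.asarray(eps_core, dtype=np.float64),
        np.asarray(eps_inact, dtype=np.float64),
        np.asarray(eps_virt, dtype=np.float64),
        float(omega),
    )
    return DoublesBlock(
        c_cja=V.V_cja / D,
        c_caj=V.V_caj / D.transpose(0, 2, 1),
        omega_used=float(omega),
    )


def d_correction(V: VIntermediates, c2: DoublesBlock, scaling: ScalingSpec) -> float:
    """Spin-scaled second-order correction energy (Hartree).

    ``c_os * (sum V*c) + c_ss * (sum V*(c - c'))`` over both coupling
    classes; with (1, 1) this is the plain correction
    ``sum V_cja (2c_cja - c_caj) + sum V_caj (2c_caj - c_cja)``.
    """
    if V.V_cja.shape != c2.c_cja.shape or V.V_caj.shape != c2.c_caj.shape:
        raise ShapeMismatchError("V and doubles blocks have mismatched shapes")
    cp_cja, cp_caj = c2.exchange_permuted()
    os_part = float(np.sum(V.V_cja * c2.c_cja) + np.sum(V.V_caj * c2.c_caj))
    ss_part = float(
        np.sum(V.V_cja * (c2.c_cja - cp_cja)) + np.sum(V.V_caj * (c2.c_caj - cp_caj))
    )
    return scaling.c_os * os_part + scaling.c_ss * ss_part


def cis_d_ionization(
    ref: ScfReference,
    partition: OrbitalPartition,
    df: DFTensors,
    scaling: ScalingSpec,
) -> list[IPResult]:
    """CVS-IP-CIS(D) energies for every active core orbital.

    The doubles denominators are evaluated once, at the IP-CIS frequency
    ``omega = -eps_K``, and never iterated — that is what distinguishes the
    perturbative method from the self-consistent ADC(2) solver.
    """
    _check_df(partition, df)
    eps_core, eps_inact, eps_virt = _partition_energies(ref, partition)
    results = []
    for pos, idx in enumerate(partition.active_core):
        omega0 = -float(ref.orbital_energies[idx])
        V = build_v_perturbative(df, pos)
        c2 = doubles_coefficients(V, eps_core, eps_inact, eps_virt, omega0)
        corr = d_correction(V, c2, scaling)
        vec = np.zeros(partition.n_act)
        vec[pos] = 1.0
        results.append(
            IPResult(
                omega=omega0 + corr,
                method_tag=f"ip-cis(d)/{scaling.provenance}",
                orbital_index=idx,
                epsilon=-omega0,
                singles_vector=vec,
                correction=corr,
            )
        )
    return results
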