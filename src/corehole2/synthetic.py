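"""Seeded synthetic systems standing in for backend-derived inputs.

A synthetic system mimics the data a converged closed-shell reference plus
MO-basis density fitting would deliver: orbital energies with a clear
core-valence gap (deep active-core levels, valence-like inactive occupied
and virtual levels) and random three-center tensors fitted over a generated
symmetric-positive-definite Coulomb metric.  The coupling scale is kept
small relative to the core gap so second-order shifts are a small fraction
of the ionization energy and the self-consistent fold-in iteration stays
contractive — these fixtures are meant to exercise the solvers, not to break
them.  Everything is reproducible bit-exactly from (sizes, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .df import DFTensors, fit_coefficients, metric_inverse_sqrt
from .partition import OrbitalPartition
from .reference import ScfReference

__all__ = ["SyntheticSystem", "generate_fixture"]


@dataclass
class SyntheticSystem:
    """A self-contained fake reference: energies, DF blocks, partition info."""

    eps_core: np.ndarray
    eps_inact: np.ndarray
    eps_virt: np.ndarray
    df: DFTensors
    metric: np.ndarray
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int, int]:
        return (self.eps_core.size, self.eps_inact.size, self.eps_virt.size, self.df.n_aux)

    def reference(self) -> ScfReference:
        """Assemble an :class:`ScfReference` (no frozen orbitals)."""
        eps = np.concatenate([self.eps_core, self.eps_inact, self.eps_virt])
        return ScfReference(
            orbital_energies=eps,
            n_occupied=self.eps_core.size + self.eps_inact.size,
            atom_labels=["X"],
            reference_kind="HF",
        )

    def partition(self) -> OrbitalPartition:
        n_act, n_inact, n_virt, _ = self.sizes
        return OrbitalPartition(
            frozen=(),
            active_core=range(n_act),
            inactive_occ=range(n_act, n_act + n_inact),
            virtual=range(n_act + n_inact, n_act + n_inact + n_virt),
            selector_provenance={"mode": "synthetic", "seed": self.seed},
        )


def generate_fixture(
    sizes: tuple[int, int, int, int],
    seed: int,
    core_center: float = -10.0,
    core_spread: float = 0.1,
    inact_range: tuple[float, float] = (-1.0, -0.3),
    virt_range: tuple[float, float] = (0.2, 2.0),
    coupling_scale: float = 0.1,
) -> SyntheticSystem:
    """Generate a reproducible synthetic system.

    Parameters
    ----------
    sizes : (n_act, n_inact, n_virt, n_aux)
        Partition block sizes, each >= 1.
    seed : int
        Seeds a dedicated :func:`numpy.random.default_rng`.
    core_center, core_spread : float, Hartree
        Active-core energies are drawn uniformly in
        ``core_center +- core_spread``; the default -10 Eh puts the core well
        below the valence window, as for a second-row 1s level in a modest
        basis.  The default spread (0.1 Eh) keeps every fold-in denominator
        ``eps_I + eps_j - eps_a + omega`` bounded away from zero for
        near-Koopmans omega (the smallest inactive-to-virtual gap is 0.5 Eh),
        so the self-consistent iteration stays contractive — fixtures are
        meant to exercise the solver, not to park it on a shake-up resonance.
    inact_range, virt_range : (low, high), Hartree
        Uniform windows for the inactive occupied and virtual energies.
    coupling_scale : float
        Standard deviation of the raw three-center integrals; small enough
        that second-order shifts stay well below the core gap.

    Raises
    ------
    ValueError
        If any size is < 1 or the energy windows leave no core-valence gap.
    """
    n_act, n_inact, n_virt, n_aux = (int(s) for s in sizes)
    if min(n_act, n_inact, n_virt, n_aux) < 1:
        raise ValueError(f"all sizes must be >= 1, got {sizes}")
    if core_center + core_spread >= inact_range[0]:
        raise ValueError(
            f"degenerate gap settings: core window reaches {core_center + core_spread} Eh, "
            f"inactive window starts at {inact_range[0]} Eh"
        )
    if inact_range[0] >= inact_range[1] or virt_range[0] >= virt_range[1]:
        raise ValueError("energy windows must be increasing (low, high) pairs")

    rng = np.random.default_rng(seed)
    eps_core = np.sort(rng.uniform(core_center - core_spread, core_center + core_spread, n_act))
    eps_inact = np.sort(rng.uniform(*inact_range, n_inact))
    eps_virt = np.sort(rng.uniform(*virt_range, n_virt))

    # SPD metric: Gram matrix of random vectors plus a ridge for conditioning
    A = rng.standard_normal((n_aux, n_aux))
    metric = A @ A.T + 0.1 * np.eye(n_aux)

    # Raw three-center integrals are drawn on the metric's natural scale,
    # I = V^(1/2) B with B standard-normal: physical Coulomb three-center
    # integrals lie in the metric's range, and the fitted J = W^T I is then
    # an orthogonal transform of B, keeping couplings at coupling_scale
    # instead of blowing up along weak metric directions.
    evals_m, evecs_m = np.linalg.eigh(metric)
    sqrt_metric = (evecs_m * np.sqrt(evals_m)) @ evecs_m.T

    def draw(shape):
        return np.einsum(
            "qp,pij->qij", sqrt_metric, rng.normal(0.0, coupling_scale, shape)
        )

    raw_cc = draw((n_aux, n_act, n_act))
    raw_cc = 0.5 * (raw_cc + raw_cc.transpose(0, 2, 1))  # (IK| pair symmetry
    raw = {
        "J_CC": raw_cc,
        "J_CO": draw((n_aux, n_act, n_inact)),
        "J_CV": draw((n_aux, n_act, n_virt)),
        "J_OV": draw((n_aux, n_inact, n_virt)),
    }
    W = metric_inverse_sqrt(metric)
    df = fit_coefficients(raw, W)
    return SyntheticSystem(
        eps_core=eps_core,
        eps_inact=eps_inact,
        eps_virt=eps_virt,
        df=df,
        metric=metric,
        seed=seed,
    )
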