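import numpy as np
import pytest

from corehole2 import DFTensors, OrbitalPartition, ScfReference


@pytest.fixture
def toy_t1():
    """Minimal hand-checkable system: one auxiliary channel, one active core,
    one inactive occupied, one virtual orbital.

    J_II = 1.0, J_ja = 0.1, J_Ia = 0.2, J_jI = 0.3;
    eps = (-10, -0.5, +0.5) Hartree.  All second-order quantities follow by
    hand: V_cja = -0.10, V_caj = -0.06, and at omega = 10 the denominator is
    exactly -1, giving a (D) correction of -0.0152 Eh.
    """
    df = DFTensors(
        J_CC=np.array([[[1.0]]]),
        J_CO=np.array([[[0.3]]]),
        J_CV=np.array([[[0.2]]]),
        J_OV=np.array([[[0.1]]]),
    )
    ref = ScfReference(
        orbital_energies=np.array([-10.0, -0.5, 0.5]),
        n_occupied=2,
        atom_labels=["X"],
    )
    partition = OrbitalPartition(
        frozen=(), active_core=(0,), inactive_occ=(1,), virtual=(2,)
    )
    return ref, partition, df


@pytest.fixture
def sweep_sizes():
    """Reproducible random block sizes for the oracle-equivalence sweep."""

    def _sizes(seed):
        r = np.random.default_rng(seed + 1000)
        return (
            int(r.integers(1, 4)),
            int(r.integers(1, 7)),
            int(r.integers(1, 7)),
            int(r.integers(1, 11)),
        )

    return _sizes


def make_exact_df_system(seed=3, n_act=1, n_inact=2, n_virt=2):
    """A <=6-orbital system whose auxiliary basis spans the full pair space.

    The exact four-center integral matrix over all orbital pairs is a random
    symmetric positive-definite Gram matrix; choosing the auxiliary index to
    run over the symmetric pairs with three-center integrals I = K and metric
    V = K makes the density fit exact: J J^T = K V^{-1} K^T = K.

    Returns (eps_core, eps_inact, eps_virt, df, pair_integral) where
    pair_integral(p, q, r, s) looks up the exact (pq|rs).
    """
    rng = np.random.default_rng(seed)
    n_orb = n_act + n_inact + n_virt
    pairs = [(p, q) for p in range(n_orb) for q in range(p, n_orb)]
    pair_pos = {}
    for k, (p, q) in enumerate(pairs):
        pair_pos[(p, q)] = k
        pair_pos[(q, p)] = k
    npair = len(pairs)
    G = rng.standard_normal((npair, 3 * npair))
    K = G @ G.T * 0.001  # exact (pq|rs) on the symmetric-pair space, SPD

    def pair_integral(p, q, r, s):
        return K[pair_pos[(p, q)], pair_pos[(r, s)]]

    core = list(range(n_act))
    inact = list(range(n_act, n_act + n_inact))
    virt = list(range(n_act + n_inact, n_orb))

    def raw_block(left, right):
        out = np.empty((npair, len(left), len(right)))
        for i, p in enumerate(left):
            for j, q in enumerate(right):
                out[:, i, j] = K[:, pair_pos[(p, q)]]
        return out

    from corehole2 import fit_coefficients, metric_inverse_sqrt

    W = metric_inverse_sqrt(K, drop_threshold=1e-10)
    df = fit_coefficients(
        {
            "J_CC": raw_block(core, core),
            "J_CO": raw_block(core, inact),
            "J_CV": raw_block(core, virt),
            "J_OV": raw_block(inact, virt),
        },
        W,
    )
    eps_core = np.linspace(-10.0, -9.9, n_act)
    eps_inact = np.linspace(-0.9, -0.4, n_inact)
    eps_virt = np.linspace(0.3, 1.5, n_virt)
    return eps_core, eps_inact, eps_virt, df, pair_integral
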