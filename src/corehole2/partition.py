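"""Orbital partitioning for the core-valence separation.

Spatial orbitals are split into four disjoint sets: frozen core, active core
(the orbitals the ionization targets, labels ``I``, ``K``), inactive occupied
(all other correlated occupied orbitals, labels ``i``, ``j``, ``k``) and
virtual (``a``, ``b``).  The separation is enforced by index-range
restriction: downstream code only ever contracts integrals whose occupied
indices carry at most one active-core hole, so couplings that the
integral-based core-valence separation discards are never even built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import PartitionError
from .reference import ScfReference

__all__ = ["OrbitalPartition", "select_active_core", "parse_selector"]

# Occupied orbitals below this energy (Hartree) count as chemical core and
# are frozen by default when not targeted; configurable per call.
DEFAULT_CORE_FREEZE_CUTOFF = -5.0


@dataclass
class OrbitalPartition:
    """Disjoint frozen / active-core / inactive-occupied / virtual index sets."""

    frozen: tuple[int, ...]
    active_core: tuple[int, ...]
    inactive_occ: tuple[int, ...]
    virtual: tuple[int, ...]
    selector_provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frozen = tuple(sorted(int(i) for i in self.frozen))
        self.active_core = tuple(sorted(int(i) for i in self.active_core))
        self.inactive_occ = tuple(sorted(int(i) for i in self.inactive_occ))
        self.virtual = tuple(sorted(int(i) for i in self.virtual))
        if not self.active_core:
            raise PartitionError("active core set must be nonempty")
        sets = [self.frozen, self.active_core, self.inactive_occ, self.virtual]
        flat = [i for s in sets for i in s]
        if len(set(flat)) != len(flat):
            raise PartitionError("partition sets are not disjoint")

    @property
    def n_act(self) -> int:
        return len(self.active_core)

    @property
    def n_inact(self) -> int:
        return len(self.inactive_occ)

    @property
    def n_virt(self) -> int:
        return len(self.virtual)

    def validate_against(self, ref: ScfReference) -> None:
        """Check completeness and the CVS energy-ordering invariant."""
        n = ref.n_basis
        flat = sorted(self.frozen + self.active_core + self.inactive_occ + self.virtual)
        if flat != list(range(n)):
            raise PartitionError("partition does not cover all spatial orbitals exactly once")
        occ = set(range(ref.n_occupied))
        for i in self.frozen + self.active_core + self.inactive_occ:
            if i not in occ:
                raise PartitionError(f"orbital {i} assigned to an occupied set but is virtual")
        eps = ref.orbital_energies
        if self.inactive_occ:
            emax_core = max(eps[i] for i in self.active_core)
            emin_inact = min(eps[i] for i in self.inactive_occ)
            if emax_core >= emin_inact:
                raise PartitionError(
                    f"active-core energies must lie below all inactive occupied energies "
                    f"(core max {emax_core:.6f} Eh >= inactive min {emin_inact:.6f} Eh)"
                )


def parse_selector(text: str):
    """Parse the config/CLI core-selector syntax.

    ``"indices:0,1"`` -> explicit orbital indices;
    ``"N:K"``         -> all K-edge (1s) orbitals of element N;
    ``"window:<-15"`` -> every occupied orbital below -15 Hartree.
    """
    text = text.strip()
    if text.startswith("indices:"):
        return {"indices": [int(t) for t in text[len("indices:") :].split(",") if t.strip()]}
    if text.startswith("window:<"):
        return {"window_below": float(text[len("window:<") :])}
    if ":" in text:
        element, edge = text.split(":", 1)
        if edge.strip().upper() != "K":
            raise PartitionError(f"only K edges are supported, got {edge!r}")
        return {"element": element.strip(), "edge": "K"}
    raise PartitionError(f"cannot parse core selector {text!r}")


def _dominant_atoms(ref: ScfReference, ao_atom_map=None) -> np.ndarray:
    """Per-MO dominant atom: largest squared-coefficient weight per atom,
    ties broken by the lowest atom index.  Used only when the backend did not
    already supply the assignment."""
    if ref.orbital_atoms is not None:
        return ref.orbital_atoms
    if ref.mo_coefficients is None or ao_atom_map is None:
        raise PartitionError(
            "element-based selection needs orbital_atoms, or mo_coefficients plus an "
            "AO->atom map"
        )
    ao_atom_map = np.asarray(ao_atom_map, dtype=np.int64)
    C2 = ref.mo_coefficients**2
    natom = int(ao_atom_map.max()) + 1
    pops = np.zeros((natom, C2.shape[1]))
    for ao, atom in enumerate(ao_atom_map):
        pops[atom] += C2[ao]
    # argmax returns the first (lowest atom index) maximum: deterministic ties
    return np.argmax(pops, axis=0)


def select_active_core(
    ref: ScfReference,
    selector,
    ao_atom_map=None,
    freeze_cutoff: float = DEFAULT_CORE_FREEZE_CUTOFF,
    freeze_other_cores: bool = True,
) -> OrbitalPartition:
    """Build the CVS orbital partition from a core selector.

    ``selector`` is either the string syntax of :func:`parse_selector` or the
    parsed dict.  For an element selector, the active set comprises the
    1s-like occupied MOs assigned to atoms of that element (largest per-atom
    population; lowest energies), one per atom of the element.  By default
    every other chemical-core orbital (energy below ``freeze_cutoff``) is
    frozen; pass ``freeze_other_cores=False`` to correlate them instead.
    """
    if isinstance(selector, str):
        selector = parse_selector(selector)
    eps = ref.orbital_energies
    n_occ = ref.n_occupied
    occupied = list(range(n_occ))

    if "indices" in selector:
        active = sorted(set(int(i) for i in selector["indices"]))
        for i in active:
            if i >= n_occ or i < 0:
                raise PartitionError(f"selector index {i} outside occupied range [0, {n_occ})")
        provenance = {"mode": "indices", "indices": active}
    elif "window_below" in selector:
        cut = float(selector["window_below"])
        active = [i for i in occupied if eps[i] < cut]
        if not active:
            raise PartitionError(f"no occupied orbital below {cut} Eh")
        provenance = {"mode": "window", "below": cut}
    elif "element" in selector:
        element = selector["element"]
        atoms = [k for k, sym in enumerate(ref.atom_labels) if sym == element]
        if not atoms:
            raise PartitionError(f"element {element} absent from molecule {ref.atom_labels}")
        dom = _dominant_atoms(ref, ao_atom_map)
        active = []
        for atom in atoms:
            mine = [i for i in occupied if dom[i] == atom]
            if not mine:
                raise PartitionError(f"no occupied orbital assigned to atom {atom} ({element})")
            # 1s-like = deepest occupied MO on this atom
            active.append(min(mine, key=lambda i: eps[i]))
        active = sorted(set(active))
        provenance = {"mode": "element", "element": element, "edge": "K", "atoms": atoms}
    else:
        raise PartitionError(f"unrecognized selector {selector!r}")

    rest = [i for i in occupied if i not in active]
    if freeze_other_cores:
        frozen = [i for i in rest if eps[i] < freeze_cutoff]
    else:
        frozen = []
    inactive = [i for i in rest if i not in frozen]
    part = OrbitalPartition(
        frozen=frozen,
        active_core=active,
        inactive_occ=inactive,
        virtual=range(n_occ, ref.n_basis),
        selector_provenance=provenance,
    )
    part.validate_against(ref)
    return part
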