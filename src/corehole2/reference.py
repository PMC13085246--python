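"""SCF reference contract and the on-disk reference bundle.

The library never computes atomic-orbital integrals itself.  An external SCF
engine (registered through :func:`register_backend`) supplies canonical
orbital energies, MO coefficients and MO-basis density-fitting tensors;
alternatively a serialized :dfn:`reference bundle` carries the same data so
that every downstream algorithm runs without any quantum-chemistry engine.

Units are Hartree throughout; conversion to eV happens only in the reporting
layer (:data:`HARTREE_TO_EV`).
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .df import BLOCK_NAMES, DFTensors
from .exceptions import (
    BackendUnavailableError,
    BundleFormatError,
    ShapeMismatchError,
)

__all__ = [
    "HARTREE_TO_EV",
    "ScfReference",
    "ScfBackend",
    "register_backend",
    "get_backend",
    "available_backends",
    "compute_reference",
    "save_bundle",
    "load_bundle",
    "read_xyz",
]

#: CODATA 2018 Hartree-to-electronvolt conversion; the single conversion point.
HARTREE_TO_EV = 27.211386245988

BUNDLE_FORMAT_VERSION = 1


@dataclass
class ScfReference:
    """Canonical orbitals and metadata from a converged HF or KS calculation.

    Orbital indexing is 0-based everywhere in the API.

    Attributes
    ----------
    orbital_energies : (n_basis,) array, Hartree
        Canonical orbital energies, ascending within the occupied and within
        the virtual block.
    n_occupied : int
        Number of doubly occupied spatial orbitals.
    mo_coefficients : (n_basis, n_basis) array or None
        AO->MO coefficient matrix; optional when MO-basis tensors are already
        available (e.g. loaded from a bundle).
    atom_labels : list of str
        Element symbol per atom.
    orbital_atoms : (n_basis,) int array or None
        Dominant-atom assignment per MO (largest Mulliken-style population,
        ties to the lowest atom index), used for element-based core selection.
    reference_kind : {"HF", "KS"}
    functional_tag : str
        Exchange-correlation functional name; empty for HF.
    scalar_relativistic : bool
        Whether a scalar-relativistic (SFX2C-1e type) one-electron Hamiltonian
        was requested of the backend.
    total_energy : float, Hartree
    """

    orbital_energies: np.ndarray
    n_occupied: int
    mo_coefficients: np.ndarray | None = None
    atom_labels: list[str] = field(default_factory=list)
    orbital_atoms: np.ndarray | None = None
    reference_kind: str = "HF"
    functional_tag: str = ""
    scalar_relativistic: bool = False
    total_energy: float = 0.0

    def __post_init__(self):
        self.orbital_energies = np.asarray(self.orbital_energies, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.orbital_energies)):
            raise ValueError("orbital energies must be finite")
        n = self.n_basis
        if not (1 <= self.n_occupied < n):
            raise ValueError(
                f"need 1 <= n_occupied < n_basis, got n_occupied={self.n_occupied}, n_basis={n}"
            )
        if self.reference_kind not in ("HF", "KS"):
            raise ValueError(f"reference_kind must be 'HF' or 'KS', got {self.reference_kind!r}")
        if self.mo_coefficients is not None:
            self.mo_coefficients = np.asarray(self.mo_coefficients, dtype=np.float64)
        if self.orbital_atoms is not None:
            self.orbital_atoms = np.asarray(self.orbital_atoms, dtype=np.int64).ravel()
            if self.orbital_atoms.size != n:
                raise ShapeMismatchError("orbital_atoms length disagrees with n_basis")
        occ = self.orbital_energies[: self.n_occupied]
        vir = self.orbital_energies[self.n_occupied :]
        if occ.size and vir.size and occ.max() >= vir.min():
            warnings.warn(
                "highest occupied orbital energy is not below the lowest virtual; "
                "proceeding (ordering between blocks is not assumed)",
                stacklevel=2,
            )

    @property
    def n_basis(self) -> int:
        return int(self.orbital_energies.size)

    @property
    def n_virtual(self) -> int:
        return self.n_basis - self.n_occupied


class ScfBackend(Protocol):
    """Adapter contract for an external SCF / integral engine.

    An adapter converges the SCF for a geometry and returns a
    :class:`ScfReference`; it may additionally expose MO-basis three-center
    and two-center Coulomb integrals for :mod:`corehole2.df`, and whether it
    can apply a scalar-relativistic one-electron Hamiltonian is its own
    business.  The library never computes AO integrals itself.
    """

    def compute(self, geometry, settings) -> ScfReference: ...


_BACKENDS: dict[str, Callable] = {}


def register_backend(name: str, factory: Callable) -> None:
    """Register an SCF backend adapter under ``name``.

    ``factory()`` must return an object with a
    ``compute(geometry, settings) -> ScfReference`` method.
    """
    _BACKENDS[name] = factory


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def get_backend(name: str):
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise BackendUnavailableError(
            f"no SCF backend registered under {name!r}; available: {available_backends()}"
        ) from None
    return factory()


def compute_reference(geometry, settings: dict) -> ScfReference:
    """Run the external SCF engine and return the converged reference.

    ``settings`` must name the backend (``backend``) and basis; for a KS
    reference also the functional.  The ``scalar_relativistic`` flag is passed
    through to the backend untouched.  Raises
    :class:`~corehole2.exceptions.ScfNotConvergedError` if the engine reports
    non-convergence.
    """
    backend = get_backend(settings.get("backend", "pyscf"))
    return backend.compute(geometry, settings)


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Read a standard XYZ file: count line, comment line, then
    ``symbol x y z`` per atom in Angstrom.  Returns (symbols, coordinates)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    try:
        natom = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: first XYZ line must be the atom count") from exc
    body = lines[2 : 2 + natom]
    if len(body) < natom:
        raise ValueError(f"{path}: XYZ declares {natom} atoms but holds {len(body)}")
    symbols, coords = [], []
    for ln in body:
        parts = ln.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return symbols, np.asarray(coords, dtype=np.float64)


# --------------------------------------------------------------------------
# Reference bundle: a zip archive of named row-major float64 .npy payloads
# plus a JSON metadata document.  Layout documented in docs/methods.md.
# --------------------------------------------------------------------------

_META_NAME = "metadata.json"


def _reference_metadata(ref: ScfReference) -> dict:
    return {
        "format_version": BUNDLE_FORMAT_VERSION,
        "n_basis": ref.n_basis,
        "n_occupied": ref.n_occupied,
        "atom_labels": list(ref.atom_labels),
        "reference_kind": ref.reference_kind,
        "functional_tag": ref.functional_tag,
        "scalar_relativistic": bool(ref.scalar_relativistic),
        "total_energy": float(ref.total_energy),
        "has_mo_coefficients": ref.mo_coefficients is not None,
        "has_orbital_atoms": ref.orbital_atoms is not None,
    }


def save_bundle(ref: ScfReference, df: DFTensors, path) -> None:
    """Serialize a reference + DF tensors to a single archive at ``path``.

    All arrays are stored as uncompressed row-major float64 ``.npy`` members
    of a zip archive (NumPy's ``.npz`` container) together with a JSON
    metadata member; the round trip is bit-exact.
    """
    arrays: dict[str, np.ndarray] = {
        "orbital_energies": ref.orbital_energies,
    }
    if ref.mo_coefficients is not None:
        arrays["mo_coefficients"] = ref.mo_coefficients
    if ref.orbital_atoms is not None:
        arrays["orbital_atoms"] = ref.orbital_atoms.astype(np.float64)
    for name in BLOCK_NAMES:
        arrays[name] = getattr(df, name)
    meta = _reference_metadata(ref)
    meta["df_shapes"] = {name: list(getattr(df, name).shape) for name in BLOCK_NAMES}
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    buf.seek(0)
    with zipfile.ZipFile(buf, "a") as zf:
        zf.writestr(_META_NAME, json.dumps(meta, indent=1, sort_keys=True))
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_bundle(path) -> tuple[ScfReference, DFTensors]:
    """Inverse of :func:`save_bundle`; validates shapes against metadata."""
    try:
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            if _META_NAME not in names:
                raise BundleFormatError(f"{path}: bundle lacks {_META_NAME}")
            meta = json.loads(zf.read(_META_NAME))
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except (zipfile.BadZipFile, OSError, ValueError, KeyError) as exc:
        raise BundleFormatError(f"{path}: malformed or truncated bundle ({exc})") from exc

    required = {"orbital_energies", *BLOCK_NAMES}
    missing = required - set(arrays)
    if missing:
        raise BundleFormatError(f"{path}: bundle lacks arrays {sorted(missing)}")
    eps = arrays["orbital_energies"]
    if eps.size != meta["n_basis"]:
        raise BundleFormatError(
            f"{path}: orbital_energies length {eps.size} != metadata n_basis {meta['n_basis']}"
        )
    for name in BLOCK_NAMES:
        declared = tuple(meta.get("df_shapes", {}).get(name, ()))
        if declared and tuple(arrays[name].shape) != declared:
            raise BundleFormatError(
                f"{path}: {name} shape {arrays[name].shape} != declared {declared}"
            )
    try:
        df = DFTensors(**{name: arrays[name] for name in BLOCK_NAMES})
    except ShapeMismatchError as exc:
        raise BundleFormatError(f"{path}: inconsistent DF blocks ({exc})") from exc
    n_core_plus = df.n_act + df.n_inact
    if meta["n_occupied"] < n_core_plus:
        raise BundleFormatError(
            f"{path}: metadata n_occupied {meta['n_occupied']} smaller than "
            f"correlated occupied count {n_core_plus}"
        )
    ref = ScfReference(
        orbital_energies=eps,
        n_occupied=meta["n_occupied"],
        mo_coefficients=arrays.get("mo_coefficients"),
        atom_labels=list(meta.get("atom_labels", [])),
        orbital_atoms=(
            arrays["orbital_atoms"].astype(np.int64) if "orbital_atoms" in arrays else None
        ),
        reference_kind=meta["reference_kind"],
        functional_tag=meta.get("functional_tag", ""),
        scalar_relativistic=bool(meta.get("scalar_relativistic", False)),
        total_energy=float(meta.get("total_energy", 0.0)),
    )
    return ref, df


# --------------------------------------------------------------------------
# PySCF adapter (optional; imported lazily)
# --------------------------------------------------------------------------


class PyscfBackend:
    """Adapter delegating SCF and MO-basis DF integrals to PySCF.

    Constructed lazily; importing this module never imports pyscf.  The
    adapter exists as the production entry point for real molecules and is
    registered under the name ``"pyscf"``.
    """

    def __init__(self):
        try:
            import pyscf  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                "the 'pyscf' backend requires the pyscf package"
            ) from exc
        self._mol = None
        self._mf = None

    def compute(self, geometry, settings) -> ScfReference:
        from pyscf import df as pyscf_df  # noqa: F401
        from pyscf import gto, scf, dft

        symbols, coords = geometry
        mol = gto.M(
            atom=[(s, tuple(xyz)) for s, xyz in zip(symbols, coords)],
            basis=settings["basis"],
            unit="Angstrom",
        )
        if settings.get("functional"):
            mf = dft.RKS(mol, xc=settings["functional"])
            kind, tag = "KS", settings["functional"]
        else:
            mf = scf.RHF(mol)
            kind, tag = "HF", ""
        if settings.get("scalar_relativistic"):
            mf = mf.sfx2c1e()
        mf.kernel()
        if not mf.converged:
            from .exceptions import ScfNotConvergedError

            raise ScfNotConvergedError("backend SCF did not converge")
        self._mol, self._mf = mol, mf
        ao_atoms = np.asarray([lbl[0] for lbl in mol.ao_labels(fmt=None)], dtype=np.int64)
        C = mf.mo_coeff
        pops = np.zeros((mol.natm, C.shape[1]))
        S = mf.get_ovlp()
        CS = C * (S @ C)  # Mulliken gross populations per AO, per MO
        for ao, atom in enumerate(ao_atoms):
            pops[atom] += CS[ao]
        orbital_atoms = np.argmax(pops, axis=0)
        return ScfReference(
            orbital_energies=mf.mo_energy,
            n_occupied=mol.nelectron // 2,
            mo_coefficients=C,
            atom_labels=[mol.atom_symbol(i) for i in range(mol.natm)],
            orbital_atoms=orbital_atoms,
            reference_kind=kind,
            functional_tag=tag,
            scalar_relativistic=bool(settings.get("scalar_relativistic")),
            total_energy=float(mf.e_tot),
        )

    def df_blocks(self, partition, aux_basis=None):
        """MO-basis fitted three-center blocks for the four CVS slices."""
        import numpy as np
        from pyscf import df as pyscf_df
        from pyscf import gto

        from .df import fit_coefficients, metric_inverse_sqrt

        if self._mf is None:
            raise BackendUnavailableError("call compute() before df_blocks()")
        mol, C = self._mol, self._mf.mo_coeff
        auxmol = pyscf_df.addons.make_auxmol(mol, aux_basis)
        ints3c = pyscf_df.incore.aux_e2(mol, auxmol, intor="int3c2e")  # (ao, ao, aux)
        metric = auxmol.intor("int2c2e")
        slices = {
            "C": C[:, list(partition.active_core)],
            "O": C[:, list(partition.inactive_occ)],
            "V": C[:, list(partition.virtual)],
        }
        raw = {}
        for name, (left, right) in {
            "J_CC": ("C", "C"),
            "J_CO": ("C", "O"),
            "J_CV": ("C", "V"),
            "J_OV": ("O", "V"),
        }.items():
            raw[name] = np.einsum(
                "mnq,mi,nj->qij", ints3c, slices[left], slices[right], optimize=True
            )
        W = metric_inverse_sqrt(metric)
        return fit_coefficients(raw, W)


register_backend("pyscf", PyscfBackend)
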