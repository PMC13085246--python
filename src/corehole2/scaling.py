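"""Spin-scaling resolution.

All second-order contributions separate into opposite-spin (OS) and
same-spin (SS) channels.  For the closed-shell spatial-orbital contractions
used throughout, the decomposition is

    OS part = sum V * c          (direct)
    SS part = sum V * (c - c')   (direct minus exchange-permuted)

so that ``OS + SS = sum V * (2c - c')`` reproduces the unscaled working
equations.  A method tag resolves to the pair of channel factors:

* ``none``       -> (1, 1): the plain wave-function method;
* ``sos``        -> (1.3, 0): spin-opposite scaling, a single factor of 1.3
  on the opposite-spin channel with same-spin contributions neglected;
* ``dh:<name>``  -> the correlation-mixing coefficients of the named
  double-hybrid functional, read from a user-editable registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .exceptions import ScalingRegistryError

__all__ = ["ScalingSpec", "resolve_scaling", "load_registry", "SOS_FACTOR"]

#: The single opposite-spin factor of the SOS scheme.
SOS_FACTOR = 1.3


@dataclass(frozen=True)
class ScalingSpec:
    """Effective channel factors applied to all second-order terms.

    ``provenance`` is ``"plain"``, ``"SOS"`` or ``"DH:<name>"``;
    ``reference_settings`` carries the DH functional's reference-orbital
    parameters (exchange mixing, base functional) to forward to the backend.
    """

    c_os: float
    c_ss: float
    provenance: str = "plain"
    reference_settings: dict | None = None

    def is_koopmans_limit(self) -> bool:
        return self.c_os == 0.0 and self.c_ss == 0.0


def load_registry(path=None) -> dict:
    """Load the DH functional registry (name -> coefficient record)."""
    if path is None:
        source = resources.files("corehole2").joinpath("data/dh_registry.yaml")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    for name, entry in data.items():
        for key in ("c_os", "c_ss"):
            if key not in entry:
                raise ScalingRegistryError(f"registry entry {name!r} lacks {key}")
    return data


def resolve_scaling(method_tag: str, functional_registry: dict | None = None) -> ScalingSpec:
    """Resolve a method tag into a :class:`ScalingSpec`.

    ``method_tag`` is ``"none"``, ``"sos"`` or ``"dh:<registered name>"``
    (case-insensitive for the fixed tags; DH names are matched
    case-insensitively against the registry).
    """
    tag = method_tag.strip()
    low = tag.lower()
    if low == "none":
        return ScalingSpec(1.0, 1.0, "plain")
    if low == "sos":
        return ScalingSpec(SOS_FACTOR, 0.0, "SOS")
    if low.startswith("dh:"):
        name = tag[3:].strip()
        registry = functional_registry if functional_registry is not None else load_registry()
        match = {k.lower(): k for k in registry}.get(name.lower())
        if match is None:
            raise ScalingRegistryError(
                f"double-hybrid functional {name!r} is not registered; "
                f"known: {sorted(registry)}"
            )
        entry = registry[match]
        ref_settings = {
            k: entry[k] for k in ("exchange_mixing", "base_functional") if k in entry
        }
        return ScalingSpec(
            float(entry["c_os"]),
            float(entry["c_ss"]),
            provenance=f"DH:{match}",
            reference_settings=ref_settings or None,
        )
    raise ScalingRegistryError(
        f"method tag {method_tag!r} not understood (use 'none', 'sos' or 'dh:<name>')"
    )
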