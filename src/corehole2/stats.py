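"""Benchmark error statistics and peak-separation analysis.

Error measures follow the usual benchmarking conventions for core binding
energies: signed errors ``computed - reference`` (eV) summarized by mean
error (ME), mean absolute error (MAE), standard deviation of the errors
(SD, sample-normalized for n >= 2), root-mean-square error (RMSE), maximum
absolute error (MAX) and the span (max error - min error).

Peak separations compare chemically inequivalent same-element sites within
one molecule: every ionization of an element is referenced to the lowest
ionization energy of that element in the same molecule, and the resulting
separations are compared between computed and reference data via relative
errors — mean relative error MRE = (1/n) sum (w_i - w_i_ref) / w_i_ref,
mean absolute relative error (MARE) and the SD of the relative errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BenchmarkEntry",
    "StatsSummary",
    "error_stats",
    "peak_separations",
    "read_benchmark_table",
]


@dataclass(frozen=True)
class BenchmarkEntry:
    """One computed-vs-reference core ionization (energies in eV, > 0)."""

    molecule: str
    element: str
    computed_ev: float
    reference_ev: float

    def __post_init__(self):
        if self.computed_ev <= 0 or self.reference_ev <= 0:
            raise ValueError(
                f"{self.molecule}/{self.element}: energies must be positive eV"
            )


@dataclass(frozen=True)
class StatsSummary:
    """ME / MAE / SD / RMSE / MAX / span over n signed errors (eV)."""

    me: float
    mae: float
    sd: float
    rmse: float
    max: float
    span: float
    n: int

    def as_dict(self) -> dict:
        return {
            "ME": self.me,
            "MAE": self.mae,
            "SD": self.sd,
            "RMSE": self.rmse,
            "MAX": self.max,
            "span": self.span,
            "n": self.n,
        }


def _summarize(errors: np.ndarray) -> StatsSummary:
    errors = np.asarray(errors, dtype=np.float64)
    n = errors.size
    if n == 0:
        raise ValueError("no entries to summarize")
    sd = float(np.std(errors, ddof=1)) if n >= 2 else 0.0
    return StatsSummary(
        me=float(np.mean(errors)),
        mae=float(np.mean(np.abs(errors))),
        sd=sd,
        rmse=float(np.sqrt(np.mean(errors**2))),
        max=float(np.max(np.abs(errors))),
        span=float(np.max(errors) - np.min(errors)),
        n=n,
    )


def error_stats(entries: list[BenchmarkEntry]) -> StatsSummary:
    """Summary statistics of the signed errors ``computed - reference``."""
    return _summarize([e.computed_ev - e.reference_ev for e in entries])


def peak_separations(entries: list[BenchmarkEntry]) -> tuple[pd.DataFrame, dict]:
    """Same-element peak separations and their relative-error statistics.

    For each (molecule, element) group with >= 2 entries, separations are
    taken against the group's lowest *reference* ionization (the anchor site,
    whose zero self-separation is excluded).  Returns the per-separation
    table and a dict with MRE, MARE, the SD of the relative errors
    (population normalization, matching the printed definition
    ``sqrt((1/n) sum (rel_i - MRE)^2)``), and n.
    """
    rows = []
    frame = pd.DataFrame(
        {
            "molecule": [e.molecule for e in entries],
            "element": [e.element for e in entries],
            "computed": [e.computed_ev for e in entries],
            "reference": [e.reference_ev for e in entries],
        }
    )
    for (mol, elem), grp in frame.groupby(["molecule", "element"], sort=True):
        if len(grp) < 2:
            continue
        anchor = grp.loc[grp["reference"].idxmin()]
        others = grp.drop(index=anchor.name)
        for _, row in others.iterrows():
            sep_ref = row["reference"] - anchor["reference"]
            sep_comp = row["computed"] - anchor["computed"]
            rows.append(
                {
                    "molecule": mol,
                    "element": elem,
                    "reference_separation": sep_ref,
                    "computed_separation": sep_comp,
                    "relative_error": (sep_comp - sep_ref) / sep_ref,
                }
            )
    if not rows:
        raise ValueError(
            "no qualifying pairs: need >= 2 same-element entries in one molecule"
        )
    table = pd.DataFrame(rows)
    rel = table["relative_error"].to_numpy()
    n = rel.size
    mre = float(np.mean(rel))
    summary = {
        "MRE": mre,
        "MARE": float(np.mean(np.abs(rel))),
        "SD_rel": float(np.std(rel)) if n >= 2 else 0.0,
        "n": n,
    }
    return table, summary


def read_benchmark_table(path, sep=None) -> list[BenchmarkEntry]:
    """Read a delimited table with columns molecule, element, computed_eV,
    reference_eV (any common delimiter; header required)."""
    frame = pd.read_csv(path, sep=sep, engine="python")
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"molecule", "element", "computed_ev", "reference_ev"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        BenchmarkEntry(
            molecule=str(r["molecule"]),
            element=str(r["element"]),
            computed_ev=float(r["computed_ev"]),
            reference_ev=float(r["reference_ev"]),
        )
        for _, r in frame.iterrows()
    ]
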