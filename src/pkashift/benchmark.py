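"""Benchmarking predicted against experimental folded-state pKas.

Predictor outputs (from continuum-electrostatics or empirical pKa
calculators run on single crystal-structure chains or on conformational
ensembles) are compared with the NMR-derived pKas: Pearson correlation,
root-mean-square error in pKa units, and the two-tailed p-value of the
correlation via t = r sqrt(n-2) / sqrt(1-r^2).  Prediction files are pure
inputs -- this package never runs a predictor itself.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictionSet",
    "BenchmarkRow",
    "normalize_residue",
    "ensemble_average",
    "benchmark",
    "benchmark_report",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def normalize_residue(label: str) -> str:
    """Canonical one-letter-plus-number residue label, e.g. ``GLU-50`` -> ``E50``."""
    s = str(label).strip().upper().replace("-", "").replace("_", "")
    m = re.fullmatch(r"([A-Z]+)(\d+)", s)
    if not m:
        raise ValueError(f"cannot parse residue label {label!r}")
    aa, num = m.groups()
    if len(aa) == 3 and aa in _THREE_TO_ONE:
        aa = _THREE_TO_ONE[aa]
    if len(aa) != 1:
        raise ValueError(f"unrecognised amino-acid code in {label!r}")
    return f"{aa}{int(num)}"


@dataclass
class PredictionSet:
    """One predictor's pKa values for one structural model.

    ``structure`` conventionally distinguishes single chains from
    conformational ensembles (e.g. "A", "B", "Aens", "Bens").  When
    per-member ensemble values are supplied, ``values`` holds their
    arithmetic mean.
    """

    method: str
    structure: str
    values: dict[str, float]
    ensemble_members: list[dict[str, float]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = {normalize_residue(k): float(v) for k, v in self.values.items()}
        if self.ensemble_members is not None:
            self.ensemble_members = [
                {normalize_residue(k): float(v) for k, v in m.items()}
                for m in self.ensemble_members
            ]

    @classmethod
    def from_members(
        cls, method: str, structure: str, members: list[dict[str, float]]
    ) -> "PredictionSet":
        return cls(method, structure, ensemble_average(members), ensemble_members=members)


@dataclass(frozen=True)
class BenchmarkRow:
    method: str
    structure: str
    r: float
    rmse: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation coefficient out of range")
        if self.rmse < 0 or not 0.0 <= self.p_value <= 1.0:
            raise ValueError("invalid rmse or p-value")


def ensemble_average(members: list[dict[str, float]]) -> dict[str, float]:
    """Arithmetic per-residue mean over ensemble members.

    Residues absent from some members are dropped with a warning so the
    average is always over the same number of structures per residue.
    """
    if not members:
        raise ValueError("ensemble must contain at least one member")
    norm = [{normalize_residue(k): float(v) for k, v in m.items()} for m in members]
    common = set(norm[0])
    union = set(norm[0])
    for m in norm[1:]:
        common &= set(m)
        union |= set(m)
    dropped = sorted(union - common)
    if dropped:
        warnings.warn(
            f"residues missing from some ensemble members dropped: {dropped}",
            stacklevel=2,
        )
    return {res: float(np.mean([m[res] for m in norm])) for res in sorted(common)}


def benchmark(experimental: dict[str, float], prediction: PredictionSet) -> BenchmarkRow:
    """Correlation statistics of one prediction set against experiment.

    Residues are matched by normalised label; at least three matches are
    required.  RMSE is sqrt(mean((pred - exp)^2)) in pKa units and the
    p-value is the two-tailed test of r = 0.
    """
    exp = {}
    for k, v in experimental.items():
        nk = normalize_residue(k)
        if nk in exp:
            raise ValueError(f"duplicate experimental residue {nk}")
        exp[nk] = float(v)
    shared = sorted(set(exp) & set(prediction.values))
    if len(shared) < 3:
        raise ValueError(f"need at least 3 matched residues, got {len(shared)}")
    x = np.array([exp[r] for r in shared])
    y = np.array([prediction.values[r] for r in shared])
    r, p = stats.pearsonr(x, y)
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    return BenchmarkRow(
        method=prediction.method,
        structure=prediction.structure,
        r=float(r),
        rmse=rmse,
        p_value=float(p),
        n=len(shared),
    )


def benchmark_report(
    experimental: dict[str, float], predictions: list[PredictionSet]
) -> pd.DataFrame:
    """Long-form benchmark table: one row per (method, structure).

    Pivoting on method x structure reproduces the familiar report layout of
    an R / RMSE / p-value block per predictor and structural model.
    """
    rows = [benchmark(experimental, p) for p in predictions]
    return pd.DataFrame(
        {
            "method": [r.method for r in rows],
            "structure": [r.structure for r in rows],
            "r": [r.r for r in rows],
            "rmse": [r.rmse for r in rows],
            "p_value": [r.p_value for r in rows],
            "n": [r.n for r in rows],
        }
    )
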