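"""Thermodynamic linkage: pKa shifts to electrostatic stability contributions.

A titratable group whose pKa differs between the folded and unfolded states
contributes to the Gibbs free energy of unfolding.  For an acid,

    DDG_u^charge = ln(10) * R * T * (pKa_unfold - pKa_fold)

in kJ/mol with R = 8.314 J mol^-1 K^-1: an up-shifted folded pKa
(pKa_fold > pKa_unfold) means the charged form is harder to make in the
folded state, i.e. the charge destabilises the fold (negative DDG).
Uncertainties propagate in quadrature from the two pKa standard errors.

The module also compares the per-residue contributions between two
temperatures and correlates them with independently measured mutational
stability changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "R_GAS_KJ",
    "PkaPair",
    "DeltaGRecord",
    "delta_g_charge",
    "ddg_from_tables",
    "pairs_from_tables",
    "temperature_comparison",
    "correlate_with_mutagenesis",
    "CorrelationResult",
]

R_GAS_KJ = 8.314e-3  # kJ mol^-1 K^-1
LN10 = math.log(10.0)


@dataclass(frozen=True)
class PkaPair:
    """Folded/unfolded pKa pair for one residue at one temperature.

    ``unfold_group`` records a shared denatured-state resonance (e.g.
    "D12/D48") when two residues' unfolded pKas are degenerate.
    """

    residue: str
    temperature: float
    pka_fold: float
    pka_unfold: float
    err_fold: float = 0.0
    err_unfold: float = 0.0
    unfold_group: str | None = None

    def __post_init__(self) -> None:
        if self.err_fold < 0 or self.err_unfold < 0:
            raise ValueError("pKa errors must be non-negative")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")
        for name in ("pka_fold", "pka_unfold"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"incomplete pair for {self.residue}: {name} missing")


@dataclass(frozen=True)
class DeltaGRecord:
    residue: str
    temperature: float
    delta_pka: float
    ddg: float  # kJ/mol
    ddg_err: float  # kJ/mol


def delta_g_charge(pair: PkaPair) -> DeltaGRecord:
    """Electrostatic contribution of one residue to unfolding free energy.

    delta_pKa = pKa_unfold - pKa_fold; DDG = ln(10) R T delta_pKa (kJ/mol);
    the error is the quadrature sum of the two pKa errors on the same scale.
    """
    factor = LN10 * R_GAS_KJ * pair.temperature
    dpka = pair.pka_unfold - pair.pka_fold
    return DeltaGRecord(
        residue=pair.residue,
        temperature=pair.temperature,
        delta_pka=dpka,
        ddg=factor * dpka,
        ddg_err=factor * math.hypot(pair.err_fold, pair.err_unfold),
    )


def _unfolded_lookup(unfolded: pd.DataFrame, pka_col: str, err_col: str):
    """Expand slash-joined degenerate rows into a per-residue map."""
    table: dict[str, tuple[float, float, str | None]] = {}
    for _, row in unfolded.iterrows():
        members = str(row["residue"]).split("/")
        group = row["residue"] if len(members) > 1 else None
        for m in members:
            if m in table:
                raise ValueError(f"duplicate unfolded residue {m}")
            table[m] = (float(row[pka_col]), float(row[err_col]), group)
    return table


def pairs_from_tables(
    folded: pd.DataFrame,
    unfolded: pd.DataFrame,
    temperature: float,
    pka_col: str = "pka",
    err_col: str = "err",
) -> list[PkaPair]:
    """Match folded and unfolded pKa tables residue-by-residue.

    Both tables need ``residue`` plus the pKa/error columns; unfolded rows
    whose label joins residues with "/" (degenerate denatured resonances)
    supply the shared value to every member.  Residues missing from either
    table are skipped.
    """
    lookup = _unfolded_lookup(unfolded, pka_col, err_col)
    pairs = []
    for _, row in folded.iterrows():
        res = str(row["residue"])
        if res not in lookup:
            continue
        pu, eu, group = lookup[res]
        pairs.append(
            PkaPair(
                residue=res,
                temperature=temperature,
                pka_fold=float(row[pka_col]),
                err_fold=float(row[err_col]),
                pka_unfold=pu,
                err_unfold=eu,
                unfold_group=group,
            )
        )
    return pairs


def ddg_from_tables(
    folded: pd.DataFrame, unfolded: pd.DataFrame, temperature: float, **kw
) -> pd.DataFrame:
    """Per-residue DDG_u^charge table (kJ/mol) at one temperature."""
    records = [delta_g_charge(p) for p in pairs_from_tables(folded, unfolded, temperature, **kw)]
    return pd.DataFrame(
        {
            "residue": [r.residue for r in records],
            "temperature_K": [r.temperature for r in records],
            "delta_pka": [r.delta_pka for r in records],
            "ddg_kJ_mol": [r.ddg for r in records],
            "ddg_err_kJ_mol": [r.ddg_err for r in records],
        }
    )


@dataclass
class TemperatureComparison:
    table: pd.DataFrame
    max_abs_difference: float
    threshold: float
    insensitive: bool
    unmatched: list[str]


def temperature_comparison(
    records_t1: pd.DataFrame,
    records_t2: pd.DataFrame,
    threshold: float = 2.0,
) -> TemperatureComparison:
    """Residue-wise difference of DDG between two temperatures.

    The ensemble is flagged temperature-insensitive when the largest
    per-residue |DDG(T1) - DDG(T2)| does not exceed ``threshold`` kJ/mol.
    Residues present in only one table are listed and excluded.
    """
    t1 = records_t1.set_index("residue")
    t2 = records_t2.set_index("residue")
    shared = [r for r in t1.index if r in t2.index]
    unmatched = sorted(set(t1.index).symmetric_difference(t2.index))
    diff = t1.loc[shared, "ddg_kJ_mol"].to_numpy() - t2.loc[shared, "ddg_kJ_mol"].to_numpy()
    table = pd.DataFrame(
        {
            "residue": shared,
            "ddg_T1_kJ_mol": t1.loc[shared, "ddg_kJ_mol"].to_numpy(),
            "ddg_T2_kJ_mol": t2.loc[shared, "ddg_kJ_mol"].to_numpy(),
            "difference_kJ_mol": diff,
        }
    )
    max_abs = float(np.max(np.abs(diff))) if len(diff) else 0.0
    return TemperatureComparison(
        table=table,
        max_abs_difference=max_abs,
        threshold=threshold,
        insensitive=max_abs <= threshold,
        unmatched=unmatched,
    )


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    table: pd.DataFrame


def correlate_with_mutagenesis(
    ddg_charge: pd.DataFrame, ddg_mut: pd.DataFrame
) -> CorrelationResult:
    """Pearson correlation of pKa-shift DDG with mutational DDG.

    Both inputs need columns ``residue`` and ``ddg_kJ_mol``; the mutational
    values come from charge-to-alanine variant stability measurements and
    are supplied by the user.  The p-value is the two-tailed t-test on r
    with n - 2 degrees of freedom.
    """
    a = ddg_charge.set_index("residue")["ddg_kJ_mol"]
    b = ddg_mut.set_index("residue")["ddg_kJ_mol"]
    shared = [r for r in a.index if r in b.index]
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared residues, got {len(shared)}")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    r, p = stats.pearsonr(x, y)
    table = pd.DataFrame(
        {"residue": shared, "ddg_charge_kJ_mol": x, "ddg_mut_kJ_mol": y}
    )
    return CorrelationResult(r=float(r), p_value=float(p), n=len(shared), table=table)
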