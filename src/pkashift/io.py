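"""Tab-separated table readers and writers for every pipeline stage.

Dialect: UTF-8, tab-separated, '.' decimal separator, '#' comment lines.
Residue labels look like "E50", states are "folded"/"unfolded", and
temperatures are in kelvin.  Writers emit a provenance header (inputs,
options, seed, package version) as comment lines; readers skip it, so
writer -> reader round-trips are lossless.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .hhfit import HHFitResult, TitrationCurve
from .peptide import PotentiometricSeries
from .benchmark import PredictionSet

__all__ = [
    "ParseError",
    "read_titration_table",
    "write_titration_table",
    "read_potentiometric_table",
    "write_potentiometric_table",
    "read_pka_table",
    "write_pka_table",
    "read_prediction_table",
    "write_prediction_table",
    "write_table",
    "fit_results_frame",
]

TITRATION_COLUMNS = ["residue", "state", "temperature_K", "pH", "shift_ppm"]
POTENTIOMETRIC_COLUMNS = ["pH", "c_exp_mM"]
PKA_COLUMNS = ["residue", "state", "temperature_K", "pka", "err"]
PREDICTION_COLUMNS = ["method", "structure", "residue", "pka"]


class ParseError(ValueError):
    """A table failed validation; the message lists offending lines."""


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _numeric(df: pd.DataFrame, cols: Iterable[str], path) -> tuple[pd.DataFrame, list[str]]:
    """Coerce columns to float, collecting offender descriptions.

    Line numbers are approximate when comment lines precede the data block:
    they count from the header row of the parsed table.
    """
    problems = []
    out = df.copy()
    for c in cols:
        coerced = pd.to_numeric(out[c], errors="coerce")
        bad = out.index[coerced.isna() & out[c].notna()]
        for i in bad:
            problems.append(f"line {i + 2}: non-numeric {c!r} value {out.loc[i, c]!r}")
        out[c] = coerced
    return out, problems


def read_titration_table(path) -> list[TitrationCurve]:
    """Read chemical-shift titration data grouped per (residue, state, T).

    Expects columns residue, state, temperature_K, pH, shift_ppm.  Rows
    with non-numeric values, pH outside [0, 14] or duplicate (residue, pH)
    entries raise :class:`ParseError` listing every offender.
    """
    df = _read_tsv(path, TITRATION_COLUMNS)
    if df.empty:
        import warnings

        warnings.warn(f"{path}: no titration rows found", stacklevel=2)
        return []
    df, problems = _numeric(df, ["temperature_K", "pH", "shift_ppm"], path)
    ok = df.dropna(subset=["temperature_K", "pH", "shift_ppm"])
    bad_ph = ok.index[(ok["pH"] < 0) | (ok["pH"] > 14)]
    for i in bad_ph:
        problems.append(f"line {i + 2}: pH {ok.loc[i, 'pH']} outside [0, 14]")
    dup = ok.duplicated(subset=["residue", "state", "temperature_K", "pH"], keep=False)
    for i in ok.index[dup & ~ok.index.isin(bad_ph)]:
        problems.append(
            f"line {i + 2}: duplicate (residue, pH) row "
            f"({ok.loc[i, 'residue']}, {ok.loc[i, 'pH']})"
        )
    if problems:
        raise ParseError(f"{path}: " + "; ".join(problems))
    curves = []
    for (res, state, temp), grp in ok.groupby(
        ["residue", "state", "temperature_K"], sort=True
    ):
        curves.append(
            TitrationCurve(
                residue=str(res),
                state=str(state),
                temperature=float(temp),
                pH=grp["pH"].to_numpy(),
                shift=grp["shift_ppm"].to_numpy(),
            )
        )
    return curves


def _provenance_header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    from . import __version__

    lines = [f"# pkashift {__version__}"]
    for k, v in provenance.items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write any result DataFrame as TSV with an optional provenance header."""
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(_provenance_header(provenance) + buf.getvalue())


def write_titration_table(
    curves: list[TitrationCurve], path, provenance: dict | None = None
) -> None:
    rows = []
    for c in curves:
        for ph, sh in zip(c.pH, c.shift):
            rows.append((c.residue, c.state, c.temperature, ph, sh))
    write_table(pd.DataFrame(rows, columns=TITRATION_COLUMNS), path, provenance)


def read_potentiometric_table(
    path, c_peptide: float, temperature: float = 298.0, gdnhcl: float = 0.0, label: str = ""
) -> PotentiometricSeries:
    """Read a (pH, cumulative NaOH mM) series; metadata come from arguments."""
    df = _read_tsv(path, POTENTIOMETRIC_COLUMNS)
    df, problems = _numeric(df, POTENTIOMETRIC_COLUMNS, path)
    if problems:
        raise ParseError(f"{path}: " + "; ".join(problems))
    return PotentiometricSeries(
        pH=df["pH"].to_numpy(),
        c_exp=df["c_exp_mM"].to_numpy(),
        c_peptide=c_peptide,
        temperature=temperature,
        gdnhcl=gdnhcl,
        label=label,
    )


def write_potentiometric_table(
    series: PotentiometricSeries, path, provenance: dict | None = None
) -> None:
    df = pd.DataFrame({"pH": series.pH, "c_exp_mM": series.c_exp})
    write_table(df, path, provenance)


def read_pka_table(path) -> pd.DataFrame:
    """Read a fitted-pKa table (residue, state, temperature_K, pka, err).

    Degenerate unfolded resonances may use slash-joined residue labels
    ("D12/D48"); downstream pairing expands them.
    """
    df = _read_tsv(path, PKA_COLUMNS)
    df, problems = _numeric(df, ["temperature_K", "pka", "err"], path)
    if problems:
        raise ParseError(f"{path}: " + "; ".join(problems))
    return df


def write_pka_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    write_table(df[PKA_COLUMNS], path, provenance)


def read_prediction_table(path) -> list[PredictionSet]:
    """Read predictor outputs into one PredictionSet per (method, structure).

    Columns: method, structure, residue, pka, optional member_id for
    ensembles (members are averaged per residue).  Duplicate residues
    within one (method, structure, member) block are an error.
    """
    df = _read_tsv(path, PREDICTION_COLUMNS)
    df, problems = _numeric(df, ["pka"], path)
    if problems:
        raise ParseError(f"{path}: " + "; ".join(problems))
    has_members = "member_id" in df.columns and df["member_id"].notna().any()
    sets = []
    for (method, structure), grp in df.groupby(["method", "structure"], sort=True):
        if has_members and grp["member_id"].notna().any():
            members = [
                dict(zip(m["residue"], m["pka"]))
                for _, m in grp.groupby("member_id", sort=True)
            ]
            for _, m in grp.groupby("member_id", sort=True):
                if m["residue"].duplicated().any():
                    raise ParseError(
                        f"{path}: duplicate residues in {method}/{structure}"
                    )
            sets.append(PredictionSet.from_members(str(method), str(structure), members))
        else:
            if grp["residue"].duplicated().any():
                raise ParseError(f"{path}: duplicate residues in {method}/{structure}")
            sets.append(
                PredictionSet(
                    str(method), str(structure), dict(zip(grp["residue"], grp["pka"]))
                )
            )
    return sets


def write_prediction_table(
    sets: list[PredictionSet], path, provenance: dict | None = None
) -> None:
    rows = []
    for s in sets:
        if s.ensemble_members:
            for k, member in enumerate(s.ensemble_members):
                for res, v in member.items():
                    rows.append((s.method, s.structure, res, v, k))
        else:
            for res, v in s.values.items():
                rows.append((s.method, s.structure, res, v, None))
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS + ["member_id"])
    if df["member_id"].isna().all():
        df = df.drop(columns="member_id")
    write_table(df, path, provenance)


def fit_results_frame(results: list[HHFitResult]) -> pd.DataFrame:
    """Tabular report of single-site fits, one row per curve."""
    return pd.DataFrame(
        {
            "residue": [r.residue for r in results],
            "state": [r.state for r in results],
            "temperature_K": [r.temperature for r in results],
            "pka": [r.pka for r in results],
            "err": [r.pka_err for r in results],
            "hill": [r.hill for r in results],
            "hill_fixed": [r.hill_fixed for r in results],
            "rss": [r.rss for r in results],
            "n_points": [r.n_points for r in results],
            "biphasic_candidate": [r.biphasic_candidate for r in results],
        }
    )
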