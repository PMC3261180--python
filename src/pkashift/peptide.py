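"""Potentiometric NaOH titrations of blocked model pentapeptides.

Terminally protected pentapeptides (Ac-GGDGG-NH2, Ac-GGEGG-NH2) carry a
single titratable carboxylate and supply model-compound pKas against which
the unfolded-state protein values are judged.  The observable is the
cumulative NaOH concentration C_exp (mM) as a function of the measured pH,
fitted to

    C_exp(pH) = 1000 * 10^-pH
                - 10^-pKa * C_peptide / (10^-pH + 10^-pKa)
                - C_offset

with the peptide concentration held fixed at its known value and C_offset
absorbing the hydroxide already present before the first titration step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .hhfit import FitError

__all__ = ["PotentiometricSeries", "PeptideFitResult", "peptide_model", "fit_peptide"]

MIN_POINTS = 8


@dataclass
class PotentiometricSeries:
    """One peptide titration: (pH, cumulative NaOH mM) pairs plus metadata."""

    pH: np.ndarray
    c_exp: np.ndarray  # mM NaOH
    c_peptide: float  # mM
    temperature: float = 298.0
    gdnhcl: float = 0.0  # M
    label: str = ""

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.c_exp = np.asarray(self.c_exp, dtype=float)
        if self.pH.shape != self.c_exp.shape or self.pH.ndim != 1:
            raise ValueError("pH and c_exp must be 1-D arrays of equal length")
        if len(self.pH) < MIN_POINTS:
            raise ValueError(f"need at least {MIN_POINTS} titration points")
        order = np.argsort(self.pH)
        self.pH = self.pH[order]
        self.c_exp = self.c_exp[order]
        if not self.c_peptide > 0:
            raise ValueError("c_peptide must be positive (mM)")

    @property
    def n_points(self) -> int:
        return len(self.pH)


@dataclass
class PeptideFitResult:
    pka: float
    pka_err: float
    c_offset: float  # mM
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if not 1.0 <= self.pka <= 8.0:
            raise ValueError(
                f"fitted pKa {self.pka:.2f} outside the carboxylate range [1, 8]"
            )


def peptide_model(pH, pka, c_peptide, c_offset):
    """NaOH concentration model (mM) for a single-carboxylate titration.

    At pH = pKa the peptide term equals C_peptide/2 (half-deprotonation);
    far above the pKa it saturates at C_peptide.
    """
    ph = np.asarray(pH, dtype=float)
    h = np.power(10.0, -ph)
    ka = 10.0 ** (-pka)
    return 1000.0 * h - ka * c_peptide / (h + ka) - c_offset


def fit_peptide(series: PotentiometricSeries) -> PeptideFitResult:
    """Least-squares fit of (pKa, C_offset); C_peptide is held fixed.

    A uniform shift of every C_exp value is absorbed entirely by C_offset
    and leaves the pKa estimate unchanged.
    """
    if not (series.pH[0] < 7.0 < series.pH[-1] + 3.0):
        raise ValueError("titration does not bracket the carboxylate transition")
    model = lambda ph, pka, c_off: peptide_model(ph, pka, series.c_peptide, c_off)
    # C_offset enters linearly; pKa start at the mid-pH of the series.
    pka0 = float(np.clip(np.median(series.pH), 2.0, 7.0))
    c_off0 = float(peptide_model(series.pH[0], pka0, series.c_peptide, 0.0) - series.c_exp[0])
    try:
        popt, pcov = optimize.curve_fit(
            model,
            series.pH,
            series.c_exp,
            p0=[pka0, c_off0],
            bounds=([1.0, -np.inf], [8.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"peptide fit did not converge: {exc}", p0=[pka0, c_off0]) from exc
    resid = series.c_exp - model(series.pH, *popt)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    return PeptideFitResult(
        pka=float(popt[0]),
        pka_err=float(perr[0]) if np.isfinite(perr[0]) else 0.0,
        c_offset=float(popt[1]),
        rss=float(resid @ resid),
        n_points=series.n_points,
    )
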