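"""Single-site fits of NMR chemical-shift pH titrations.

The observable is the side-chain carbonyl 13C shift of an Asp/Glu residue
followed across a pH series.  Each curve is fitted to a modified
Henderson-Hasselbalch equation

    delta(pH) = [delta_A + delta_B * 10^(n (pH - pKa))] / [1 + 10^(n (pH - pKa))]

where delta_A / delta_B are the protonated / deprotonated plateau shifts and
n is an empirical Hill coefficient.  The Hill coefficient may be fitted
freely or fixed at 1; an F-test on the nested pair decides which model the
data support.  Curves whose free-Hill fit is shallow (n well below 1) with
structured residuals are flagged as candidates for coupled-site analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TitrationCurve",
    "HHFitResult",
    "ModelSelection",
    "FitError",
    "hh_model",
    "fit_hh",
    "f_test_model_selection",
]

#: smallest plateau-to-plateau amplitude (ppm) worth fitting
MIN_AMPLITUDE = 0.1
#: minimum number of titration points
MIN_POINTS = 5


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the initial guesses used."""

    def __init__(self, message: str, p0=None):
        super().__init__(message)
        self.p0 = p0


class ExtrapolationWarning(UserWarning):
    """Fitted pKa lies outside the sampled pH range (+/- 1 unit)."""


@dataclass
class TitrationCurve:
    """One residue's (pH, chemical shift) titration series.

    Points are sorted by pH on construction.  At least five points are
    required, pH must lie in [0, 14], and duplicate pH values are rejected.
    """

    residue: str
    state: str  # "folded" | "unfolded"
    temperature: float  # K
    pH: np.ndarray
    shift: np.ndarray  # ppm
    shift_id: str = "CO"

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        if self.pH.shape != self.shift.shape or self.pH.ndim != 1:
            raise ValueError("pH and shift must be 1-D arrays of equal length")
        if len(self.pH) < MIN_POINTS:
            raise ValueError(f"need at least {MIN_POINTS} points, got {len(self.pH)}")
        if np.any(self.pH < 0) or np.any(self.pH > 14):
            raise ValueError("pH values must lie in [0, 14]")
        order = np.argsort(self.pH)
        self.pH = self.pH[order]
        self.shift = self.shift[order]
        if np.any(np.diff(self.pH) <= 0):
            raise ValueError(f"duplicate pH values in curve for {self.residue}")
        if self.state not in ("folded", "unfolded"):
            raise ValueError(f"state must be 'folded' or 'unfolded', got {self.state!r}")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def n_points(self) -> int:
        return len(self.pH)

    @property
    def amplitude(self) -> float:
        """Observed shift range (ppm), a lower bound on the transition size."""
        return float(self.shift.max() - self.shift.min())


@dataclass
class HHFitResult:
    """Fitted modified Henderson-Hasselbalch parameters for one curve."""

    residue: str
    state: str
    temperature: float
    pka: float
    pka_err: float
    delta_A: float
    delta_B: float
    hill: float
    hill_fixed: bool
    rss: float
    n_points: int
    biphasic_candidate: bool = False
    covariance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.pka_err < 0:
            raise ValueError("pka_err must be non-negative")
        if self.hill_fixed and self.hill != 1.0:
            raise ValueError("hill_fixed implies hill == 1")

    @property
    def n_params(self) -> int:
        return 3 if self.hill_fixed else 4


@dataclass
class ModelSelection:
    """Outcome of the fixed-vs-free Hill coefficient F-test."""

    chosen: HHFitResult
    f_statistic: float
    p_value: float
    alpha: float


def hh_model(pH, pka, delta_A, delta_B, n=1.0):
    """Modified Henderson-Hasselbalch chemical shift (ppm).

    Midpoint at pH = pKa; tends to ``delta_A`` at low pH and ``delta_B``
    at high pH.  ``n`` steepens (n > 1) or broadens (n < 1) the transition.
    """
    r = np.power(10.0, n * (np.asarray(pH, dtype=float) - pka))
    return (delta_A + delta_B * r) / (1.0 + r)


def _initial_guesses(curve: TitrationCurve) -> tuple[float, float, float]:
    """(pKa, delta_A, delta_B) start: plateaus from the end points, pKa from
    the pH of the steepest finite-difference slope."""
    dA = float(curve.shift[0])
    dB = float(curve.shift[-1])
    slopes = np.diff(curve.shift) / np.diff(curve.pH)
    k = int(np.argmax(np.abs(slopes)))
    pka0 = float(0.5 * (curve.pH[k] + curve.pH[k + 1]))
    return pka0, dA, dB


def _runs_test_p(residuals: np.ndarray) -> float:
    """One-sided exact Wald-Wolfowitz runs test on residual signs.

    Small p means the residual signs cluster into fewer runs than chance
    allows, the signature of systematic lack of fit.  The exact conditional
    distribution of the run count is used because titration series are
    short (~15 points), where the normal approximation is unreliable.
    """
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        return 0.0  # all residuals on one side: maximal clustering
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    comb = math.comb
    total = comb(n1 + n2, n1)
    p = 0.0
    for r in range(2, runs + 1):
        k, odd = divmod(r, 2)
        if odd:
            count = comb(n1 - 1, k - 1) * comb(n2 - 1, k) + comb(n1 - 1, k) * comb(
                n2 - 1, k - 1
            )
        else:
            count = 2 * comb(n1 - 1, k - 1) * comb(n2 - 1, k - 1)
        p += count / total
    return min(p, 1.0)


def fit_hh(
    curve: TitrationCurve,
    fix_hill: bool = False,
    n_boot: int = 0,
    seed: int | None = None,
) -> HHFitResult:
    """Nonlinear least-squares fit of one titration curve.

    Parameters
    ----------
    curve
        The titration series; must show a transition of at least
        ``MIN_AMPLITUDE`` ppm.
    fix_hill
        Fix the Hill coefficient at 1 (3-parameter model) instead of
        fitting it (4-parameter model).
    n_boot
        If > 0, replace the covariance-based pKa standard error with a
        residual-resampling bootstrap of that many replicates.
    seed
        RNG seed for the bootstrap.

    Raises
    ------
    FitError
        If the optimizer does not converge; carries the initial guesses.
    NoTransitionError-like ValueError when the shift range is below the
    amplitude floor.
    """
    if curve.amplitude < MIN_AMPLITUDE:
        raise ValueError(
            f"{curve.residue}: shift range {curve.amplitude:.3f} ppm is below the "
            f"{MIN_AMPLITUDE} ppm floor; no titration transition to fit"
        )
    pka0, dA0, dB0 = _initial_guesses(curve)
    if fix_hill:
        p0 = [pka0, dA0, dB0]
        model = lambda ph, pka, dA, dB: hh_model(ph, pka, dA, dB, 1.0)
    else:
        p0 = [pka0, dA0, dB0, 1.0]
        model = hh_model
    try:
        popt, pcov = optimize.curve_fit(
            model, curve.pH, curve.shift, p0=p0, maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"{curve.residue}: fit did not converge: {exc}", p0=p0) from exc

    resid = curve.shift - model(curve.pH, *popt)
    rss = float(resid @ resid)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    pka_err = float(perr[0]) if np.isfinite(perr[0]) else 0.0

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        fitted = model(curve.pH, *popt)
        boot = []
        for _ in range(n_boot):
            resampled = fitted + rng.choice(resid, size=len(resid), replace=True)
            try:
                pb, _ = optimize.curve_fit(
                    model, curve.pH, resampled, p0=popt, maxfev=10000
                )
                boot.append(pb[0])
            except RuntimeError:
                continue
        if len(boot) >= 2:
            pka_err = float(np.std(boot, ddof=1))

    pka = float(popt[0])
    if not (curve.pH[0] - 1.0 <= pka <= curve.pH[-1] + 1.0):
        warnings.warn(
            f"{curve.residue}: fitted pKa {pka:.2f} lies outside the sampled "
            f"pH range {curve.pH[0]:.1f}-{curve.pH[-1]:.1f} (+/- 1)",
            ExtrapolationWarning,
            stacklevel=2,
        )

    hill = 1.0 if fix_hill else float(popt[3])
    # Shallow Hill coefficient plus structured residuals is the automated
    # proxy for a visually biphasic curve needing a coupled-site model.
    biphasic = (not fix_hill) and hill < 0.85 and _runs_test_p(resid) < 0.05

    return HHFitResult(
        residue=curve.residue,
        state=curve.state,
        temperature=curve.temperature,
        pka=pka,
        pka_err=pka_err,
        delta_A=float(popt[1]),
        delta_B=float(popt[2]),
        hill=hill,
        hill_fixed=fix_hill,
        rss=rss,
        n_points=curve.n_points,
        biphasic_candidate=biphasic,
        covariance=pcov,
    )


def f_test_model_selection(
    fit_free: HHFitResult, fit_fixed: HHFitResult, alpha: float = 0.05
) -> ModelSelection:
    """Choose between the fixed-Hill (3-parameter) and free-Hill (4-parameter)
    fits of the same curve by an extra-sum-of-squares F-test.

    F = ((RSS_fixed - RSS_free) / (p_free - p_fixed)) / (RSS_free / (N - p_free))

    The simpler fixed-Hill model is retained when p >= alpha.
    """
    if fit_free.n_points != fit_fixed.n_points:
        raise ValueError("F-test requires fits of the same curve")
    n = fit_free.n_points
    p1, p2 = fit_fixed.n_params, fit_free.n_params
    if n <= p2:
        raise ValueError(f"need more than {p2} points for the F-test, got {n}")
    df1, df2 = p2 - p1, n - p2
    # below this RSS both models reproduce the data to floating-point noise
    # and the variance-ratio statistic is meaningless
    tiny = 1e-20
    if fit_free.rss <= tiny:
        f_stat = 0.0 if fit_fixed.rss <= tiny else math.inf
    else:
        f_stat = max(0.0, (fit_fixed.rss - fit_free.rss) / df1 / (fit_free.rss / df2))
    p_value = float(stats.f.sf(f_stat, df1, df2))
    chosen = fit_fixed if p_value >= alpha else fit_free
    return ModelSelection(chosen=chosen, f_statistic=f_stat, p_value=p_value, alpha=alpha)
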