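"""Statistical-mechanics engine for coupled protonation equilibria.

N titratable sites define 2**N protonation microstates.  Each microstate's
free energy combines a per-site proton-binding term, linear in
``ln(10)*R*T*(pH - pKa_int)``, with pairwise electrostatic interaction
energies acting between simultaneously charged (deprotonated) groups.
Per-site protonation fractions follow from the Boltzmann sum over all
microstates, and an *apparent* pKa is read off operationally as the pH of
half-protonation of the full coupled system.

For independent sites (all interaction energies zero) the model collapses
exactly to a product of Henderson-Hasselbalch curves; with a repulsive
coupling between two acids the apparent pKas split apart and reporter
chemical-shift curves become biphasic.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "R_GAS_KJ",
    "LN10",
    "Site",
    "SiteSystem",
    "ShiftModel",
    "NoTransitionError",
    "AmbiguousTransitionWarning",
    "microstates",
    "microstate_energy",
    "state_energies",
    "protonation_fraction",
    "protonation_fractions",
    "apparent_pka",
    "predict_shift",
    "predict_shifts",
]

R_GAS_KJ = 8.314e-3  # gas constant, kJ mol^-1 K^-1
LN10 = math.log(10.0)

#: exact enumeration of 2**N microstates is refused above this site count
MAX_SITES = 20


class NoTransitionError(ValueError):
    """The protonation fraction never crosses 1/2 on the scanned pH range."""


class AmbiguousTransitionWarning(UserWarning):
    """Multiple half-protonation crossings found (strong coupling regime)."""


@dataclass(frozen=True)
class Site:
    """One titratable group.

    Parameters
    ----------
    label
        Residue identifier, e.g. ``"E50"``.
    pka_int
        Intrinsic pKa (pH units): the pKa the site would have if every other
        site were in its neutral form.
    charge_deprot
        Formal charge of the deprotonated form; -1 for Asp/Glu carboxylates,
        +1 would describe a base losing its charge on deprotonation is not
        the convention here -- bases are not modelled, but 0/+1 are accepted.
    """

    label: str
    pka_int: float
    charge_deprot: int = -1

    def __post_init__(self) -> None:
        if not math.isfinite(self.pka_int):
            raise ValueError(f"pka_int must be finite, got {self.pka_int!r}")
        if self.charge_deprot not in (-1, 0, 1):
            raise ValueError(f"charge_deprot must be -1, 0 or +1, got {self.charge_deprot!r}")


@dataclass
class SiteSystem:
    """A set of coupled titratable sites.

    ``W[i, j]`` is the pairwise interaction energy (kJ/mol) paid when sites
    i and j are *both* in their charged (deprotonated) form; positive values
    are repulsive.  The matrix must be symmetric with zero diagonal.
    """

    sites: tuple[Site, ...]
    W: np.ndarray = field(default=None)  # type: ignore[assignment]
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)
        n = len(self.sites)
        if n == 0:
            raise ValueError("SiteSystem needs at least one site")
        if n > MAX_SITES:
            raise ValueError(
                f"{n} sites would require enumerating 2^{n} microstates; "
                f"the exact engine is capped at {MAX_SITES} sites"
            )
        if self.W is None:
            self.W = np.zeros((n, n))
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {self.W.shape}")
        if not np.allclose(self.W, self.W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if not np.allclose(np.diag(self.W), 0.0, atol=1e-12):
            raise ValueError("W must have zero diagonal")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def rt(self) -> float:
        """Thermal energy R*T in kJ/mol."""
        return R_GAS_KJ * self.temperature

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sites)

    @property
    def pka_int(self) -> np.ndarray:
        return np.array([s.pka_int for s in self.sites])

    @property
    def charges_deprot(self) -> np.ndarray:
        return np.array([s.charge_deprot for s in self.sites], dtype=float)

    # -- plain key-value serialization ------------------------------------
    def to_config_text(self) -> str:
        """Serialize as a plain key-value block (one ``key = value`` per line)."""
        lines = [f"temperature = {self.temperature!r}"]
        for s in self.sites:
            lines.append(f"site {s.label} = {s.pka_int!r} {s.charge_deprot}")
        for i in range(self.n_sites):
            for j in range(i + 1, self.n_sites):
                if self.W[i, j] != 0.0:
                    lines.append(
                        f"W {self.sites[i].label} {self.sites[j].label} = {float(self.W[i, j])!r}"
                    )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str) -> "SiteSystem":
        temperature = 298.0
        sites: list[Site] = []
        w_entries: list[tuple[str, str, float]] = []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "temperature":
                temperature = float(value)
            elif key.startswith("site "):
                label = key.split(None, 1)[1]
                pka, charge = value.split()
                sites.append(Site(label, float(pka), int(charge)))
            elif key.startswith("W "):
                _, a, b = key.split()
                w_entries.append((a, b, float(value)))
            else:
                raise ValueError(f"unrecognised config line: {raw!r}")
        labels = [s.label for s in sites]
        W = np.zeros((len(sites), len(sites)))
        for a, b, w in w_entries:
            i, j = labels.index(a), labels.index(b)
            W[i, j] = W[j, i] = w
        return cls(tuple(sites), W, temperature)


@dataclass
class ShiftModel:
    """Linear map from site deprotonation fractions to reporter chemical shifts.

    ``baseline[i]`` is reporter i's fully protonated-limit shift (ppm) and
    ``amplitudes[i, j]`` the shift change of reporter i per unit
    deprotonation of site j.  Off-diagonal (cross) amplitudes produce the
    biphasic curves characteristic of coupled carboxylate pairs.
    """

    baseline: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.baseline = np.atleast_1d(np.asarray(self.baseline, dtype=float))
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if not np.all(np.isfinite(self.baseline)) or not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("shift model parameters must be finite")
        if self.amplitudes.shape[0] != self.baseline.shape[0]:
            raise ValueError("one baseline per reporter is required")

    @property
    def n_reporters(self) -> int:
        return self.baseline.shape[0]


def microstates(n_sites: int) -> np.ndarray:
    """All 2**n binary protonation vectors, shape ``(2**n, n)``; 1 = protonated."""
    if n_sites > MAX_SITES:
        raise ValueError(f"refusing to enumerate 2^{n_sites} microstates")
    return np.array(list(itertools.product((0, 1), repeat=n_sites)), dtype=float)


def microstate_energy(system: SiteSystem, state, pH: float) -> float:
    """Free energy (kJ/mol) of one protonation microstate at a given pH.

    G(x) = sum_i x_i * ln(10)*R*T*(pH - pKa_int_i)
         + sum_{i<j} W_ij * q_i(x) * q_j(x)

    where q_i is the site's formal charge when deprotonated and zero when
    the proton is bound (a protonated carboxylic acid is neutral).  The
    all-deprotonated, non-interacting arrangement is the energy reference.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (system.n_sites,):
        raise ValueError(
            f"state has {x.shape} entries but the system has {system.n_sites} sites"
        )
    field_term = float(
        np.sum(x * LN10 * system.rt * (pH - system.pka_int))
    )
    q = system.charges_deprot * (1.0 - x)
    pair_term = 0.5 * float(q @ system.W @ q)  # diagonal is zero
    return field_term + pair_term


def state_energies(system: SiteSystem, pH) -> np.ndarray:
    """Energies of all microstates on a pH grid, shape ``(2**n, n_pH)``."""
    ph = np.atleast_1d(np.asarray(pH, dtype=float))
    S = microstates(system.n_sites)  # (M, n)
    per_site = LN10 * system.rt * (ph[None, :] - system.pka_int[:, None])  # (n, K)
    e_field = S @ per_site  # (M, K)
    Q = system.charges_deprot[None, :] * (1.0 - S)  # (M, n)
    e_pair = 0.5 * np.einsum("mi,ij,mj->m", Q, system.W, Q)
    return e_field + e_pair[:, None]


def protonation_fractions(system: SiteSystem, pH) -> np.ndarray:
    """Boltzmann-averaged protonation fraction of every site.

    Returns shape ``(n_sites, n_pH)`` for array pH, ``(n_sites,)`` for scalar.
    Probabilities are normalised over the full 2**n microstate sum.
    """
    ph = np.atleast_1d(np.asarray(pH, dtype=float))
    E = state_energies(system, ph)
    E = E - E.min(axis=0, keepdims=True)  # overflow guard; shifts cancel
    B = np.exp(-E / system.rt)
    Z = B.sum(axis=0)
    S = microstates(system.n_sites)
    f = (S.T @ B) / Z
    if np.isscalar(pH) or np.ndim(pH) == 0:
        return f[:, 0]
    return f


def protonation_fraction(system: SiteSystem, site_index: int, pH):
    """Protonation fraction of one site; scalar in [0, 1] or array over pH."""
    if not 0 <= site_index < system.n_sites:
        raise IndexError(f"site index {site_index} out of range")
    f = protonation_fractions(system, np.atleast_1d(pH))[site_index]
    if np.isscalar(pH) or np.ndim(pH) == 0:
        return float(f[0])
    return f


def apparent_pka(
    system: SiteSystem,
    site_index: int,
    grid_step: float = 0.1,
    window: tuple[float, float] = (0.0, 14.0),
    xtol: float = 1e-6,
) -> float:
    """pH at which a site is half-protonated in the full coupled system.

    The pH window is scanned at ``grid_step`` resolution and each bracketing
    interval of f = 1/2 is refined by bisection to ``xtol``.  With strong
    coupling a fraction can cross 1/2 more than once; the crossing with the
    steepest slope is returned and :class:`AmbiguousTransitionWarning` is
    issued.
    """
    lo, hi = window
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    f = protonation_fractions(system, grid)[site_index]
    g = f - 0.5
    crossings: list[tuple[float, float]] = []  # (pka, |slope|)
    for k in range(len(grid) - 1):
        if g[k] == 0.0:
            crossings.append((float(grid[k]), abs(f[k + 1] - f[k]) / grid_step))
        elif g[k] * g[k + 1] < 0:
            root = brentq(
                lambda p: protonation_fraction(system, site_index, p) - 0.5,
                grid[k],
                grid[k + 1],
                xtol=xtol,
            )
            crossings.append((float(root), abs(f[k + 1] - f[k]) / grid_step))
    if g[-1] == 0.0:
        crossings.append((float(grid[-1]), abs(g[-1] - g[-2]) / grid_step))
    if not crossings:
        raise NoTransitionError(
            f"site {system.sites[site_index].label}: protonation fraction does not "
            f"cross 1/2 on pH {lo}-{hi}"
        )
    if len(crossings) > 1:
        warnings.warn(
            f"site {system.sites[site_index].label}: {len(crossings)} "
            "half-protonation crossings; returning the steepest",
            AmbiguousTransitionWarning,
            stacklevel=2,
        )
    return max(crossings, key=lambda c: c[1])[0]


def predict_shifts(system: SiteSystem, shifts: ShiftModel, pH) -> np.ndarray:
    """Chemical shifts of all reporters, shape ``(n_reporters, n_pH)``.

    delta_i(pH) = baseline_i + sum_j a[i, j] * (1 - f_j(pH)).
    """
    if shifts.amplitudes.shape[1] != system.n_sites:
        raise ValueError(
            f"shift model covers {shifts.amplitudes.shape[1]} sites, "
            f"system has {system.n_sites}"
        )
    if shifts.n_reporters > system.n_sites:
        raise ValueError("more reporters than sites")
    ph = np.atleast_1d(np.asarray(pH, dtype=float))
    f = protonation_fractions(system, ph)  # (n_sites, K)
    out = shifts.baseline[:, None] + shifts.amplitudes @ (1.0 - f)
    return out


def predict_shift(system: SiteSystem, shifts: ShiftModel, reporter_index: int, pH):
    """Predicted chemical shift (ppm) of one reporter at given pH."""
    if not 0 <= reporter_index < shifts.n_reporters:
        raise IndexError(f"reporter index {reporter_index} out of range")
    d = predict_shifts(system, shifts, np.atleast_1d(pH))[reporter_index]
    if np.isscalar(pH) or np.ndim(pH) == 0:
        return float(d[0])
    return d
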