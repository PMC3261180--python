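"""Synthetic titration data generators.

The raw NMR titration series behind the published pKa tables were never
deposited, so the pipeline is exercised on synthetic data: sigmoidal
chemical-shift curves from the modified Henderson-Hasselbalch model,
biphasic coupled-pair curves from the Boltzmann-sum engine, and
potentiometric NaOH series from the peptide charge-balance equation,
each with i.i.d. Gaussian noise.  Truth parameters default to the
published pKas; every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hhfit import TitrationCurve, hh_model
from .multisite import ShiftModel, Site, SiteSystem, apparent_pka, predict_shifts
from .peptide import PotentiometricSeries, peptide_model
from . import tables

__all__ = [
    "SimulationSpec",
    "DEFAULT_PH_GRID",
    "simulate",
    "simulate_single_site",
    "simulate_coupled_pair",
    "simulate_peptide",
    "simulate_predictor_table",
    "system_with_apparent_pkas",
    "fixtures_paper_tables",
]

#: the experimental folded-state sampling window: pH 1.2-6.7, 15 points
DEFAULT_PH_GRID = np.linspace(1.2, 6.7, 15)

#: default per-point noise, chosen to mimic typical 13C shift read precision
DEFAULT_SHIFT_NOISE_SD = 0.03  # ppm
#: default potentiometric noise on the NaOH concentration
DEFAULT_CEXP_NOISE_SD = 0.2  # mM

# Typical side-chain carboxyl 13C plateau shifts (ppm): protonated ->
# deprotonated moves downfield by ~3-4 ppm.
ASP_PLATEAUS = (177.5, 180.9)
GLU_PLATEAUS = (179.5, 183.5)


@dataclass
class SimulationSpec:
    """Truth parameters and sampling plan for one synthetic scenario.

    ``scenario`` selects the generator: ``single_site``, ``coupled_pair``,
    ``peptide`` or ``predictor_table``.  Only the fields relevant to the
    chosen scenario are read.
    """

    scenario: str
    seed: int = 1
    noise_sd: float | None = None
    n_replicates: int = 1
    ph_grid: np.ndarray = field(default_factory=lambda: DEFAULT_PH_GRID.copy())
    temperature: float = 298.0
    state: str = "folded"
    # single-site truth
    residue: str = "D2"
    pka: float = 3.13
    hill: float = 1.0
    delta_A: float = ASP_PLATEAUS[0]
    delta_B: float = ASP_PLATEAUS[1]
    # coupled-pair truth (defaults emulate the E50/E62 folded pair at 298 K)
    residues: tuple[str, str] = ("E50", "E62")
    apparent_pkas: tuple[float, float] = (5.10, 3.20)
    w_coupling: float = 3.6  # kJ/mol, magnitude of a measured carboxylate/lysine pair
    baselines: tuple[float, float] = (179.3, 179.6)
    self_amplitudes: tuple[float, float] = (3.3, 3.0)
    cross_amplitudes: tuple[float, float] = (0.8, 0.7)
    # peptide truth
    peptide_pka: float = 4.17
    c_peptide: float = 9.4  # mM, ~40 mg pentapeptide in 10 ml
    c_offset: float = 0.0
    gdnhcl: float = 0.0
    peptide_label: str = "Ac-GGEGG-NH2"
    # predictor-table truth
    experimental: dict | None = None
    predictor_bias: float = 0.0
    n_members: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd is None:
            self.noise_sd = (
                DEFAULT_CEXP_NOISE_SD if self.scenario == "peptide" else DEFAULT_SHIFT_NOISE_SD
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.ph_grid = np.asarray(self.ph_grid, dtype=float)
        if np.any(self.ph_grid < 0) or np.any(self.ph_grid > 14):
            raise ValueError("pH grid must lie within [0, 14]")


def simulate(spec: SimulationSpec):
    """Dispatch to the generator named by ``spec.scenario``."""
    try:
        fn = {
            "single_site": simulate_single_site,
            "coupled_pair": simulate_coupled_pair,
            "peptide": simulate_peptide,
            "predictor_table": simulate_predictor_table,
        }[spec.scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {spec.scenario!r}") from None
    return fn(spec)


def simulate_single_site(spec: SimulationSpec):
    """Noisy modified-HH titration curve(s) for one residue.

    Returns a single :class:`TitrationCurve` when ``n_replicates`` is 1,
    else a list.  Bit-reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    clean = hh_model(spec.ph_grid, spec.pka, spec.delta_A, spec.delta_B, spec.hill)
    curves = []
    for _ in range(spec.n_replicates):
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
        curves.append(
            TitrationCurve(
                residue=spec.residue,
                state=spec.state,
                temperature=spec.temperature,
                pH=spec.ph_grid.copy(),
                shift=noisy,
            )
        )
    return curves[0] if spec.n_replicates == 1 else curves


def system_with_apparent_pkas(
    targets: tuple[float, float],
    w_coupling: float,
    temperature: float = 298.0,
    labels: tuple[str, str] = ("E50", "E62"),
    tol: float = 1e-8,
) -> SiteSystem:
    """Two-acid system whose *apparent* pKas equal the requested targets.

    Intrinsic pKas are solved by fixed-point iteration: the map
    pKa_int <- pKa_int + (target - apparent) contracts because the apparent
    pKa responds nearly one-to-one to its own intrinsic value.
    """
    pka_int = np.array(targets, dtype=float)
    W = np.array([[0.0, w_coupling], [w_coupling, 0.0]])
    for _ in range(200):
        system = SiteSystem(
            tuple(Site(l, float(p)) for l, p in zip(labels, pka_int)), W, temperature
        )
        app = np.array([apparent_pka(system, j) for j in range(2)])
        err = np.array(targets) - app
        if np.max(np.abs(err)) < tol:
            return system
        pka_int = pka_int + err
    raise RuntimeError(
        f"apparent-pKa calibration did not converge for targets {targets}"
    )


def simulate_coupled_pair(spec: SimulationSpec) -> tuple[TitrationCurve, TitrationCurve]:
    """Biphasic coupled-pair titration curves for two reporters.

    The generating system is calibrated so its apparent (half-protonation)
    pKas equal ``spec.apparent_pkas``; non-zero cross-amplitudes imprint
    each site's transition on the other reporter's curve, producing the
    characteristic major/minor biphasic shape.
    """
    rng = np.random.default_rng(spec.seed)
    system = system_with_apparent_pkas(
        spec.apparent_pkas, spec.w_coupling, spec.temperature, spec.residues
    )
    amps = np.array(
        [
            [spec.self_amplitudes[0], spec.cross_amplitudes[0]],
            [spec.cross_amplitudes[1], spec.self_amplitudes[1]],
        ]
    )
    shifts = ShiftModel(np.array(spec.baselines), amps)
    clean = predict_shifts(system, shifts, spec.ph_grid)
    curves = []
    for i, res in enumerate(spec.residues):
        noisy = clean[i] + rng.normal(0.0, spec.noise_sd, size=spec.ph_grid.shape)
        curves.append(
            TitrationCurve(
                residue=res,
                state=spec.state,
                temperature=spec.temperature,
                pH=spec.ph_grid.copy(),
                shift=noisy,
            )
        )
    return curves[0], curves[1]


def simulate_peptide(spec: SimulationSpec) -> PotentiometricSeries:
    """Noisy potentiometric NaOH series from the charge-balance model."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.ph_grid
    if grid is DEFAULT_PH_GRID or np.array_equal(grid, DEFAULT_PH_GRID):
        # potentiometric runs titrate up past pH 8, unlike the NMR window
        grid = np.linspace(2.6, 8.2, 15)
    clean = peptide_model(grid, spec.peptide_pka, spec.c_peptide, spec.c_offset)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=grid.shape)
    return PotentiometricSeries(
        pH=grid,
        c_exp=noisy,
        c_peptide=spec.c_peptide,
        temperature=spec.temperature,
        gdnhcl=spec.gdnhcl,
        label=spec.peptide_label,
    )


def simulate_predictor_table(spec: SimulationSpec):
    """Synthetic predictor output: experimental pKas plus bias and noise.

    Returns a residue -> predicted pKa map when ``n_members`` is 0, else a
    list of per-member maps emulating a conformational ensemble.
    """
    exp = spec.experimental
    if exp is None:
        t = tables.folded_pka_table()
        exp = dict(zip(t["residue"], t["pka_298"]))
    rng = np.random.default_rng(spec.seed)

    def one() -> dict[str, float]:
        return {
            res: float(v + spec.predictor_bias + rng.normal(0.0, spec.noise_sd))
            for res, v in exp.items()
        }

    if spec.n_members == 0:
        return one()
    return [one() for _ in range(spec.n_members)]


def fixtures_paper_tables() -> dict:
    """Machine-readable copies of the published pKa and DDG tables."""
    return {
        "folded_pka": tables.folded_pka_table(),
        "unfolded_pka": tables.unfolded_pka_table(),
        "peptide_pka": tables.peptide_pka_table(),
        "ddg": tables.ddg_table(),
    }
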