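"""Published pKa and stability tables for T. celer ribosomal protein L30e*.

These are the experimentally determined side-chain carboxylate pKa values of
the 5R->K pseudo-wild-type (L30e*) in the folded and guanidine-denatured
states at 298 K and 333 K, the model-pentapeptide pKas, and the derived
electrostatic contributions to the free energy of unfolding.  They serve two
roles: regression fixtures for the thermodynamic layer, and ground-truth
parameters for the synthetic titration-curve generators.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "folded_pka_table",
    "unfolded_pka_table",
    "peptide_pka_table",
    "ddg_table",
    "UNFOLDED_DEGENERATE_GROUPS",
]

# Folded-state pKas; E50 and E62 were obtained by coupled (global) fitting of
# their biphasic titration curves, all others by single-site fits.
_FOLDED = [
    # residue, pka_298, err_298, pka_333, err_333, coupled
    ("D2", 3.13, 0.04, 3.09, 0.05, False),
    ("D12", 3.69, 0.02, 3.69, 0.03, False),
    ("D44", 3.08, 0.04, 2.88, 0.04, False),
    ("D48", 4.14, 0.04, 4.24, 0.04, False),
    ("D87", 2.50, 0.02, 2.49, 0.03, False),
    ("E6", 2.34, 0.03, 2.38, 0.04, False),
    ("E47", 4.53, 0.04, 4.56, 0.04, False),
    ("E50", 5.10, 0.07, 5.00, 0.06, True),
    ("E62", 3.20, 0.06, 3.30, 0.06, True),
    ("E64", 4.10, 0.06, 4.06, 0.07, False),
    ("E69", 3.79, 0.03, 3.82, 0.03, False),
    ("E90", 4.17, 0.02, 4.24, 0.02, False),
    ("E100", 4.31, 0.03, 4.38, 0.05, False),
]

# Unfolded-state pKas (5.4 M GdnHCl).  Some side-chain carboxyl resonances
# are degenerate in the denatured state and share a single fitted pKa; those
# rows carry a slash-joined group label.
_UNFOLDED = [
    ("D2", 3.62, 0.01, 3.53, 0.02),
    ("D44", 3.62, 0.01, 3.52, 0.02),
    ("D87", 3.54, 0.02, 3.47, 0.02),
    ("D12/D48", 3.56, 0.02, 3.46, 0.02),
    ("E6", 4.17, 0.02, 4.00, 0.02),
    ("E62", 4.19, 0.02, 4.03, 0.02),
    ("E69", 4.19, 0.02, 4.01, 0.03),
    ("E100", 4.19, 0.02, 4.06, 0.02),
    ("E47/E64", 4.17, 0.02, 4.00, 0.02),
    ("E50/E90", 4.16, 0.02, 4.02, 0.03),
]

UNFOLDED_DEGENERATE_GROUPS = ("D12/D48", "E47/E64", "E50/E90")

# Terminally blocked pentapeptide (Ac-GGDGG-NH2 / Ac-GGEGG-NH2) pKas from
# potentiometric NaOH titration, with and without 5.4 M GdnHCl.
_PEPTIDE = [
    ("Ac-GGDGG-NH2", 0.0, 3.69, 0.03, 3.61, 0.02),
    ("Ac-GGDGG-NH2", 5.4, 3.70, 0.01, 3.64, 0.02),
    ("Ac-GGEGG-NH2", 0.0, 4.17, 0.03, 4.10, 0.01),
    ("Ac-GGEGG-NH2", 5.4, 4.18, 0.04, 4.10, 0.02),
]

# Published electrostatic contributions DDG_u (kJ/mol) derived from the pKa
# shifts above; regression target for the thermodynamic layer.
_DDG = [
    ("D2", 2.84, 0.27, 2.84, 0.37),
    ("D12", -0.72, 0.18, -1.44, 0.23),
    ("D44", 3.05, 0.24, 4.06, 0.28),
    ("D48", -3.29, 0.26, -4.97, 0.29),
    ("D87", 5.88, 0.14, 6.26, 0.24),
    ("E6", 10.43, 0.23, 10.31, 0.26),
    ("E47", -2.05, 0.26, -3.57, 0.29),
    ("E50", -5.36, 0.40, -6.25, 0.43),
    ("E62", 5.66, 0.36, 4.64, 0.41),
    ("E64", 0.40, 0.36, -0.38, 0.45),
    ("E69", 2.29, 0.19, 1.17, 0.25),
    ("E90", -0.02, 0.15, -1.42, 0.23),
    ("E100", -0.68, 0.21, -2.04, 0.34),
]


def folded_pka_table() -> pd.DataFrame:
    """Folded-state (native) pKas at 298 K and 333 K, one row per residue."""
    return pd.DataFrame(
        _FOLDED,
        columns=["residue", "pka_298", "err_298", "pka_333", "err_333", "coupled"],
    )


def unfolded_pka_table() -> pd.DataFrame:
    """Unfolded-state (5.4 M GdnHCl) pKas; degenerate groups share a row."""
    return pd.DataFrame(
        _UNFOLDED, columns=["residue", "pka_298", "err_298", "pka_333", "err_333"]
    )


def peptide_pka_table() -> pd.DataFrame:
    """Model-compound pKas of the blocked Asp/Glu pentapeptides."""
    return pd.DataFrame(
        _PEPTIDE,
        columns=["peptide", "gdnhcl_M", "pka_298", "err_298", "pka_333", "err_333"],
    )


def ddg_table() -> pd.DataFrame:
    """Published per-residue DDG_u^charge (kJ/mol) at 298 K and 333 K."""
    return pd.DataFrame(
        _DDG, columns=["residue", "ddg_298", "err_298", "ddg_333", "err_333"]
    )
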