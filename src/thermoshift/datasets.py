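"""Published reference tables for the thermophilic-rhodopsin (TR) constructs.

These small tables are the experimental / prediction inputs that the analysis
operates on: the FoldX-style ΔΔG candidate lists for the extramembrane
mutation design, the wet-lab characterization of the wild type and the ten
single mutants (residual pigment after 4 min at 90 °C, decoloration rate
constant at 90 °C, DSC melting temperature), and the MD-ensemble RMSD group
summaries for the native-state (vs crystal) and random-coil (vs medoid)
analyses.  Values are means ± s.e.m.; missing entries (constructs that were
not carried through every assay) are NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "load_characterization",
    "load_position_scan",
    "load_build_model",
    "load_native_rmsd",
    "load_coil_rmsd",
    "load_exposed_residues",
]

_NAN = float("nan")

# construct, residual pigment %, sem, relative yield, k (min^-1), k sem,
# Tm (°C), Tm sem, replicates
_CHARACTERIZATION = [
    ("WT",    44.5, 3.2, 1.0,  0.21,  0.01,  91.78, 0.34, 3),
    ("S8D",   21.7, 2.9, 0.81, _NAN,  _NAN,  _NAN,  _NAN, 3),
    ("V79K",  61.4, 4.0, 0.69, 0.11,  0.01,  94.52, 0.07, 3),
    ("T114D", 67.6, 3.2, 1.3,  0.069, 0.001, 95.93, 0.04, 3),
    ("A115P", 66.5, 4.8, 0.50, 0.11,  0.01,  94.37, 0.06, 3),
    ("A116E", 69.5, 6.3, 0.96, 0.11,  0.01,  94.04, 0.08, 3),
    ("T143K", 49.1, 4.9, _NAN, _NAN,  _NAN,  _NAN,  _NAN, 3),
    ("A177K", 35.9, 2.7, 0.66, _NAN,  _NAN,  _NAN,  _NAN, 3),
    ("W210R", 12.6, 1.0, 0.74, _NAN,  _NAN,  _NAN,  _NAN, 3),
    ("G214D", 35.8, 5.0, 0.95, _NAN,  _NAN,  _NAN,  _NAN, 3),
    ("A215P", 36.0, 4.5, 1.2,  _NAN,  _NAN,  _NAN,  _NAN, 3),
]


def load_characterization() -> pd.DataFrame:
    """Wet-lab stability characterization of the TR constructs.

    Columns: construct, residual_pigment (%), residual_pigment_sem,
    relative_yield, k (min⁻¹), k_sem, tm (°C), tm_sem, n (replicates).
    """
    return pd.DataFrame(
        _CHARACTERIZATION,
        columns=["construct", "residual_pigment", "residual_pigment_sem",
                 "relative_yield", "k", "k_sem", "tm", "tm_sem", "n"],
    )


# 20 position-scan candidates: mutation label, ΔΔG (kcal/mol), protein side
_POSITION_SCAN = [
    ("S8D", -2.30, "N"), ("Q76R", -0.48, "N"), ("V79K", -0.41, "N"),
    ("V81R", -0.26, "N"), ("T114D", -3.08, "C"), ("T114E", -2.77, "C"),
    ("A115P", -1.26, "C"), ("A116D", -2.12, "C"), ("A116E", -1.53, "C"),
    ("N142R", -0.70, "N"), ("T143K", -1.01, "N"), ("A177K", -1.24, "C"),
    ("G180P", -1.87, "C"), ("W210R", -0.50, "N"), ("G214D", -3.43, "N"),
    ("G214E", -1.43, "N"), ("A215P", -1.48, "N"), ("A216E", -1.28, "N"),
    ("L249R", -0.15, "C"), ("E250M", -1.30, "C"),
]

# 10 final candidates with Build-Model ΔΔG and FoldX effect suggestion
_BUILD_MODEL = [
    ("S8D",   "N", -2.32, "helix_dipole",  -2.40),
    ("V79K",  "N", -0.45, "electrostatic", -0.21),
    ("T114D", "C", -3.91, "helix_dipole",  -2.61),
    ("A115P", "C", -1.32, "entropic",      -1.08),
    ("A116E", "C", -2.20, "helix_dipole",  -1.01),
    ("T143K", "N", -1.02, "hydrogen_bond", -1.76),
    ("A177K", "C", -1.08, "helix_dipole",  -0.60),
    ("W210R", "N", -0.66, "helix_dipole",  -0.33),
    ("G214D", "N", -3.42, "helix_dipole",  -2.48),
    ("A215P", "N", -1.54, "entropic",      -1.12),
]


def _split_mutation(label: str) -> tuple[str, int, str]:
    wt, sub = label[0], label[-1]
    return wt, int(label[1:-1]), sub


def load_position_scan() -> pd.DataFrame:
    """The 20 position-scan mutation candidates with predicted ΔΔG.

    Columns: mutation, site, wild_type, substitution, ddg_position_scan
    (kcal/mol; negative = predicted stabilizing), side (N/C protein side).
    """
    rows = []
    for label, ddg, side in _POSITION_SCAN:
        wt, site, sub = _split_mutation(label)
        rows.append((label, site, wt, sub, ddg, side))
    return pd.DataFrame(rows, columns=["mutation", "site", "wild_type",
                                       "substitution", "ddg_position_scan",
                                       "side"])


def load_build_model() -> pd.DataFrame:
    """The 10 selected candidates with Build-Model ΔΔG and effect tags.

    Columns: mutation, site, wild_type, substitution, side,
    ddg_build_model (kcal/mol), effect_tag, effect_contribution (kcal/mol).
    """
    rows = []
    for label, side, ddg, tag, contrib in _BUILD_MODEL:
        wt, site, sub = _split_mutation(label)
        rows.append((label, site, wt, sub, side, ddg, tag, contrib))
    return pd.DataFrame(rows, columns=["mutation", "site", "wild_type",
                                       "substitution", "side",
                                       "ddg_build_model", "effect_tag",
                                       "effect_contribution"])


# native-state ensemble score: mean Cα RMSD vs crystal (Å) ± sem over runs
_NATIVE_RMSD = [
    ("WT", 1.06, 0.06, 3), ("S8D", 1.03, 0.03, 3), ("V79K", 1.29, 0.08, 3),
    ("T114D", 1.47, 0.06, 3), ("A115P", 1.05, 0.08, 3),
    ("A116E", 1.15, 0.15, 3), ("T143K", 1.26, 0.14, 4),
    ("A177K", 1.25, 0.11, 3), ("W210R", 1.21, 0.08, 3),
    ("G214D", 1.07, 0.06, 3), ("A215P", 1.11, 0.09, 3),
]

# random-coil medoid fluctuation statistic: mean of the 19 RMSDs to the
# representative structure (Å) ± sem
_COIL_RMSD = [
    ("WT", 22.4, 0.5, 19), ("S8D", 24.9, 0.4, 19), ("V79K", 23.1, 0.7, 19),
    ("T114D", 22.7, 0.5, 19), ("A115P", 22.7, 0.6, 19),
    ("A116E", 23.3, 0.6, 19), ("T143K", 22.3, 0.6, 19),
    ("A177K", 22.7, 0.6, 19), ("W210R", 22.9, 0.4, 19),
    ("G214D", 23.3, 0.6, 19), ("A215P", 22.7, 0.4, 19),
]


def load_native_rmsd() -> pd.DataFrame:
    """Native-state MD score: run-averaged Cα RMSD vs the crystal, per construct."""
    return pd.DataFrame(_NATIVE_RMSD, columns=["construct", "rmsd", "sem", "n"])


def load_coil_rmsd() -> pd.DataFrame:
    """Random-coil medoid fluctuation statistic per construct (n = 19 RMSDs)."""
    return pd.DataFrame(_COIL_RMSD, columns=["construct", "rmsd", "sem", "n"])


# 28 manually selected solvent-exposed extramembrane residues
_EXPOSED = [
    (8, "SER", "N"), (9, "PHE", "N"), (41, "ALA", "C"), (71, "GLY", "N"),
    (74, "GLN", "N"), (75, "LEU", "N"), (76, "GLN", "N"), (79, "VAL", "N"),
    (81, "VAL", "N"), (83, "THR", "N"), (86, "PRO", "N"), (114, "THR", "C"),
    (115, "ALA", "C"), (116, "ALA", "C"), (142, "ASN", "N"), (143, "THR", "N"),
    (146, "GLY", "N"), (177, "ALA", "C"), (180, "GLY", "C"), (182, "ARG", "C"),
    (210, "TRP", "N"), (212, "PRO", "N"), (214, "GLY", "N"), (215, "ALA", "N"),
    (216, "ALA", "N"), (249, "LEU", "C"), (250, "GLU", "C"), (251, "GLU", "C"),
]


def load_exposed_residues() -> pd.DataFrame:
    """The 28 solvent-exposed extramembrane residues submitted to the scan.

    Columns: residue_number, residue_type, side (N/C-terminal protein side).
    """
    return pd.DataFrame(_EXPOSED,
                        columns=["residue_number", "residue_type", "side"])
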