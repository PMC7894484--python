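"""Mutation-candidate selection for extramembrane thermo-stabilization.

The design procedure: (1) keep solvent-exposed extramembrane residues,
dropping any residue hit by an exclusion rule (restricted main-chain
dihedral position, Pro/acidic residue at a helix N-cap, basic residue at a
helix C-cap, ion-pair participation, predicted burial in the native-state
MD); (2) rank candidate single substitutions by predicted folding ΔΔG
(position-scan score, most negative first); (3) greedily pick the final set
by the refined (build-model) ΔΔG under per-site uniqueness, a
structural-change veto, an optional N/C-side balance bound, and an
effect-tag diversity preference on ties.

Solvent exposure and the dihedral restriction are caller-supplied
annotations (e.g. from a SASA program and a Ramachandran check), not
computed here: the rule set, not the geometry, is what this module encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResidueAnnotation",
    "MutationCandidate",
    "SelectionConstraints",
    "select_exposed_sites",
    "rank_position_scan",
    "finalize_candidates",
    "annotations_from_frame",
    "candidates_from_frame",
    "candidates_to_frame",
]

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_ACIDIC = {"ASP", "GLU"}
_BASIC = {"LYS", "ARG", "HIS"}
_SS_POSITIONS = {"helix_N_cap", "helix_C_cap", "helix_body", "strand",
                 "turn", "coil"}
_EFFECT_TAGS = {"helix_dipole", "entropic", "electrostatic", "hydrogen_bond",
                "other"}


@dataclass
class ResidueAnnotation:
    """Caller-supplied annotation of one residue of the reference model."""

    residue_number: int
    residue_type: str  # 3-letter code
    side: str  # "N" or "C" terminal side of the protein
    region: str  # "extramembrane" or "intramembrane"
    relative_exposure: float  # in [0, 1]
    ss_position: str = "coil"
    in_ion_pair: bool = False
    predicted_buried_in_md: bool = False
    dihedral_restricted: bool = False  # main-chain dihedral allowed only
    # for limited residue types (e.g. left-handed-helix region)

    def __post_init__(self) -> None:
        if self.residue_type not in _STANDARD_AA:
            raise ValueError(f"non-standard residue type {self.residue_type!r}")
        if not 0.0 <= self.relative_exposure <= 1.0:
            raise ValueError("relative_exposure must lie in [0, 1]")
        if self.side not in ("N", "C"):
            raise ValueError("side must be 'N' or 'C'")
        if self.region not in ("extramembrane", "intramembrane"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.ss_position not in _SS_POSITIONS:
            raise ValueError(f"unknown ss_position {self.ss_position!r}")


@dataclass
class MutationCandidate:
    """A single-substitution candidate with predicted ΔΔG scores."""

    site: int
    wild_type: str  # 1-letter
    substitution: str  # 1-letter
    ddg_position_scan: float  # kcal/mol; negative = predicted stabilizing
    ddg_build_model: Optional[float] = None
    effect_tag: Optional[str] = None
    effect_contribution: Optional[float] = None
    side: Optional[str] = None
    structural_change: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg_position_scan):
            raise ValueError("ddg_position_scan must be finite")
        if self.ddg_build_model is not None and not np.isfinite(self.ddg_build_model):
            raise ValueError("ddg_build_model must be finite")
        if self.effect_tag is not None and self.effect_tag not in _EFFECT_TAGS:
            raise ValueError(f"unknown effect tag {self.effect_tag!r}")

    @property
    def label(self) -> str:
        return f"{self.wild_type}{self.site}{self.substitution}"


@dataclass
class SelectionConstraints:
    """Configuration of the final-selection step."""

    max_side_imbalance: Optional[int] = None  # bound on |n(N) − n(C)|
    prefer_tag_diversity: bool = True


def select_exposed_sites(annotations: Sequence[ResidueAnnotation],
                         exposure_threshold: float = 0.3) -> list[int]:
    """Residue numbers that survive the exposure filter and exclusion rules.

    Kept: extramembrane residues with relative exposure ≥ threshold, minus
    residues with a restricted main-chain dihedral position, Pro or Asp/Glu
    at a helix N-cap, Lys/Arg/His at a helix C-cap, ion-pair participation,
    or predicted burial in the native-state MD.  Idempotent and always a
    subset of the annotated extramembrane residues.
    """
    if not annotations:
        raise ValueError("empty annotation list")
    kept = []
    for ann in annotations:
        if ann.region != "extramembrane":
            continue
        if ann.relative_exposure < exposure_threshold:
            continue
        if ann.dihedral_restricted:
            continue
        if ann.ss_position == "helix_N_cap" and (
                ann.residue_type == "PRO" or ann.residue_type in _ACIDIC):
            continue
        if ann.ss_position == "helix_C_cap" and ann.residue_type in _BASIC:
            continue
        if ann.in_ion_pair or ann.predicted_buried_in_md:
            continue
        kept.append(ann.residue_number)
    return sorted(kept)


def rank_position_scan(candidates: Sequence[MutationCandidate],
                       top_n: int) -> list[MutationCandidate]:
    """Top candidates by position-scan ΔΔG, most stabilizing first.

    Sorted ascending by ``ddg_position_scan`` with a stable
    (site, substitution) tie-break, truncated to ``top_n``.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > len(candidates):
        raise ValueError("top_n exceeds the number of candidates")
    ranked = sorted(candidates,
                    key=lambda c: (c.ddg_position_scan, c.site, c.substitution))
    return ranked[:top_n]


def finalize_candidates(ranked: Sequence[MutationCandidate], n_final: int,
                        constraints: SelectionConstraints | None = None,
                        ) -> list[MutationCandidate]:
    """Greedy final selection by build-model ΔΔG under the design constraints.

    Every candidate must carry a ``ddg_build_model``.  At each step the
    best-scoring feasible candidate is taken: sites are used at most once,
    candidates vetoed for a substantial predicted structural change are
    skipped, and with a configured side-balance bound a candidate is skipped
    when the remaining picks could no longer bring |n(N) − n(C)| within the
    bound.  On build-model ties an unrepresented effect tag is preferred,
    then (site, substitution) order.
    """
    if constraints is None:
        constraints = SelectionConstraints()
    if n_final <= 0:
        raise ValueError("n_final must be positive")
    for c in ranked:
        if c.ddg_build_model is None:
            raise ValueError(f"candidate {c.label} lacks ddg_build_model")
    pool = [c for c in ranked if not c.structural_change]
    chosen: list[MutationCandidate] = []
    used_sites: set[int] = set()
    used_tags: set[str] = set()
    counts = {"N": 0, "C": 0}
    bound = constraints.max_side_imbalance

    def feasible(c: MutationCandidate) -> bool:
        if c.site in used_sites:
            return False
        if bound is not None and c.side in counts:
            n = counts["N"] + (c.side == "N")
            cc = counts["C"] + (c.side == "C")
            remaining = n_final - len(chosen) - 1
            if abs(n - cc) > bound + remaining:
                return False
        return True

    def sort_key(c: MutationCandidate):
        tag_new = 0 if (constraints.prefer_tag_diversity
                        and c.effect_tag is not None
                        and c.effect_tag not in used_tags) else 1
        return (c.ddg_build_model, tag_new, c.site, c.substitution)

    while len(chosen) < n_final:
        options = [c for c in pool if feasible(c)]
        if not options:
            raise ValueError(
                f"only {len(chosen)} feasible candidates for n_final={n_final}")
        best = min(options, key=sort_key)
        chosen.append(best)
        pool.remove(best)
        used_sites.add(best.site)
        if best.effect_tag is not None:
            used_tags.add(best.effect_tag)
        if best.side in counts:
            counts[best.side] += 1
    return chosen


# ---------------------------------------------------------------------------
# DataFrame adapters
# ---------------------------------------------------------------------------

def annotations_from_frame(df: pd.DataFrame) -> list[ResidueAnnotation]:
    """Build annotations from a CSV-shaped table (see ResidueAnnotation fields)."""
    defaults = {"ss_position": "coil", "in_ion_pair": False,
                "predicted_buried_in_md": False, "dihedral_restricted": False}
    out = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in ("residue_number", "residue_type", "side",
                                      "region", "relative_exposure")}
        for k, dflt in defaults.items():
            kwargs[k] = row[k] if k in df.columns else dflt
        kwargs["residue_number"] = int(kwargs["residue_number"])
        kwargs["relative_exposure"] = float(kwargs["relative_exposure"])
        for k in ("in_ion_pair", "predicted_buried_in_md", "dihedral_restricted"):
            kwargs[k] = bool(kwargs[k])
        out.append(ResidueAnnotation(**kwargs))
    return out


def candidates_from_frame(df: pd.DataFrame) -> list[MutationCandidate]:
    """Build candidates from a ΔΔG table (position-scan and/or build-model)."""
    def _opt(row, key):
        if key not in df.columns or pd.isna(row[key]):
            return None
        return row[key]

    out = []
    for _, row in df.iterrows():
        bm = _opt(row, "ddg_build_model")
        ec = _opt(row, "effect_contribution")
        out.append(MutationCandidate(
            site=int(row["site"]),
            wild_type=str(row["wild_type"]),
            substitution=str(row["substitution"]),
            ddg_position_scan=float(row["ddg_position_scan"]),
            ddg_build_model=None if bm is None else float(bm),
            effect_tag=_opt(row, "effect_tag"),
            effect_contribution=None if ec is None else float(ec),
            side=_opt(row, "side"),
            structural_change=bool(row["structural_change"])
            if "structural_change" in df.columns else False,
        ))
    return out


def candidates_to_frame(candidates: Sequence[MutationCandidate]) -> pd.DataFrame:
    """Serialize candidates to the CSV schema used across the pipeline."""
    return pd.DataFrame([{
        "mutation": c.label, "site": c.site, "wild_type": c.wild_type,
        "substitution": c.substitution,
        "ddg_position_scan": c.ddg_position_scan,
        "ddg_build_model": c.ddg_build_model,
        "effect_tag": c.effect_tag,
        "effect_contribution": c.effect_contribution,
        "side": c.side, "structural_change": c.structural_change,
    } for c in candidates])
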