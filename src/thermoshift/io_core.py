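"""Structure / ensemble containers and file IO.

Coordinates are stored in ångström throughout; conversion to nm happens only
at reporting boundaries (gyration radius).  Residue numbering is taken
verbatim from the file (crystal numbering, e.g. 3–253 for the TR model), and
is never remapped.

PDB parsing is delegated to :mod:`gemmi`; a light pre-scan gives
line-numbered errors for malformed ATOM records, which gemmi silently
tolerates.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

CARBON_MASS = 12.011  # amu

__all__ = [
    "StructureModel",
    "Ensemble",
    "CoordinateSet",
    "PDBParseError",
    "read_structure",
    "read_ensemble",
    "write_ensemble",
    "select_calpha",
    "read_table",
    "write_table",
    "log",
]


class PDBParseError(ValueError):
    """Raised for malformed or inconsistent PDB input."""


def log(level: str, message: str) -> None:
    """Write a level-prefixed log line to standard error."""
    print(f"[{level.upper()}] {message}", file=sys.stderr)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """One structural snapshot: parallel per-atom arrays plus a model id.

    Invariants checked at construction: finite coordinates, positive masses,
    and residue numbers strictly increasing (at residue granularity) within
    each chain.
    """

    atom_names: list[str]
    residue_numbers: np.ndarray  # (N,) int
    residue_types: list[str]  # 3-letter codes
    chain_ids: list[str]
    xyz: np.ndarray  # (N, 3) float, Å
    masses: np.ndarray  # (N,) float, amu
    model_id: int = 1

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.atom_names)
        if not (len(self.residue_numbers) == len(self.residue_types)
                == len(self.chain_ids) == n == self.xyz.shape[0]
                == len(self.masses)):
            raise ValueError("per-atom arrays have inconsistent lengths")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (N, 3) array")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be positive")
        for chain in dict.fromkeys(self.chain_ids):
            nums = self.residue_numbers[np.array(self.chain_ids) == chain]
            # collapse runs of equal numbers (atoms of one residue)
            distinct = nums[np.r_[True, np.diff(nums) != 0]]
            if np.any(np.diff(distinct) <= 0):
                raise ValueError(
                    f"residue numbers not strictly increasing in chain {chain!r}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        """Index of a uniquely named atom; raises KeyError when absent."""
        for i in range(self.n_atoms):
            if (self.chain_ids[i] == chain_id
                    and self.residue_numbers[i] == residue_number
                    and self.atom_names[i] == atom_name):
                return i
        raise KeyError(f"atom {chain_id}:{residue_number}:{atom_name} not found")


@dataclass
class CoordinateSet:
    """A labelled point cloud used for superposition and Rg computation."""

    points: np.ndarray  # (N, 3), Å
    labels: list[tuple[str, int]]  # (chain_id, residue_number)
    masses: np.ndarray | None = None  # (N,), amu; default unit mass

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if self.points.shape[0] < 1:
            raise ValueError("CoordinateSet needs at least one point")
        if len(self.labels) != self.points.shape[0]:
            raise ValueError("label list length must equal the number of points")
        if self.masses is None:
            self.masses = np.ones(self.points.shape[0])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if len(self.masses) != self.points.shape[0]:
                raise ValueError("mass list length must equal the number of points")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class Ensemble:
    """An ordered series of snapshots with time stamps in ns."""

    snapshots: list[StructureModel]
    times: np.ndarray  # ns
    construct_label: str = ""
    run_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.snapshots) != len(self.times):
            raise ValueError("number of snapshots must equal number of times")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.snapshots)

    def calpha_coords(self, residue_range="all") -> tuple[np.ndarray, list[tuple[str, int]]]:
        """Stacked (n_frames, N, 3) Cα coordinates for a shared selection.

        All snapshots must expose the identical Cα selection (shared atom
        ordering invariant).
        """
        first = select_calpha(self.snapshots[0], residue_range)
        coords = np.empty((len(self.snapshots), first.n, 3))
        coords[0] = first.points
        for k, snap in enumerate(self.snapshots[1:], start=1):
            cs = select_calpha(snap, residue_range)
            if cs.labels != first.labels:
                raise ValueError(f"snapshot {k} Cα selection differs from snapshot 0")
            coords[k] = cs.points
        return coords, first.labels


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Reject malformed ATOM/HETATM records with a line-numbered error."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"{path}:{lineno}: truncated ATOM record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise PDBParseError(
                        f"{path}:{lineno}: malformed ATOM record ({exc})"
                    ) from None


def read_structure(path, chain: str = "A", model_index: int = 1,
                   include_hetatm: bool = False) -> StructureModel:
    """Read one model / one chain from a PDB file.

    Parameters
    ----------
    path : str or Path
        PDB-format text file (single- or multi-MODEL).
    chain : str
        Chain identifier to extract.
    model_index : int
        1-based MODEL index.
    include_hetatm : bool
        When True, HETATM records (e.g. the retinal ligand) are kept;
        by default only ATOM records are returned.

    Alternate locations: altloc blank or "A" kept, others dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    st = gemmi.read_pdb(str(path))
    if not (1 <= model_index <= len(st)):
        raise IndexError(f"model_index {model_index} out of range (file has {len(st)})")
    model = st[model_index - 1]
    gchain = model.find_chain(chain)
    if gchain is None:
        raise KeyError(f"chain {chain!r} not present in {path}")
    names, resnums, restypes, chains, coords, masses = [], [], [], [], [], []
    for res in gchain:
        if res.het_flag == "H" and not include_hetatm:
            continue
        for atom in res:
            if atom.altloc not in ("", "\0", "A"):
                continue
            names.append(atom.name)
            resnums.append(res.seqid.num)
            restypes.append(res.name)
            chains.append(chain)
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            masses.append(atom.element.weight if atom.element.weight > 0 else CARBON_MASS)
    if not names:
        raise PDBParseError(f"no atoms read from chain {chain!r} of {path}")
    return StructureModel(
        atom_names=names,
        residue_numbers=np.array(resnums),
        residue_types=restypes,
        chain_ids=chains,
        xyz=np.array(coords),
        masses=np.array(masses),
        model_id=model_index,
    )


def read_ensemble(paths_or_multimodel, times: Sequence[float], chain: str = "A",
                  construct_label: str = "", run_id: int = 0,
                  include_hetatm: bool = False) -> Ensemble:
    """Read an MD snapshot series from one multi-MODEL PDB or many files.

    The snapshots must share the Cα atom ordering; a mismatch raises.
    """
    if isinstance(paths_or_multimodel, (str, Path)):
        path = Path(paths_or_multimodel)
        _prescan_pdb(path)
        n_models = len(gemmi.read_pdb(str(path)))
        snapshots = [read_structure(path, chain, m, include_hetatm)
                     for m in range(1, n_models + 1)]
    else:
        snapshots = [read_structure(p, chain, 1, include_hetatm)
                     for p in paths_or_multimodel]
    if len(snapshots) != len(times):
        raise ValueError(
            f"{len(snapshots)} models but {len(times)} time stamps"
        )
    ref = select_calpha(snapshots[0], "all")
    for k, snap in enumerate(snapshots[1:], start=1):
        cs = select_calpha(snap, "all")
        if cs.labels != ref.labels:
            raise ValueError(f"model {k + 1} Cα selection differs from model 1")
    return Ensemble(snapshots=snapshots, times=np.asarray(times, dtype=float),
                    construct_label=construct_label, run_id=run_id)


def write_ensemble(models: Iterable[StructureModel], path) -> None:
    """Write snapshots as a multi-MODEL PDB file (via gemmi)."""
    st = gemmi.Structure()
    for k, m in enumerate(models, start=1):
        gm = gemmi.Model(k)
        for chain_id in dict.fromkeys(m.chain_ids):
            gc = gemmi.Chain(chain_id)
            current_num = None
            res = None
            for i in range(m.n_atoms):
                if m.chain_ids[i] != chain_id:
                    continue
                if m.residue_numbers[i] != current_num:
                    if res is not None:
                        gc.add_residue(res)
                    res = gemmi.Residue()
                    res.name = m.residue_types[i]
                    res.seqid = gemmi.SeqId(int(m.residue_numbers[i]), " ")
                    current_num = m.residue_numbers[i]
                atom = gemmi.Atom()
                atom.name = m.atom_names[i]
                atom.pos = gemmi.Position(*m.xyz[i])
                atom.element = gemmi.Element("C" if m.atom_names[i].startswith("C") else "X")
                res.add_atom(atom)
            if res is not None:
                gc.add_residue(res)
            gm.add_chain(gc)
        st.add_model(gm)
    st.write_pdb(str(path))


def write_structure(model: StructureModel, path) -> None:
    """Write a single snapshot as a PDB file."""
    write_ensemble([model], path)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def select_calpha(model: StructureModel, residue_range="all") -> CoordinateSet:
    """Cα coordinate selection ordered by residue number.

    ``residue_range`` is an inclusive ``(first, last)`` pair or ``"all"``.
    Masses are set to the carbon mass.  Raises on an empty selection.
    """
    names = np.array(model.atom_names)
    mask = names == "CA"
    if residue_range != "all":
        lo, hi = residue_range
        mask &= (model.residue_numbers >= lo) & (model.residue_numbers <= hi)
    idx = np.where(mask)[0]
    if idx.size == 0:
        raise ValueError(f"empty Cα selection for residue range {residue_range!r}")
    order = np.argsort(model.residue_numbers[idx], kind="stable")
    idx = idx[order]
    labels = [(model.chain_ids[i], int(model.residue_numbers[i])) for i in idx]
    return CoordinateSet(points=model.xyz[idx],
                         labels=labels,
                         masses=np.full(idx.size, CARBON_MASS))


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def read_table(path, schema: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a CSV with a header row, optionally enforcing a column schema.

    ``schema`` maps column name → python type (float, int, str).  Missing
    columns or non-numeric cells in numeric columns raise ``ValueError``.
    """
    df = pd.read_csv(path)
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns in {path}: {missing}")
        for col, typ in schema.items():
            if typ in (float, int):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    raise ValueError(
                        f"non-numeric value in column {col!r} at row {int(bad.idxmax())}"
                    )
                df[col] = coerced if typ is float else coerced.astype("Int64")
            else:
                df[col] = df[col].astype(str)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as CSV with header, no index column."""
    df.to_csv(path, index=False)
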