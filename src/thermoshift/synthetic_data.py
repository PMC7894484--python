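"""Synthetic generators emulating the pipeline's input data.

These generators stand in for cluster-scale MD trajectories and wet-lab
instruments: an idealized Cα helical-bundle as a synthetic crystal
reference, native-state snapshot ensembles (Gaussian positional noise with
optional slow AR(1) drift about the reference), random-coil conformer
ensembles (mean-reverting cumulative backbone displacement whose pairwise
RMSD grows monotonically with the fluctuation scale), exponential decoloration
decays, DSC endotherms on sloping baselines, and ion-pair distance traces.

No physical realism is claimed — no force field, membrane, or temperature
semantics.  Only the statistical contracts the analysis relies on are
reproduced, with construct presets carrying the published per-construct
parameters (decoloration rate constants, melting temperatures, native-state
RMSD levels) so the full pipeline can be exercised end to end.  Every
generator is bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import datasets
from .io_core import Ensemble, StructureModel
from .stability_metrics import DecolorationSeries, DSCThermogram

__all__ = [
    "ConstructPreset",
    "CONSTRUCT_PRESETS",
    "SyntheticConfig",
    "gen_toy_structure",
    "gen_native_runs",
    "gen_coil_ensemble",
    "gen_decoloration",
    "gen_dsc",
    "gen_distance_trace",
]

CA_STEP = 3.8  # consecutive Cα distance, Å
_HELIX_RADIUS = 2.3  # Å, ideal alpha-helix Cα radius
_HELIX_TURN = np.deg2rad(100.0)  # per-residue rotation
_LOOP_POINTS = 4  # interior residues per inter-helix connector (5 chords)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstructPreset:
    """Per-construct generator parameters.

    ``native_sigma`` (Å) sets the per-coordinate Gaussian noise of the
    native-state generator so the expected post-fit Cα RMSD (≈ √3·σ)
    reproduces the construct's published native-state score; ``coil_scale``
    (Å) sets the cumulative-walk displacement scale of the random-coil
    generator (only the ordering across constructs is meaningful);
    ``k`` (min⁻¹), ``tm`` (°C) and ``residual_pigment`` (%) carry the
    published stability measurements (None where not measured).
    """

    native_sigma: float
    coil_scale: float
    k: Optional[float]
    tm: Optional[float]
    residual_pigment: Optional[float]


def _build_presets() -> dict[str, ConstructPreset]:
    char = datasets.load_characterization().set_index("construct")
    native = datasets.load_native_rmsd().set_index("construct")
    # E[pairwise RMSD] ~ sqrt(6)*scale after superposition, so ~9 A puts the
    # medoid statistic in the ~20 A regime of a denatured 251-residue chain
    base_coil = 9.0
    presets = {}
    for label in char.index:
        row = char.loc[label]
        coil = base_coil * (1.15 if label == "S8D" else 1.0)
        presets[label] = ConstructPreset(
            native_sigma=float(native.loc[label, "rmsd"]) / np.sqrt(3.0),
            coil_scale=coil,
            k=None if np.isnan(row["k"]) else float(row["k"]),
            tm=None if np.isnan(row["tm"]) else float(row["tm"]),
            residual_pigment=float(row["residual_pigment"]),
        )
    return presets


CONSTRUCT_PRESETS: dict[str, ConstructPreset] = _build_presets()


@dataclass
class SyntheticConfig:
    """Bundle of generator settings for a reproducible simulated study."""

    seed: int = 0
    construct_presets: dict[str, ConstructPreset] = field(
        default_factory=lambda: dict(CONSTRUCT_PRESETS))
    n_runs: int = 3
    native_window: tuple[float, float] = (90.0, 100.0)
    native_interval: float = 0.2  # ns → 51 frames
    coil_members: int = 20
    decay_times: tuple[float, ...] = tuple(float(t) for t in range(11))  # min
    decay_noise_sd: float = 0.5  # % of initial
    dsc_grid: float = 0.01  # °C
    dsc_width: float = 3.0  # °C
    dsc_baseline_slope: float = 0.01  # per °C


# ---------------------------------------------------------------------------
# toy reference structure
# ---------------------------------------------------------------------------

def _arc_points(a: np.ndarray, b: np.ndarray, k: int, length: float,
                bulge: np.ndarray) -> np.ndarray:
    """k−1 interior points from a to b along k equal chords of ``length``.

    The points lie on a circular arc in the plane spanned by (b − a) and
    ``bulge``; requires |b − a| ≤ k·length.
    """
    d = float(np.linalg.norm(b - a))
    if d <= 0:
        raise ValueError("coincident arc endpoints")
    if d > k * length * (1 + 1e-9):
        raise ValueError("gap too wide for the connector")
    if d > k * length * (1 - 1e-9):  # effectively straight
        return np.array([a + (b - a) * j / k for j in range(1, k)])
    # solve sin(k b)/sin(b) = d/length for the half chord angle b
    lo, hi = 1e-12, np.pi / k - 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.sin(k * mid) / np.sin(mid) > d / length:
            lo = mid
        else:
            hi = mid
    beta = 0.5 * (lo + hi)
    rho = length / (2.0 * np.sin(beta))
    u = (b - a) / d
    v = bulge - np.dot(bulge, u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-9:  # bulge parallel to chord: pick any perpendicular
        v = np.cross(u, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(v) < 1e-9:
            v = np.cross(u, np.array([0.0, 1.0, 0.0]))
        nv = np.linalg.norm(v)
    v = v / nv
    mid = 0.5 * (a + b)
    h = np.sqrt(max(rho ** 2 - (d / 2.0) ** 2, 0.0))
    center = mid - h * v
    e1 = (a - center) / rho
    e2_raw = (b - center) / rho
    e2 = e2_raw - np.dot(e2_raw, e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    total = 2.0 * k * beta
    phis = total * np.arange(1, k) / k
    return np.array([center + rho * (np.cos(p) * e1 + np.sin(p) * e2)
                     for p in phis])


def gen_toy_structure(n_res: int = 251, n_helices: int = 7,
                      bundle_radius: float = 14.5, seed: int | None = None,
                      first_residue: int = 3, chain_id: str = "A",
                      ) -> StructureModel:
    """Synthetic Cα helical-bundle reference structure.

    A stand-in for a seven-transmembrane rhodopsin crystal model (not a real
    structure): ideal α-helical Cα traces (exact 3.8 Å consecutive spacing)
    arranged antiparallel on a circle of ``bundle_radius``, joined by
    equal-chord arc connectors.  The default dimensions (251 residues,
    7 helices, 14.5 Å bundle radius) follow seven-helix-bundle geometry and
    give a gyration radius near the 2.0 nm of the real crystal fold.
    Deterministic: ``seed`` is accepted for API symmetry only.

    Residues are numbered from ``first_residue`` (default 3, crystal
    numbering 3–253 for the default length).
    """
    n_loops = n_helices - 1
    n_helix_res = n_res - _LOOP_POINTS * n_loops
    if n_helices < 1 or n_helix_res < 4 * n_helices:
        raise ValueError(
            f"infeasible geometry: {n_res} residues cannot form "
            f"{n_helices} helices with {_LOOP_POINTS}-residue connectors")
    per = np.full(n_helices, n_helix_res // n_helices)
    per[: n_helix_res % n_helices] += 1
    rise = np.sqrt(CA_STEP ** 2 - (2 * _HELIX_RADIUS * np.sin(_HELIX_TURN / 2)) ** 2)

    coords: list[np.ndarray] = []
    for h in range(n_helices):
        ang = 2 * np.pi * h / n_helices
        center = bundle_radius * np.array([np.cos(ang), np.sin(ang), 0.0])
        n_h = per[h]
        height = (n_h - 1) * rise
        zs = np.arange(n_h) * rise - height / 2.0
        if h % 2 == 1:  # antiparallel bundle
            zs = zs[::-1]
        thetas = _HELIX_TURN * np.arange(n_h) + h  # phase offset per helix
        pts = center + np.column_stack([
            _HELIX_RADIUS * np.cos(thetas),
            _HELIX_RADIUS * np.sin(thetas),
            np.zeros(n_h)])
        pts[:, 2] = center[2] + zs
        if h > 0:
            a = coords[-1]
            b = pts[0]
            outward = 0.5 * (a + b)
            outward = outward - np.array([0.0, 0.0, outward[2]])
            bulge = outward if np.linalg.norm(outward) > 1e-6 else np.array([1.0, 0.0, 0.0])
            try:
                coords.extend(_arc_points(a, b, _LOOP_POINTS + 1, CA_STEP, bulge))
            except ValueError as exc:
                raise ValueError(
                    "infeasible geometry: inter-helix gap exceeds the "
                    f"connector span (reduce bundle_radius): {exc}") from None
        coords.extend(pts)
    xyz = np.asarray(coords)
    assert xyz.shape[0] == n_res
    resnums = first_residue + np.arange(n_res)
    return StructureModel(
        atom_names=["CA"] * n_res,
        residue_numbers=resnums,
        residue_types=["ALA"] * n_res,
        chain_ids=[chain_id] * n_res,
        xyz=xyz,
        masses=np.full(n_res, 12.011),
        model_id=1,
    )


def _clone_with_coords(base: StructureModel, xyz: np.ndarray,
                       model_id: int) -> StructureModel:
    return StructureModel(atom_names=list(base.atom_names),
                          residue_numbers=base.residue_numbers.copy(),
                          residue_types=list(base.residue_types),
                          chain_ids=list(base.chain_ids),
                          xyz=xyz, masses=base.masses.copy(),
                          model_id=model_id)


# ---------------------------------------------------------------------------
# native-state runs
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator, angle_sd_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, angle_sd_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def gen_native_runs(base: StructureModel, sigma: float, drift: float = 0.0,
                    n_runs: int = 3, window: tuple[float, float] = (90.0, 100.0),
                    interval: float = 0.2, seed: int | None = None,
                    n_frames: int | None = None,
                    run_scale_sd: float = 0.0,
                    rigid_offset_sd: float = 3.0,
                    rigid_rotation_sd: float = 2.0,
                    construct_label: str = "") -> list[Ensemble]:
    """Independent native-state runs about a reference structure.

    Each run applies a run-level rigid-body offset (random rotation of a few
    degrees plus a translation of scale ``rigid_offset_sd`` Å — removed by
    superposition, present so downstream fits are exercised), then per-frame
    per-atom displacement: isotropic Gaussian noise of per-coordinate scale
    ``sigma`` plus a slow AR(1) component (lag correlation 0.9) of
    stationary scale ``drift``.  ``run_scale_sd`` adds run-to-run variation
    by scaling sigma with a N(1, run_scale_sd²) factor per run, emulating
    the between-run spread of real trajectory averages.

    Times cover ``window`` at ``interval`` (endpoints inclusive).
    """
    if sigma < 0 or drift < 0:
        raise ValueError("sigma and drift must be non-negative")
    rng = np.random.default_rng(seed)
    start, end = window
    times = start + interval * np.arange(int(round((end - start) / interval)) + 1)
    if n_frames is not None and len(times) != n_frames:
        raise ValueError(f"window/interval give {len(times)} frames, not {n_frames}")
    n_atoms = base.n_atoms
    com = base.xyz.mean(axis=0)
    phi = 0.9
    runs = []
    for r in range(n_runs):
        R = _random_rotation(rng, rigid_rotation_sd) \
            if rigid_rotation_sd > 0 else np.eye(3)
        shift = rng.normal(0.0, rigid_offset_sd, size=3)
        moved = (base.xyz - com) @ R.T + com + shift
        s = sigma * max(float(rng.normal(1.0, run_scale_sd)), 0.1) \
            if run_scale_sd > 0 else sigma
        ar = np.zeros((n_atoms, 3))
        snaps = []
        for f in range(len(times)):
            if drift > 0:
                ar = phi * ar + np.sqrt(1 - phi ** 2) * rng.normal(0.0, drift, (n_atoms, 3))
            noise = rng.normal(0.0, s, (n_atoms, 3)) if s > 0 else 0.0
            snaps.append(_clone_with_coords(base, moved + ar + noise, f + 1))
        runs.append(Ensemble(snapshots=snaps, times=times,
                             construct_label=construct_label, run_id=r))
    return runs


# ---------------------------------------------------------------------------
# random-coil ensembles
# ---------------------------------------------------------------------------

def gen_coil_ensemble(base: StructureModel, coil_scale: float,
                      n_members: int = 20, seed: int | None = None,
                      correlation_length: float = 10.0,
                      ) -> list[StructureModel]:
    """Strongly perturbed conformers emulating a denatured-state ensemble.

    Each member displaces the backbone by a cumulative random perturbation
    with mean reversion along the chain — a chain-local Ornstein–Uhlenbeck
    field of stationary per-coordinate scale ``coil_scale`` (Å) and
    residue-lag correlation length ``correlation_length``.  Expected
    pairwise RMSD grows monotonically (linearly) with ``coil_scale``, while
    the correlation decay keeps the member-to-member RMSD spread in the
    ~10 % relative range observed for real denatured-state ensembles (a
    plain unreverted walk concentrates variance in the lowest chain mode
    and roughly doubles that spread), and the base fold keeps the ensemble
    loosely compact.
    """
    if coil_scale <= 0:
        raise ValueError("coil_scale must be positive")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    rng = np.random.default_rng(seed)
    n = base.n_atoms
    rho = np.exp(-1.0 / correlation_length)
    members = []
    for m in range(n_members):
        eps = rng.normal(0.0, coil_scale, (n, 3))
        field = np.empty((n, 3))
        field[0] = eps[0]
        for i in range(1, n):
            field[i] = rho * field[i - 1] + np.sqrt(1 - rho ** 2) * eps[i]
        members.append(_clone_with_coords(base, base.xyz + field, m + 1))
    return members


# ---------------------------------------------------------------------------
# decoloration and DSC
# ---------------------------------------------------------------------------

def gen_decoloration(k: float, times: Sequence[float] | None = None,
                     noise_sd: float = 0.0, seed: int | None = None,
                     construct_label: str = "") -> DecolorationSeries:
    """Exponential pigment decay P(t) = 100·e^{−kt} with Gaussian noise (%).

    Noise is additive with sd ``noise_sd`` (percentage points), clipped at
    zero; ``k`` in min⁻¹, times in minutes (default 0–10 min at 1 min).
    """
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(0.0, 11.0) if times is None else np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    p = 100.0 * np.exp(-k * t)
    if noise_sd > 0:
        p = p + rng.normal(0.0, noise_sd, t.shape)
    return DecolorationSeries(times=t, pigment=np.clip(p, 0.0, None),
                              construct_label=construct_label)


def _default_buffer_profile(T: np.ndarray) -> np.ndarray:
    # gently curved instrument background
    return 0.5 - 0.002 * T + 2e-5 * (T - 80.0) ** 2


def gen_dsc(tm: float, width: float = 3.0, amplitude: float = 1.0,
            baseline_slope: float = 0.01,
            buffer_profile: Callable[[np.ndarray], np.ndarray] | None = None,
            noise_sd: float = 0.0, grid: float = 0.01,
            seed: int | None = None, scan: tuple[float, float] = (30.0, 130.0),
            construct_label: str = "") -> tuple[DSCThermogram, DSCThermogram]:
    """Raw (sample, buffer) thermogram pair with a Gaussian endotherm.

    sample = buffer profile + linear baseline (slope per °C) + Gaussian peak
    of sd ``width`` centred at ``tm`` + noise; buffer = buffer profile +
    noise.  The scan covers ``scan`` on a ``grid``-°C spacing (grid ≤ 0.01
    needed for two-decimal Tm recovery).  ``tm`` must lie inside the scan.
    """
    lo, hi = scan
    if not (lo <= tm <= hi):
        raise ValueError(f"tm {tm} outside the scan window {scan}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round((hi - lo) / grid)) + 1
    T = np.linspace(lo, hi, n)
    prof = (_default_buffer_profile if buffer_profile is None else buffer_profile)(T)
    peak = amplitude * np.exp(-0.5 * ((T - tm) / width) ** 2)
    sample = prof + 0.2 + baseline_slope * (T - lo) + peak
    buffer = prof.copy()
    if noise_sd > 0:
        sample = sample + rng.normal(0.0, noise_sd, n)
        buffer = buffer + rng.normal(0.0, noise_sd, n)
    return (DSCThermogram(temperatures=T, signal=sample, stage="raw",
                          construct_label=construct_label),
            DSCThermogram(temperatures=T, signal=buffer, stage="raw"))


def gen_distance_trace(n_frames: int, n_below: int, cutoff: float = 5.0,
                       seed: int | None = None) -> np.ndarray:
    """Distance trace (Å) with exactly ``n_below`` values ≤ cutoff.

    Satisfying frames are uniform in [2.5, cutoff], the rest in
    (cutoff, 12]; the order is shuffled by the seed.
    """
    if not 0 <= n_below <= n_frames:
        raise ValueError("need 0 <= n_below <= n_frames")
    rng = np.random.default_rng(seed)
    below = rng.uniform(2.5, cutoff, n_below)
    above = rng.uniform(cutoff + 1e-9, 12.0, n_frames - n_below)
    trace = np.concatenate([below, above])
    rng.shuffle(trace)
    return trace
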