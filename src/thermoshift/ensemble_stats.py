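"""Structural-ensemble statistics.

Everything computed from MD snapshot ensembles: optimal Cα superposition
(Kabsch), late-window snapshot sampling, the native-state RMSD score versus
the crystal reference, the random-coil medoid fluctuation statistic,
per-residue Cα deviation profiles, ion-pair distance occupancy, and the
radius of gyration.

The native-state score mirrors the standard protocol: snapshots sampled
every 200 ps over the 90–100 ns window (51 frames, endpoints inclusive) are
each superposed onto the crystal Cα trace; the 51 RMSDs are averaged within
a run, and the run averages are summarized as mean ± s.e.m. across 3–4
independent runs.  The random-coil statistic takes 20 independent heavily
denatured snapshots, finds the medoid (the member minimizing its mean
pairwise RMSD), and uses its 19 RMSDs to the remaining members as the
fluctuation group — a proxy for denatured-state conformational entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .io_core import CoordinateSet, Ensemble, StructureModel, select_calpha
from .stat_protocol import GroupSummary, StatComparison, compare_groups

__all__ = [
    "SuperpositionResult",
    "RunGroupStats",
    "MedoidResult",
    "ResidueDeviationProfile",
    "DeviationComparison",
    "IonPairTrace",
    "GyrationTrace",
    "kabsch_superpose",
    "superposed_rmsd",
    "sample_snapshots",
    "native_state_score",
    "medoid_representative",
    "coil_fluctuation_compare",
    "per_residue_deviation",
    "compare_residue_profiles",
    "radius_of_gyration",
    "gyration_trace",
    "ion_pair_occupancy",
]


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of a mobile point set onto a reference.

    ``rotation`` is a proper rotation (det = +1); the fitted coordinates are
    ``rotation @ x + translation``.  ``degenerate`` flags collinear point
    sets whose rotation is not unique (the RMSD is still valid).
    """

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd: float  # Å
    degenerate: bool = False

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _kabsch_arrays(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Least-squares proper rotation+translation mapping P onto Q."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = P0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q0) ** 2, axis=1))))
    # collinear mobile/reference: second singular value vanishes
    degenerate = bool(S[0] > 0 and S[1] / S[0] < 1e-9)
    t = qc - R @ pc
    return R, t, rmsd, degenerate


def kabsch_superpose(mobile: CoordinateSet, reference: CoordinateSet) -> SuperpositionResult:
    """Optimal Cα superposition (Kabsch) of ``mobile`` onto ``reference``.

    Requires matched labels and at least 3 points; reflections are prevented
    by the determinant correction.  Collinear inputs are flagged degenerate.
    """
    if mobile.n != reference.n:
        raise ValueError(f"point counts differ: {mobile.n} vs {reference.n}")
    if mobile.n < 3:
        raise ValueError("superposition needs at least 3 points")
    if mobile.labels != reference.labels:
        raise ValueError("point labels do not match between mobile and reference")
    R, t, rmsd, degen = _kabsch_arrays(mobile.points, reference.points)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, degenerate=degen)


def superposed_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD between two (N, 3) arrays over rigid-body motion."""
    return _kabsch_arrays(np.asarray(P, float), np.asarray(Q, float))[2]


# ---------------------------------------------------------------------------
# frame sampling
# ---------------------------------------------------------------------------

def sample_snapshots(times: Sequence[float], window: tuple[float, float],
                     interval: float) -> np.ndarray:
    """Indices of frames at window start, start+interval, …, end (inclusive).

    Each requested time is matched to the nearest frame within a tolerance
    of interval/2; a gap raises.  The inclusive endpoints reproduce the
    51-frame (90–100 ns at 200 ps) and 501-frame (0–100 ns) counts.
    """
    times = np.asarray(times, dtype=float)
    start, end = window
    if interval <= 0:
        raise ValueError("interval must be positive")
    if end < start:
        raise ValueError("window end before start")
    n_steps = int(round((end - start) / interval))
    targets = start + interval * np.arange(n_steps + 1)
    if targets[-1] < end - 1e-9:  # window not an integer number of intervals
        targets = np.append(targets, end)
    idx = np.empty(targets.size, dtype=int)
    for k, t in enumerate(targets):
        j = int(np.argmin(np.abs(times - t)))
        if abs(times[j] - t) > interval / 2 + 1e-9:
            raise ValueError(f"no frame within {interval / 2} ns of t = {t} ns")
        idx[k] = j
    return idx


# ---------------------------------------------------------------------------
# native-state score
# ---------------------------------------------------------------------------

@dataclass
class RunGroupStats:
    """Per-run mean RMSDs and their across-run mean ± s.e.m."""

    per_run_mean_rmsd: np.ndarray
    mean: float
    sem: float
    n_runs: int

    @classmethod
    def from_run_means(cls, means: Sequence[float]) -> "RunGroupStats":
        v = np.asarray(means, dtype=float)
        if v.size < 2:
            raise ValueError("need at least 2 runs for a s.e.m.")
        return cls(per_run_mean_rmsd=v, mean=float(v.mean()),
                   sem=float(v.std(ddof=1) / np.sqrt(v.size)), n_runs=v.size)


def _matched_frames(run: Ensemble, crystal: CoordinateSet, residue_range):
    coords, labels = run.calpha_coords(residue_range)
    if labels != crystal.labels:
        # fall back to the label intersection, preserving crystal order
        common = [lab for lab in crystal.labels if lab in set(labels)]
        if len(common) < 3:
            raise ValueError("snapshot and crystal selections share fewer than 3 Cα")
        snap_pos = {lab: i for i, lab in enumerate(labels)}
        cry_pos = {lab: i for i, lab in enumerate(crystal.labels)}
        coords = coords[:, [snap_pos[lab] for lab in common]]
        ref = crystal.points[[cry_pos[lab] for lab in common]]
        return coords, ref, common
    return coords, crystal.points, labels


def native_state_score(runs: Sequence[Ensemble], crystal: CoordinateSet,
                       window: tuple[float, float], interval: float,
                       residue_range="all") -> RunGroupStats:
    """Run-group native-state RMSD score versus the crystal reference.

    For each run, every sampled snapshot is superposed onto the crystal Cα
    selection and the RMSDs averaged; the per-run averages are reduced to
    mean ± s.e.m. across runs (≥ 2 runs required).
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 independent runs")
    run_means = []
    for run in runs:
        idx = sample_snapshots(run.times, window, interval)
        coords, ref, _ = _matched_frames(run, crystal, residue_range)
        rmsds = [superposed_rmsd(coords[i], ref) for i in idx]
        run_means.append(float(np.mean(rmsds)))
    return RunGroupStats.from_run_means(run_means)


# ---------------------------------------------------------------------------
# medoid / random-coil fluctuation statistic
# ---------------------------------------------------------------------------

@dataclass
class MedoidResult:
    """The representative (medoid) member and its RMSDs to the others."""

    representative_index: int
    rmsd_to_others: np.ndarray  # (n-1,)
    mean_rmsd: float
    sem: float

    def as_group(self) -> GroupSummary:
        return GroupSummary.from_values(self.rmsd_to_others)


def _pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = superposed_rmsd(coords[i], coords[j])
    return M


def medoid_representative(ensemble: Sequence[StructureModel],
                          residue_range="all") -> MedoidResult:
    """Select the medoid of an ensemble by exhaustive pairwise RMSD.

    The medoid minimizes the mean RMSD to all other members; ties break to
    the lowest snapshot index.  Returns the medoid's n−1 RMSDs to the rest
    as the fluctuation group.
    """
    n = len(ensemble)
    if n < 3:
        raise ValueError("medoid selection needs at least 3 members")
    ref = select_calpha(ensemble[0], residue_range)
    coords = np.empty((n, ref.n, 3))
    coords[0] = ref.points
    for k in range(1, n):
        cs = select_calpha(ensemble[k], residue_range)
        if cs.labels != ref.labels:
            raise ValueError(f"member {k} Cα selection differs from member 0")
        coords[k] = cs.points
    M = _pairwise_rmsd_matrix(coords)
    mean_to_others = M.sum(axis=1) / (n - 1)
    rep = int(np.argmin(mean_to_others))  # argmin takes the lowest index on ties
    others = np.delete(M[rep], rep)
    v = others
    return MedoidResult(representative_index=rep, rmsd_to_others=v,
                        mean_rmsd=float(v.mean()),
                        sem=float(v.std(ddof=1) / np.sqrt(v.size)))


def coil_fluctuation_compare(ensembles: Mapping[str, Sequence[StructureModel]],
                             wild_type: str, residue_range="all",
                             alpha: float = 0.05,
                             ) -> tuple[dict[str, MedoidResult], dict[str, StatComparison]]:
    """Medoid fluctuation statistic per construct, each mutant vs wild type.

    Every construct must supply the same ensemble size; each mutant's
    (n−1)-value RMSD group is compared to the wild type's with the branching
    test protocol.
    """
    if wild_type not in ensembles:
        raise KeyError(f"wild-type key {wild_type!r} missing")
    sizes = {len(v) for v in ensembles.values()}
    if len(sizes) != 1:
        raise ValueError(f"ensemble sizes differ across constructs: {sorted(sizes)}")
    medoids = {label: medoid_representative(ens, residue_range)
               for label, ens in ensembles.items()}
    wt_group = medoids[wild_type].as_group()
    comparisons = {}
    for label, med in medoids.items():
        if label == wild_type:
            continue
        comparisons[label] = compare_groups(med.as_group(), wt_group, alpha)
    return medoids, comparisons


# ---------------------------------------------------------------------------
# per-residue deviations
# ---------------------------------------------------------------------------

@dataclass
class ResidueDeviationProfile:
    """Per-run, per-residue mean Cα deviation from the crystal (Å)."""

    residue_numbers: np.ndarray  # (N,)
    per_run_deviation: np.ndarray  # (n_runs, N)
    mean_deviation: np.ndarray  # (N,)


@dataclass
class DeviationComparison:
    """Residue-wise two-tailed t comparison of two deviation profiles."""

    residue_numbers: np.ndarray
    p_values: np.ndarray
    larger_in_b: np.ndarray  # bool: profile-b deviation exceeds profile-a
    flagged: np.ndarray  # bool: significantly larger in b


def per_residue_deviation(runs: Sequence[Ensemble], crystal: CoordinateSet,
                          window: tuple[float, float], interval: float,
                          residue_range="all") -> ResidueDeviationProfile:
    """Per-residue Cα deviation after a single global superposition.

    Each sampled snapshot is globally fitted to the crystal on the full Cα
    selection (no per-residue refit); the per-residue Euclidean deviations
    are averaged over the sampled snapshots within each run.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 independent runs")
    profiles = []
    resnums = None
    for run in runs:
        idx = sample_snapshots(run.times, window, interval)
        coords, ref, labels = _matched_frames(run, crystal, residue_range)
        nums = np.array([lab[1] for lab in labels])
        if resnums is None:
            resnums = nums
        elif not np.array_equal(resnums, nums):
            raise ValueError("residue sets differ between runs")
        dev = np.zeros(len(labels))
        for i in idx:
            R, t, _, _ = _kabsch_arrays(coords[i], ref)
            fitted = coords[i] @ R.T + t
            dev += np.linalg.norm(fitted - ref, axis=1)
        profiles.append(dev / len(idx))
    per_run = np.vstack(profiles)
    return ResidueDeviationProfile(residue_numbers=resnums,
                                   per_run_deviation=per_run,
                                   mean_deviation=per_run.mean(axis=0))


def compare_residue_profiles(a: ResidueDeviationProfile,
                             b: ResidueDeviationProfile,
                             alpha: float = 0.05,
                             bonferroni: bool = False) -> DeviationComparison:
    """Flag residues whose deviation is significantly larger in profile b.

    Per residue, a two-tailed Student's t-test across runs at ``alpha``
    (no multiple-testing correction by default; ``bonferroni=True`` divides
    alpha by the residue count).  A residue is flagged when the test is
    significant *and* the profile-b mean deviation exceeds profile-a's.
    """
    import warnings

    from scipy import stats

    if not np.array_equal(a.residue_numbers, b.residue_numbers):
        raise ValueError("profiles cover different residues")
    with warnings.catch_warnings():
        # identical (zero-variance) columns trigger a scipy precision
        # warning; their NaN p-values are mapped to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(b.per_run_deviation, a.per_run_deviation,
                              axis=0, equal_var=True)
    p = np.asarray(res.pvalue)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical columns
    thr = alpha / len(a.residue_numbers) if bonferroni else alpha
    larger = b.mean_deviation > a.mean_deviation
    return DeviationComparison(residue_numbers=a.residue_numbers,
                               p_values=p, larger_in_b=larger,
                               flagged=(p < thr) & larger)


# ---------------------------------------------------------------------------
# gyration radius
# ---------------------------------------------------------------------------

def radius_of_gyration(model: StructureModel, residue_range="all",
                       calpha_only: bool = True,
                       mass_weighted: bool = True) -> float:
    """Radius of gyration of a selection, in nm.

    Rg = sqrt(Σ mᵢ|rᵢ − r_com|² / Σ mᵢ) about the selection's center of
    mass.  Mass-weighted by default; unweighted Cα-only mode via
    ``mass_weighted=False``.
    """
    if calpha_only:
        cs = select_calpha(model, residue_range)
        pts, masses = cs.points, cs.masses
    else:
        mask = np.ones(model.n_atoms, dtype=bool)
        if residue_range != "all":
            lo, hi = residue_range
            mask = (model.residue_numbers >= lo) & (model.residue_numbers <= hi)
        if not mask.any():
            raise ValueError("empty selection")
        pts, masses = model.xyz[mask], model.masses[mask]
    w = masses if mass_weighted else np.ones(len(pts))
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total mass in selection")
    com = (pts * w[:, None]).sum(axis=0) / total
    rg2 = float((w * np.sum((pts - com) ** 2, axis=1)).sum() / total)
    return np.sqrt(rg2) / 10.0  # Å → nm


@dataclass
class GyrationTrace:
    """Across-run mean ± s.e.m. radius-of-gyration time course (nm)."""

    times: np.ndarray  # ns
    rg_mean: np.ndarray  # nm
    rg_sem: np.ndarray  # nm
    n_runs: int


def gyration_trace(runs: Sequence[Ensemble], residue_range="all",
                   stride: float | None = None,
                   mass_weighted: bool = True) -> GyrationTrace:
    """Per-time mean ± s.e.m. of Rg across ≥ 2 runs of equal length."""
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for a s.e.m. trace")
    n_frames = {len(r) for r in runs}
    if len(n_frames) != 1:
        raise ValueError("runs have unequal numbers of frames")
    times = runs[0].times
    if stride is not None:
        idx = sample_snapshots(times, (times[0], times[-1]), stride)
    else:
        idx = np.arange(len(times))
    rg = np.array([[radius_of_gyration(r.snapshots[i], residue_range,
                                       mass_weighted=mass_weighted)
                    for i in idx] for r in runs])
    return GyrationTrace(times=times[idx], rg_mean=rg.mean(axis=0),
                         rg_sem=rg.std(axis=0, ddof=1) / np.sqrt(len(runs)),
                         n_runs=len(runs))


# ---------------------------------------------------------------------------
# ion-pair occupancy
# ---------------------------------------------------------------------------

@dataclass
class IonPairTrace:
    """Per-frame distance trace and boundary-inclusive cutoff occupancy."""

    distances: np.ndarray  # Å
    cutoff: float  # Å
    n_satisfying: int
    occupancy_percent: float  # unrounded; round only at reporting


AtomSpec = tuple[str, int, str]  # (chain_id, residue_number, atom_name)


def ion_pair_occupancy(ensemble_or_distances: Union[Ensemble, Sequence[float]],
                       pair: tuple[AtomSpec, AtomSpec] | None = None,
                       cutoff: float = 5.0) -> IonPairTrace:
    """Fraction of frames with an atom-pair distance not greater than cutoff.

    Accepts either a precomputed distance list or an :class:`Ensemble` plus
    an atom pair such as ``(("A", 6, "CD"), ("A", 79, "NZ"))`` for the
    Glu6–Lys79 salt bridge.  A distance exactly at the cutoff counts as
    satisfying ("not greater than").
    """
    if isinstance(ensemble_or_distances, Ensemble):
        if pair is None:
            raise ValueError("an atom pair is required with Ensemble input")
        (c1, r1, a1), (c2, r2, a2) = pair
        dists = []
        for k, snap in enumerate(ensemble_or_distances.snapshots):
            try:
                i = snap.atom_index(c1, r1, a1)
                j = snap.atom_index(c2, r2, a2)
            except KeyError as exc:
                raise KeyError(f"frame {k}: {exc}") from None
            dists.append(float(np.linalg.norm(snap.xyz[i] - snap.xyz[j])))
        distances = np.array(dists)
    else:
        distances = np.asarray(ensemble_or_distances, dtype=float)
    if distances.size == 0:
        raise ValueError("empty distance trace")
    n_sat = int(np.count_nonzero(distances <= cutoff))
    return IonPairTrace(distances=distances, cutoff=float(cutoff),
                        n_satisfying=n_sat,
                        occupancy_percent=100.0 * n_sat / distances.size)
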