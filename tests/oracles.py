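"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths under test: superposition RMSD via
scipy's rotation fitting or an Euler-angle grid search, medoid selection by
plain double-loop enumeration.
"""

import numpy as np
from scipy.spatial.transform import Rotation


def align_vectors_rmsd(P, Q):
    """Minimum RMSD via scipy Rotation.align_vectors (independent route)."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    _, rssd = Rotation.align_vectors(Q0, P0)
    return rssd / np.sqrt(len(P))


def grid_search_rmsd(P, Q, fine_step_deg=0.5):
    """Minimum RMSD by hierarchical exhaustive search over Euler angles.

    Coarse-to-fine refinement down to ``fine_step_deg`` (then one further
    10x refinement so the quadratic minimum is resolved well below the
    1e-3 Å comparison tolerance).  Translation handled by centroid removal,
    which is optimal for any fixed rotation.
    """
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def batch_rmsd(angles):
        R = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        moved = np.einsum("rij,nj->rni", R, P0)
        return np.sqrt(np.mean(np.sum((moved - Q0) ** 2, axis=2), axis=1))

    # coarse global scan; keep several candidates (Euler coordinates are
    # singular near b = 0/180, so a single basin can hide the minimum)
    grid = np.array([[a, b, c]
                     for a in np.arange(-180, 180, 6.0)
                     for b in np.arange(0, 180.001, 6.0)
                     for c in np.arange(-180, 180, 6.0)])
    vals = batch_rmsd(grid)
    candidates = grid[np.argsort(vals)[:30]]
    best_val = vals.min()
    for start in candidates:
        best = start
        for step in (2.0, fine_step_deg, fine_step_deg / 10.0):
            offs = np.arange(-5 * step, 5 * step + step / 2, step)
            local = np.array([[best[0] + a, best[1] + b, best[2] + c]
                              for a in offs for b in offs for c in offs])
            lv = batch_rmsd(local)
            if lv.min() < batch_rmsd(best[None])[0]:
                best = local[np.argmin(lv)]
            best_val = min(best_val, lv.min())
    return best_val


def brute_medoid(coords, rmsd_fn=align_vectors_rmsd):
    """Medoid by full O(n^2) enumeration with an independent RMSD."""
    n = len(coords)
    means = []
    for i in range(n):
        tot = 0.0
        for j in range(n):
            if i != j:
                tot += rmsd_fn(coords[i], coords[j])
        means.append(tot / (n - 1))
    return int(np.argmin(means)), means
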