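"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the superposition
oracle minimizes RMSD by brute-force search over Euler-angle grids (with
local refinement), and the cavity oracle estimates volume by Monte-Carlo
rejection sampling.  Fixture builders (sphere cages) live here too.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.transform import Rotation


def _rmsd_after_rotation(rotations, mobile_c, target_c):
    """RMSD for each rotation, with centroids pre-aligned."""
    fitted = np.einsum("kij,nj->kni", rotations, mobile_c)
    return np.sqrt(((fitted - target_c[None]) ** 2).sum(axis=2).mean(axis=1))


def grid_min_rmsd(mobile, target, coarse_step=0.15, refine_levels=3):
    """Brute-force minimal RMSD over proper rotations via Euler-angle search.

    Scans a coarse grid over all of SO(3), then refines around the best
    point with a shrinking grid.  Returns the minimal RMSD found.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    m_c = mobile - mobile.mean(axis=0)
    t_c = target - target.mean(axis=0)

    def eval_angles(alphas, betas, gammas):
        grid = np.stack(
            np.meshgrid(alphas, betas, gammas, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        rots = Rotation.from_euler("zyz", grid).as_matrix()
        vals = _rmsd_after_rotation(rots, m_c, t_c)
        k = int(np.argmin(vals))
        return grid[k], float(vals[k])

    best_angles, best = eval_angles(
        np.arange(0, 2 * np.pi, coarse_step),
        np.arange(0, np.pi + coarse_step, coarse_step),
        np.arange(0, 2 * np.pi, coarse_step),
    )
    step = coarse_step
    for _ in range(refine_levels):
        step /= 5.0
        a, b, g = best_angles
        offs = np.arange(-5, 6) * step
        best_angles, best = eval_angles(a + offs, b + offs, g + offs)
    return best


def refined_min_rmsd_rotation(mobile, target):
    """Tightly converged brute-force overlay; returns (rmsd, fitted_mobile).

    Grid search followed by derivative-free local optimization of the Euler
    angles, so the per-atom fitted coordinates can be compared at ~1e-8.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    m_c = mobile - mobile.mean(axis=0)
    t_c = target - target.mean(axis=0)

    def objective(angles):
        rot = Rotation.from_euler("zyz", angles).as_matrix()
        return _rmsd_after_rotation(rot[None], m_c, t_c)[0]

    coarse = np.stack(
        np.meshgrid(
            np.arange(0, 2 * np.pi, 0.2),
            np.arange(0, np.pi + 0.2, 0.2),
            np.arange(0, 2 * np.pi, 0.2),
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    rots = Rotation.from_euler("zyz", coarse).as_matrix()
    vals = _rmsd_after_rotation(rots, m_c, t_c)
    start = coarse[int(np.argmin(vals))]
    res = minimize(
        objective, start, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    rot = Rotation.from_euler("zyz", res.x).as_matrix()
    fitted = m_c @ rot.T + target.mean(axis=0)
    return float(res.fun), fitted


def golden_sphere(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def mc_cavity_volume(
    centers, radius, seed_point=None, n_samples=400_000, rng=None
):
    """Monte-Carlo volume of {inside hull of centers} minus {atom spheres}.

    Valid as a cavity oracle when the shell is dense enough that the free
    set inside the hull is a single connected void (as for the sphere-cage
    fixtures).  ``radius`` is the common occlusion radius of all atoms.
    """
    rng = rng or np.random.default_rng(0)
    centers = np.asarray(centers, float)
    lo, hi = centers.min(axis=0), centers.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    tree = cKDTree(centers)
    d, _ = tree.query(pts, k=1)
    outside_atoms = d > radius
    tri = Delaunay(centers)
    inside_hull = tri.find_simplex(pts) >= 0
    frac = np.mean(outside_atoms & inside_hull)
    return float(frac * np.prod(hi - lo))
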