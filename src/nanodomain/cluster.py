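"""Ripley's-H-seeded DBSCAN characterization of surface nanoclusters.

The analysis chain, applied to a raw localization table with no manual
intervention:

1. Ripley's H function, H(r) = L(r) - r with L = sqrt(K / pi), is computed
   on three analysis areas dense in well-separated clusters.  H peaks near
   the characteristic cluster scale and is ~0 under complete spatial
   randomness (CSR).
2. The "preferential cluster size" of each area is the radius of the
   global H maximum; the three values are averaged and multiplied by a
   fixed 0.45 correction factor to obtain the DBSCAN seed radius (eps).
3. DBSCAN at that eps yields every individual cluster, from which size
   (disk-equivalent diameter), cluster-to-cluster nearest-neighbour
   distance, per-cluster localization counts, and per-cell totals are
   derived.

:class:`RipleySeededDBSCAN` packages the chain as a scikit-learn style
clusterer; the module-level functions expose each stage individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN
from sklearn.utils.validation import check_is_fitted

SEED_RADIUS_FACTOR = 0.45


class NoClusterSignalWarning(UserWarning):
    """Raised when H(r) shows no interior maximum above the CSR envelope."""


@dataclass
class RipleyCurve:
    """Ripley K/L/H evaluated on a radius grid for one analysis region."""

    radii: np.ndarray
    k: np.ndarray
    l: np.ndarray
    h: np.ndarray
    area: float
    n_points: int
    degenerate: bool = False   # duplicate points present

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        if r.ndim != 1 or len(r) < 1 or np.any(r <= 0) or np.any(
                np.diff(r) <= 0):
            raise ValueError("radii must be positive and strictly increasing")


@dataclass
class ClusterSet:
    """DBSCAN labels plus per-cluster and per-cell summary metrics."""

    labels: np.ndarray
    table: pd.DataFrame          # one row per cluster
    eps: float
    min_pts: int
    n_localizations: int = 0
    noise_fraction: float = 0.0

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    @property
    def locs_per_cell(self) -> int:
        return self.n_localizations


# ---------------------------------------------------------------------------
# Ripley statistics
# ---------------------------------------------------------------------------

def ripley_h(points: np.ndarray, radii: np.ndarray, area: float,
             focal_mask: np.ndarray | None = None) -> RipleyCurve:
    """Ripley's K, L, H by exact pair counting.

    Without a focal mask this is the classic estimator
    K(r) = (A / (n (n-1))) * sum_{i != j} 1(d_ij <= r) with no edge
    correction.  With ``focal_mask`` only the masked points act as centres
    while all points supply neighbours -- the guard-zone estimator
    K(r) = sum_i count_i(r) / (lambda * n_focal) with lambda = n / A,
    unbiased when the guard ring is at least ``max(radii)`` wide.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    radii = np.asarray(radii, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("Ripley's K needs at least 2 points")
    if area <= 0:
        raise ValueError("region area must be positive")
    tree = cKDTree(points)
    degenerate = tree.count_neighbors(tree, 1e-9) > n
    if degenerate:
        warnings.warn("coincident points: K jumps at r -> 0+",
                      NoClusterSignalWarning, stacklevel=2)
    if focal_mask is None:
        cum = tree.count_neighbors(tree, radii).astype(float) - n
        k = area * cum / (n * (n - 1))
    else:
        focal_mask = np.asarray(focal_mask, dtype=bool)
        nf = int(focal_mask.sum())
        if nf < 1:
            raise ValueError("focal mask selects no points")
        ftree = cKDTree(points[focal_mask])
        cum = ftree.count_neighbors(tree, radii).astype(float) - nf
        k = cum / ((n / area) * nf)
    l = np.sqrt(k / np.pi)
    return RipleyCurve(radii=radii, k=k, l=l, h=l - radii, area=area,
                       n_points=n, degenerate=degenerate)


def preferential_cluster_size(curve: RipleyCurve) -> float:
    """Radius of the global H maximum (ties -> smallest radius).

    A maximum at the grid boundary, or a monotone H with no interior
    maximum, still returns the boundary value but raises
    :class:`NoClusterSignalWarning`.
    """
    i = int(np.argmax(curve.h))
    if i == 0 or i == len(curve.radii) - 1:
        warnings.warn("H maximum at radius-grid boundary; no interior "
                      "preferential size", NoClusterSignalWarning,
                      stacklevel=2)
    return float(curve.radii[i])


def derive_seed_radius(sizes) -> float:
    """DBSCAN seed radius: mean preferential size x 0.45."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("need at least one preferential cluster size")
    if np.any(sizes <= 0):
        raise ValueError("preferential sizes must be positive")
    return float(sizes.mean() * SEED_RADIUS_FACTOR)


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Standard DBSCAN labels (-1 = noise); a core point has at least
    ``min_pts`` neighbours within ``eps`` counting itself."""
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_pts).fit(points).labels_


# ---------------------------------------------------------------------------
# cluster metrics
# ---------------------------------------------------------------------------

def cluster_metrics(points: np.ndarray, labels: np.ndarray,
                    eps: float = np.nan, min_pts: int = 0,
                    diameter: str = "disk") -> ClusterSet:
    """Per-cluster centroid, diameter, localization count, and
    nearest-neighbour centroid distance.

    The default diameter is the disk-equivalent 4 * sqrt((var_x + var_y)/2),
    which is exact in expectation for points uniform on a disk;
    ``diameter="max_extent"`` uses the maximum pairwise distance instead.
    Nearest-neighbour distance is undefined (NaN) with a single cluster.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = np.asarray(labels, dtype=int)
    if len(points) != len(labels):
        raise ValueError("points and labels length mismatch")
    ids = np.unique(labels[labels >= 0])
    rows = []
    for cid in ids:
        q = points[labels == cid]
        cx, cy = q.mean(axis=0)
        if diameter == "disk":
            diam = 4.0 * np.sqrt(q.var(axis=0).mean())
        elif diameter == "max_extent":
            d = np.sqrt(((q[:, None, :] - q[None, :, :]) ** 2).sum(-1))
            diam = float(d.max())
        else:
            raise ValueError("diameter must be 'disk' or 'max_extent'")
        rows.append({"cluster_id": int(cid), "x_nm": cx, "y_nm": cy,
                     "n_localizations": len(q), "diameter_nm": float(diam)})
    table = pd.DataFrame(rows, columns=["cluster_id", "x_nm", "y_nm",
                                        "n_localizations", "diameter_nm"])
    if len(table) >= 2:
        cen = table[["x_nm", "y_nm"]].to_numpy()
        d, _ = cKDTree(cen).query(cen, k=2)
        table["nn_distance_nm"] = d[:, 1]
    else:
        table["nn_distance_nm"] = np.nan
    noise = float((labels == -1).sum()) / len(labels) if len(labels) else 0.0
    return ClusterSet(labels=labels, table=table, eps=float(eps),
                      min_pts=int(min_pts), n_localizations=len(points),
                      noise_fraction=noise)


def estimate_antibodies_per_cell(cluster_set: ClusterSet,
                                 locs_per_antibody: float = 50.0) -> int:
    """Approximate bound antibodies per cell from the total localization
    count and a per-antibody localization yield (calibration constant
    covering dye stoichiometry and re-blinking)."""
    if locs_per_antibody <= 0:
        raise ValueError("locs_per_antibody must be positive")
    return int(round(cluster_set.locs_per_cell / locs_per_antibody))


# ---------------------------------------------------------------------------
# analysis-area selection
# ---------------------------------------------------------------------------

def select_analysis_areas(points: np.ndarray, n_areas: int = 3,
                          inner_side: float = 2000.0,
                          guard: float = 500.0) -> list:
    """Origins of the ``n_areas`` densest non-overlapping analysis windows.

    Candidate outer windows (side ``inner_side + 2 * guard``) slide on a
    half-inner-side grid; windows are ranked by the localization count of
    their inner region and picked greedily without overlap.  Returns
    ``(x0, y0)`` origins of the *outer* windows.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    outer = inner_side + 2 * guard
    step = inner_side / 2
    xmax = points[:, 0].max() - outer
    ymax = points[:, 1].max() - outer
    if xmax < 0 or ymax < 0:
        raise ValueError("field smaller than one analysis window")
    xs = np.arange(0.0, xmax + step / 2, step)
    ys = np.arange(0.0, ymax + step / 2, step)
    cands = []
    for x0 in xs:
        for y0 in ys:
            m = ((points[:, 0] >= x0 + guard)
                 & (points[:, 0] < x0 + guard + inner_side)
                 & (points[:, 1] >= y0 + guard)
                 & (points[:, 1] < y0 + guard + inner_side))
            cands.append((int(m.sum()), float(x0), float(y0)))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    chosen = []
    for cnt, x0, y0 in cands:
        if all(abs(x0 - a) >= outer or abs(y0 - b) >= outer
               for a, b in chosen):
            chosen.append((x0, y0))
        if len(chosen) == n_areas:
            break
    return chosen


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class RipleySeededDBSCAN(ClusterMixin, BaseEstimator):
    """Nanocluster segmentation with a Ripley's-H-derived DBSCAN radius.

    Parameters
    ----------
    min_samples : int
        DBSCAN ``min_pts``; a core point has at least this many neighbours
        within eps, itself included.
    correction_factor : float
        Multiplier applied to the averaged preferential cluster size to
        obtain eps (fixed to 0.45 in the reference workflow).
    n_areas, area_side, guard_nm : int, float, float
        Number, inner side length (nm), and guard-ring width (nm) of the
        analysis windows used for the H curves.  If ``areas`` is given it
        overrides automatic selection with explicit outer-window origins.
    radius_step, radius_max : float
        H radius grid: ``radius_step`` to ``radius_max`` (defaults to the
        guard width, keeping the guard-ring estimator unbiased).
    csr_envelope : int
        CSR simulations per area for the null envelope; an area whose max
        H does not exceed the envelope contributes no preferential size.
        0 disables the check.
    locs_per_antibody : float
        Calibration constant for the per-cell antibody estimate.

    Attributes
    ----------
    labels_, eps_, preferential_sizes_, ripley_curves_, cluster_table_,
    n_clusters_, noise_fraction_, antibodies_per_cell_, report_
    """

    def __init__(self, min_samples: int = 4,
                 correction_factor: float = SEED_RADIUS_FACTOR,
                 n_areas: int = 3, area_side: float = 2000.0,
                 guard_nm: float = 500.0, radius_step: float = 5.0,
                 radius_max: float | None = None, areas=None,
                 csr_envelope: int = 19, min_samples_sweep=(3, 5, 10),
                 diameter: str = "disk", locs_per_antibody: float = 50.0,
                 random_state: int | None = 0):
        self.min_samples = min_samples
        self.correction_factor = correction_factor
        self.n_areas = n_areas
        self.area_side = area_side
        self.guard_nm = guard_nm
        self.radius_step = radius_step
        self.radius_max = radius_max
        self.areas = areas
        self.csr_envelope = csr_envelope
        self.min_samples_sweep = min_samples_sweep
        self.diameter = diameter
        self.locs_per_antibody = locs_per_antibody
        self.random_state = random_state

    # -- internals --------------------------------------------------------

    def _area_curve(self, X, origin, radii, rng):
        """H curve for one outer window with guard-ring focal mask, plus a
        CSR-envelope decision on whether it carries a clustering signal."""
        x0, y0 = origin
        outer = self.area_side + 2 * self.guard_nm
        m = ((X[:, 0] >= x0) & (X[:, 0] < x0 + outer)
             & (X[:, 1] >= y0) & (X[:, 1] < y0 + outer))
        pts = X[m]
        if len(pts) < max(2, self.min_samples):
            return None, False
        focal = ((pts[:, 0] >= x0 + self.guard_nm)
                 & (pts[:, 0] < x0 + self.guard_nm + self.area_side)
                 & (pts[:, 1] >= y0 + self.guard_nm)
                 & (pts[:, 1] < y0 + self.guard_nm + self.area_side))
        if focal.sum() < 2:
            return None, False
        curve = ripley_h(pts, radii, outer ** 2, focal_mask=focal)
        significant = True
        if self.csr_envelope:
            n = len(pts)
            env = []
            env_radii = radii[::4] if len(radii) > 4 else radii
            for _ in range(self.csr_envelope):
                u = rng.random((n, 2)) * outer
                fm = ((u[:, 0] >= self.guard_nm)
                      & (u[:, 0] < self.guard_nm + self.area_side)
                      & (u[:, 1] >= self.guard_nm)
                      & (u[:, 1] < self.guard_nm + self.area_side))
                if fm.sum() < 2:
                    continue
                env.append(ripley_h(u, env_radii, outer ** 2,
                                    focal_mask=fm).h.max())
            significant = bool(env) and curve.h.max() > max(env)
        return curve, significant

    # -- API --------------------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of nm coordinates")
        rng = np.random.default_rng(self.random_state)
        rmax = self.radius_max if self.radius_max is not None else self.guard_nm
        radii = np.arange(self.radius_step, rmax + self.radius_step / 2,
                          self.radius_step)

        origins = (list(self.areas) if self.areas is not None
                   else select_analysis_areas(X, self.n_areas,
                                              self.area_side, self.guard_nm))
        curves, sizes = [], []
        for origin in origins:
            curve, significant = self._area_curve(X, origin, radii, rng)
            curves.append(curve)
            if curve is None or not significant:
                continue
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                size = preferential_cluster_size(curve)
            if any(issubclass(w.category, NoClusterSignalWarning)
                   for w in caught):
                continue
            sizes.append(size)

        self.ripley_curves_ = curves
        self.preferential_sizes_ = sizes
        self.area_origins_ = origins

        if not sizes:
            warnings.warn("no interior H maximum above the CSR envelope in "
                          "any analysis area; returning an empty cluster "
                          "set", NoClusterSignalWarning, stacklevel=2)
            self.eps_ = float("nan")
            labels = np.full(len(X), -1)
            cs = cluster_metrics(X, labels, self.eps_, self.min_samples,
                                 self.diameter)
        else:
            self.eps_ = derive_seed_radius(sizes) * (
                self.correction_factor / SEED_RADIUS_FACTOR)
            labels = dbscan(X, self.eps_, self.min_samples)
            cs = cluster_metrics(X, labels, self.eps_, self.min_samples,
                                 self.diameter)

        self.labels_ = labels
        self.cluster_set_ = cs
        self.cluster_table_ = cs.table
        self.n_clusters_ = cs.n_clusters
        self.noise_fraction_ = cs.noise_fraction
        self.antibodies_per_cell_ = (
            estimate_antibodies_per_cell(cs, self.locs_per_antibody))
        self.report_ = self._build_report(X, radii)
        return self

    def _build_report(self, X, radii):
        report = {
            "n_localizations": int(len(X)),
            "areas": [
                {"origin": list(map(float, o)),
                 "preferential_size_nm": (None if c is None else float(
                     c.radii[int(np.argmax(c.h))])),
                 "h": None if c is None else [float(v) for v in c.h],
                 "n_points": None if c is None else int(c.n_points)}
                for o, c in zip(self.area_origins_, self.ripley_curves_)],
            "radii_nm": [float(r) for r in radii],
            "preferential_sizes_nm": [float(s)
                                      for s in self.preferential_sizes_],
            "eps_nm": float(self.eps_),
            "min_samples": int(self.min_samples),
            "n_clusters": int(self.n_clusters_),
            "noise_fraction": float(self.noise_fraction_),
            "mean_diameter_nm": (
                float(self.cluster_table_["diameter_nm"].mean())
                if self.n_clusters_ else None),
            "mean_nn_distance_nm": (
                float(self.cluster_table_["nn_distance_nm"].mean())
                if self.n_clusters_ >= 2 else None),
            "locs_per_cell": int(self.cluster_set_.locs_per_cell),
            "antibodies_per_cell": int(self.antibodies_per_cell_),
        }
        if self.min_samples_sweep and np.isfinite(self.eps_):
            sweep = {}
            for m in self.min_samples_sweep:
                lb = dbscan(X, self.eps_, m)
                sweep[int(m)] = int(len(np.unique(lb[lb >= 0])))
            report["min_samples_sensitivity"] = sweep
        return report

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def run_cluster_pipeline(table: pd.DataFrame, areas=None, min_pts: int = 4,
                         radii=None, **kwargs):
    """Run the full Ripley -> seed radius -> DBSCAN -> metrics chain on a
    localization table; returns ``(ClusterSet, report dict)``."""
    est = RipleySeededDBSCAN(min_samples=min_pts, areas=areas, **kwargs)
    if radii is not None:
        radii = np.asarray(radii, dtype=float)
        est.set_params(radius_step=float(radii[0]),
                       radius_max=float(radii[-1]))
    X = table[["x_nm", "y_nm"]].to_numpy(float)
    est.fit(X)
    return est.cluster_set_, est.report_


__all__ = [
    "SEED_RADIUS_FACTOR", "NoClusterSignalWarning", "RipleyCurve",
    "ClusterSet", "ripley_h", "preferential_cluster_size",
    "derive_seed_radius", "dbscan", "cluster_metrics",
    "estimate_antibodies_per_cell", "select_analysis_areas",
    "RipleySeededDBSCAN", "run_cluster_pipeline",
]
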