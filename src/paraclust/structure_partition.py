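"""Plane-of-best-fit partition of a Cα structure and per-side chi-square tests.

A plane is fitted through the Cα atoms of the reference structure and used
to split the molecule into two sides ("left"/"right"). A second plane,
perpendicular to the first and oriented along the direction of maximal Cα
variance within it, splits the molecule into "top"/"bottom". For each
paralog, the observed number of selected sites on each side is compared to
the expectation proportional to side size (residues on a side / total
residues x number of selected sites) with a 1-df chi-square goodness-of-fit
test.

The default plane fit is ordinary least squares of z on (x, y). OLS is not
coordinate-free — it depends on which axis plays the response — so a total
least-squares (PCA) plane is available via ``method="pca"``, and is also
the recommended fallback when the best plane is nearly vertical (singular
normal equations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_mapping import StructureModel

__all__ = [
    "PartitionPlane",
    "PartitionCounts",
    "fit_best_plane",
    "perpendicular_plane",
    "assign_sides",
    "partition_counts",
    "side_chi_square",
]

#: Relative eigenvalue gap below which the in-plane principal direction is
#: considered non-unique (isotropic spread).
_EIGEN_GAP_RTOL = 1e-8

#: Condition-number limit for the OLS normal equations; beyond it the best
#: plane is nearly vertical and z-on-(x,y) regression is unstable.
_COND_LIMIT = 1e10


@dataclass(frozen=True)
class PartitionPlane:
    """A partitioning plane ``n . x = offset`` with |n| = 1."""

    unit_normal: tuple[float, float, float]
    offset: float
    label_pair: tuple[str, str] = ("left", "right")

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.unit_normal) - 1.0) > 1e-9:
            raise ValueError("unit_normal must have unit length")

    @property
    def normal(self) -> np.ndarray:
        return np.asarray(self.unit_normal, dtype=float)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distances ``n . x - offset`` of (n, 3) points (Å)."""
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def to_dict(self) -> dict:
        return {
            "unit_normal": [float(v) for v in self.unit_normal],
            "offset": float(self.offset),
            "label_pair": list(self.label_pair),
        }


@dataclass(frozen=True)
class PartitionCounts:
    """Per-side residue totals and selected-site counts for one paralog."""

    side_sizes: tuple[int, int]
    observed: tuple[int, int]
    expected: tuple[float, float]
    label_pair: tuple[str, str] = ("left", "right")

    def __post_init__(self) -> None:
        if abs(sum(self.expected) - sum(self.observed)) > 1e-9:
            raise ValueError("expected counts must sum to the number of sites")

    def to_dict(self) -> dict:
        return {
            "label_pair": list(self.label_pair),
            "side_sizes": list(self.side_sizes),
            "observed": list(self.observed),
            "expected": [float(e) for e in self.expected],
        }


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip a direction vector so its largest-magnitude component is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def fit_best_plane(structure: StructureModel | np.ndarray,
                   method: str = "ols") -> PartitionPlane:
    """Fit the plane of best fit through the Cα coordinates.

    Parameters
    ----------
    structure : StructureModel or (n, 3) array
    method : {"ols", "pca"}
        ``"ols"`` regresses the z coordinate on (x, y) (ordinary least
        squares); ``"pca"`` fits the total-least-squares plane whose normal
        is the smallest-variance principal direction. The two coincide only
        when residual variance is purely along z.

    Raises
    ------
    ValueError
        For fewer than 3 points, (near-)collinear points, or — with OLS — a
        nearly vertical best plane (ill-conditioned normal equations), where
        the error suggests ``method="pca"``.
    """
    pts = structure.coords() if isinstance(structure, StructureModel) \
        else np.asarray(structure, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise ValueError("points are collinear or coincident; no unique plane")

    if method == "pca":
        cov = centered.T @ centered
        eigval, eigvec = np.linalg.eigh(cov)  # ascending
        normal = _canonical_sign(eigvec[:, 0])
        offset = float(normal @ pts.mean(axis=0))
        return PartitionPlane(tuple(normal), offset)
    if method != "ols":
        raise ValueError("method must be 'ols' or 'pca'")

    design = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    gram = design.T @ design
    if np.linalg.cond(gram) > _COND_LIMIT:
        raise ValueError(
            "normal equations nearly singular (best plane close to vertical); "
            "use method='pca'"
        )
    b1, b2, b0 = np.linalg.solve(gram, design.T @ pts[:, 2])
    raw = np.array([b1, b2, -1.0])  # plane: b1 x + b2 y - z + b0 = 0
    norm = np.linalg.norm(raw)
    normal = _canonical_sign(raw / norm)
    # keep offset consistent with the chosen sign
    sign = 1.0 if np.allclose(normal * norm, raw) else -1.0
    offset = sign * (-b0) / norm
    return PartitionPlane(tuple(normal), float(offset))


def perpendicular_plane(plane: PartitionPlane,
                        structure: StructureModel | np.ndarray) -> PartitionPlane:
    """Plane through the Cα centroid perpendicular to a fitted plane.

    Infinitely many planes are perpendicular to the fitted one; the normal
    is chosen as the direction of maximal Cα variance *within* the fitted
    plane — the only coordinate-free choice — giving the "top"/"bottom"
    split.

    Raises
    ------
    ValueError
        If the in-plane spread is isotropic (no unique maximal direction).
    """
    pts = structure.coords() if isinstance(structure, StructureModel) \
        else np.asarray(structure, dtype=float)
    centroid = pts.mean(axis=0)
    n = plane.normal
    centered = pts - centroid
    inplane = centered - np.outer(centered @ n, n)
    cov = inplane.T @ inplane
    eigval, eigvec = np.linalg.eigh(cov)
    lam1, lam2 = eigval[-1], eigval[-2]  # top two in-plane variances
    if lam1 <= 0 or (lam1 - lam2) / lam1 < _EIGEN_GAP_RTOL:
        raise ValueError(
            "in-plane Cα variance is isotropic; perpendicular-plane "
            "orientation is not unique"
        )
    axis = eigvec[:, -1]
    axis = axis - (axis @ n) * n  # enforce exact orthogonality
    axis = _canonical_sign(axis / np.linalg.norm(axis))
    return PartitionPlane(
        tuple(axis), float(axis @ centroid), label_pair=("top", "bottom")
    )


def assign_sides(structure: StructureModel, plane: PartitionPlane) -> dict[int, str]:
    """Side label per residue index.

    Signed distance >= 0 maps to the second label of the pair
    ("right"/"bottom"), < 0 to the first; residues exactly on the plane go
    to the non-negative side (a measure-zero tie in real coordinates).
    """
    d = plane.signed_distance(structure.coords())
    first, second = plane.label_pair
    return {
        r.residue_index: (second if di >= 0 else first)
        for r, di in zip(structure.residues, d)
    }


def partition_counts(
    structure: StructureModel,
    plane: PartitionPlane,
    site_residues: set[int] | frozenset[int] | list[int],
) -> PartitionCounts:
    """Observed and expected per-side counts for one paralog's sites.

    The expectation is proportional to side size: residues on a side
    divided by total residues, multiplied by the number of selected sites.
    """
    sides = assign_sides(structure, plane)
    first, second = plane.label_pair
    size_first = sum(1 for lab in sides.values() if lab == first)
    size_second = len(sides) - size_first
    site_residues = set(site_residues)
    missing = site_residues - set(sides)
    if missing:
        raise ValueError(f"site residues {sorted(missing)} not in structure")
    obs_first = sum(1 for ri in site_residues if sides[ri] == first)
    obs_second = len(site_residues) - obs_first
    n_sites = len(site_residues)
    total = len(sides)
    return PartitionCounts(
        side_sizes=(size_first, size_second),
        observed=(obs_first, obs_second),
        expected=(n_sites * size_first / total, n_sites * size_second / total),
        label_pair=plane.label_pair,
    )


def side_chi_square(counts: PartitionCounts) -> tuple[float, float]:
    """1-df chi-square goodness of fit of observed vs expected side counts.

    Returns ``(chi2, p)`` with the upper-tail p-value. Expected counts of 0
    raise; expected counts below 5 warn that the chi-square approximation
    is questionable.
    """
    obs = np.asarray(counts.observed, dtype=float)
    exp = np.asarray(counts.expected, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("expected count of zero on one side; test undefined")
    if np.any(exp < 5):
        warnings.warn(
            "expected side count below 5; chi-square approximation may be poor",
            stacklevel=2,
        )
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2, float(stats.chi2.sf(chi2, df=1))
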