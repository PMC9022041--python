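"""Nearest-selected-site paralog-affiliation test in 3D.

Each selected site, placed on the reference structure, asks: is my nearest
selected site (Euclidean distance between Cα atoms) under selection in the
same paralog or the other one? If selection targets distinct surfaces in
the two paralogs, "same" answers dominate. The observed 2x2 layout
(paralog x same/other) is compared with a random-labeling expectation by a
chi-square statistic; with four cells and both paralog totals fixed the
test is taken to have three degrees of freedom.

Shared-site rules: a column selected in both paralogs contributes one
instance per paralog at the same coordinate (it is selected independently
in each), its co-located twin is not an eligible neighbor (otherwise every
shared site trivially self-matches at distance zero), and when some
instance's nearest neighbor is a shared site the neighbor counts as "same"
regardless of paralog.

Because nearest-neighbor relations are not independent across sites, the
chi-square reference distribution is approximate; a permutation null
(uniform relabeling of site labels over the fixed positions) is available
as the statistically defensible alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .io_mapping import SiteSet, StructureModel

__all__ = [
    "SiteInstance",
    "AffiliationTable",
    "NeighborTestResult",
    "build_instances",
    "nearest_affiliations",
    "expected_affiliations",
    "affiliation_chi_square",
    "neighbor_test",
]

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class SiteInstance:
    """One paralog's claim on a selected residue."""

    paralog: str  # "A" | "B"
    residue_index: int
    coordinate: tuple[float, float, float]
    shared: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.coordinate, dtype=float)


@dataclass(frozen=True)
class AffiliationTable:
    """Observed and expected counts for (A→same, A→other, B→same, B→other)."""

    observed: tuple[int, int, int, int]
    expected: tuple[float, float, float, float]
    df: int = 3

    def __post_init__(self) -> None:
        oa, ob = self.observed[0] + self.observed[1], self.observed[2] + self.observed[3]
        ea, eb = self.expected[0] + self.expected[1], self.expected[2] + self.expected[3]
        if abs(oa - ea) > 1e-9 or abs(ob - eb) > 1e-9:
            raise ValueError("per-paralog observed and expected totals differ")

    def to_dict(self) -> dict:
        keys = ["a_same", "a_other", "b_same", "b_other"]
        return {
            "observed": dict(zip(keys, self.observed)),
            "expected": {k: float(v) for k, v in zip(keys, self.expected)},
            "df": self.df,
        }


@dataclass(frozen=True)
class NeighborTestResult:
    table: AffiliationTable
    chi2: float
    p_value: float
    method: str  # "chi2" | "permutation"
    n_permutations: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "table": self.table.to_dict(),
            "chi2": self.chi2,
            "p_value": self.p_value,
            "method": self.method,
        }
        if self.method == "permutation":
            d["n_permutations"] = self.n_permutations
            d["seed"] = self.seed
        return d


def build_instances(
    sites_a: SiteSet,
    sites_b: SiteSet,
    mapping: dict[int, int],
    structure: StructureModel,
) -> list[SiteInstance]:
    """Place selected columns on the structure as per-paralog instances.

    A column selected in both paralogs yields two instances (one A, one B)
    at the same coordinate, both flagged ``shared``. Columns absent from
    ``mapping`` (gap columns, or columns outside the structure) are dropped
    with a logged count.

    Raises
    ------
    ValueError
        If no column of either paralog maps onto the structure.
    """
    coords_by_index = {r.residue_index: (r.x, r.y, r.z) for r in structure.residues}
    shared_cols = sites_a.columns & sites_b.columns
    instances: list[SiteInstance] = []
    dropped = 0
    for paralog, sites in (("A", sites_a), ("B", sites_b)):
        for col in sites.sorted_columns():
            ri = mapping.get(col)
            if ri is None or ri not in coords_by_index:
                dropped += 1
                continue
            instances.append(
                SiteInstance(
                    paralog=paralog,
                    residue_index=ri,
                    coordinate=coords_by_index[ri],
                    shared=col in shared_cols,
                )
            )
    if dropped:
        logger.warning("dropped %d selected columns with no structure residue", dropped)
    if not instances:
        raise ValueError("no selected column maps onto the structure")
    return instances


def _is_twin(a: SiteInstance, b: SiteInstance) -> bool:
    """Co-located twin of a shared site: same residue, opposite paralog."""
    return (
        a.shared and b.shared
        and a.residue_index == b.residue_index
        and a.paralog != b.paralog
    )


def nearest_affiliations(
    instances: list[SiteInstance],
) -> tuple[int, int, int, int]:
    """Tally nearest-neighbor affiliations (A→same, A→other, B→same, B→other).

    For each instance the Euclidean nearest other instance is found,
    excluding the instance itself and its co-located shared twin. Distance
    ties break deterministically: lower residue index first, then paralog A
    before B. The neighbor counts as "same" when it belongs to the same
    paralog or is a shared site.

    Raises
    ------
    ValueError
        If instances do not span both paralogs or fewer than two distinct
        coordinates exist.
    """
    paralogs = {inst.paralog for inst in instances}
    if paralogs != {"A", "B"}:
        raise ValueError("need selected sites from both paralogs")
    coords = np.array([inst.coord for inst in instances])
    if len({tuple(c) for c in coords.round(9).tolist()}) < 2:
        raise ValueError("fewer than two distinct coordinates")
    dists = cdist(coords, coords)

    counts = {("A", True): 0, ("A", False): 0, ("B", True): 0, ("B", False): 0}
    for i, inst in enumerate(instances):
        best = None
        best_key = None
        for j, other in enumerate(instances):
            if j == i or _is_twin(inst, other):
                continue
            key = (dists[i, j], other.residue_index, 0 if other.paralog == "A" else 1)
            if best_key is None or key < best_key:
                best_key, best = key, other
        if best is None:
            raise ValueError("instance has no eligible neighbor")
        same = best.paralog == inst.paralog or best.shared
        counts[(inst.paralog, same)] += 1
    return (
        counts[("A", True)], counts[("A", False)],
        counts[("B", True)], counts[("B", False)],
    )


def expected_affiliations(n_a: int, n_b: int) -> tuple[float, float, float, float]:
    """Random-labeling expectation of the four affiliation counts.

    If paralog labels were assigned at random over the site positions, the
    nearest neighbor of an A instance would be one of the other
    ``n_a + n_b - 1`` instances uniformly, so
    P(same | A) = (n_a - 1) / (n_a + n_b - 1), and symmetrically for B.
    Per-paralog totals are preserved by construction.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("both paralogs must have at least one site")
    if n_a + n_b < 3:
        raise ValueError("need at least 3 site instances in total")
    n = n_a + n_b
    return (
        n_a * (n_a - 1) / (n - 1),
        n_a * n_b / (n - 1),
        n_b * (n_b - 1) / (n - 1),
        n_b * n_a / (n - 1),
    )


def affiliation_chi_square(table: AffiliationTable) -> tuple[float, float]:
    """Chi-square over the four cells with 3 degrees of freedom.

    Returns ``(chi2, p)``; raises on any zero expected cell.
    """
    obs = np.asarray(table.observed, dtype=float)
    exp = np.asarray(table.expected, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("zero expected cell; test undefined")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2, float(stats.chi2.sf(chi2, df=table.df))


def _site_labels(instances: list[SiteInstance]) -> tuple[list[int], list[str]]:
    """Collapse instances to unique residues with labels 'A', 'B' or 'AB'."""
    lab: dict[int, str] = {}
    for inst in instances:
        cur = lab.get(inst.residue_index)
        if cur is None:
            lab[inst.residue_index] = "AB" if inst.shared else inst.paralog
        elif cur != "AB":
            lab[inst.residue_index] = "AB"
    residues = sorted(lab)
    return residues, [lab[r] for r in residues]


def _instances_from_labels(
    residues: list[int],
    labels: list[str],
    coords: dict[int, tuple[float, float, float]],
) -> list[SiteInstance]:
    out = []
    for ri, lab in zip(residues, labels):
        if lab in ("A", "AB"):
            out.append(SiteInstance("A", ri, coords[ri], shared=lab == "AB"))
        if lab in ("B", "AB"):
            out.append(SiteInstance("B", ri, coords[ri], shared=lab == "AB"))
    return out


def neighbor_test(
    instances: list[SiteInstance],
    null: str = "chi2",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
) -> NeighborTestResult:
    """Full affiliation test on a set of site instances.

    ``null="chi2"`` compares the chi-square statistic against the 3-df
    chi-square distribution. ``null="permutation"`` shuffles the site
    labels (A / B / shared) uniformly over the occupied residue positions
    and reports the fraction of shuffles with chi2 >= observed.
    """
    observed = nearest_affiliations(instances)
    n_a = observed[0] + observed[1]
    n_b = observed[2] + observed[3]
    table = AffiliationTable(observed=observed,
                             expected=expected_affiliations(n_a, n_b))
    chi2, p_chi2 = affiliation_chi_square(table)
    if null == "chi2":
        return NeighborTestResult(table=table, chi2=chi2, p_value=p_chi2,
                                  method="chi2")
    if null != "permutation":
        raise ValueError("null must be 'chi2' or 'permutation'")

    residues, labels = _site_labels(instances)
    coords = {inst.residue_index: inst.coordinate for inst in instances}
    rng = np.random.default_rng(seed)
    labels_arr = np.array(labels)
    at_least = 0
    for _ in range(n_permutations):
        perm = labels_arr[rng.permutation(len(labels_arr))]
        perm_inst = _instances_from_labels(residues, perm.tolist(), coords)
        perm_obs = nearest_affiliations(perm_inst)
        pa = perm_obs[0] + perm_obs[1]
        pb = perm_obs[2] + perm_obs[3]
        perm_table = AffiliationTable(
            observed=perm_obs, expected=expected_affiliations(pa, pb)
        )
        perm_chi2, _ = affiliation_chi_square(perm_table)
        if perm_chi2 >= chi2:
            at_least += 1
    return NeighborTestResult(
        table=table, chi2=chi2, p_value=at_least / n_permutations,
        method="permutation", n_permutations=n_permutations, seed=seed,
    )
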