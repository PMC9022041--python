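"""Synthetic structures, alignments and selected-site sets.

Everything the three clustering tests consume can be generated here, so
the whole pipeline is testable without downloading structures or running a
codon-model fit. The generator emulates the shape of the real inputs: a
single protein chain of Cα coordinates with realistic consecutive-residue
spacing (3.8 Å), a gapless pairwise alignment of two paralogs over the
chain, and two selected-site sets drawn either independently and uniformly
per column (the exact null of the bootstrap runs test) or spatially
clustered around distinct structural foci (the subfunctionalization-like
alternative, with selection probability decaying exponentially in Cα
distance from each paralog's focus).

Defaults mirror the study conditions of the motivating analysis: a
142-column paralog alignment with 62 selected sites expected in paralog A
and 30 in paralog B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io_mapping import PairAlignment, ResidueCoordinate, SiteSet, StructureModel

__all__ = [
    "SpatialClustering",
    "SyntheticSpec",
    "generate_structure",
    "generate_sites",
    "generate_bundle",
]

AMINO_ACIDS_1 = "ACDEFGHIKLMNPQRSTVWY"
_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: Ideal α-helix geometry: rise per residue (Å) and twist per residue (deg).
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0

#: Default per-column selection probabilities: 62 and 30 selected sites on a
#: 142-column paralog alignment.
DEFAULT_P_A = 62 / 142
DEFAULT_P_B = 30 / 142


@dataclass(frozen=True)
class SpatialClustering:
    """Selection clustered around per-paralog structural foci.

    Per-residue selection probability is proportional to
    ``exp(-d(residue, focus) / decay_length)`` and normalized so the
    expected number of selected sites stays at ``n * p``. Small decay
    lengths concentrate selection tightly around each focus.
    """

    focus_a: int  # residue index of paralog A's focus
    focus_b: int
    decay_length: float  # Å

    def __post_init__(self) -> None:
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic input bundle."""

    n_residues: int = 142
    chain_model: str = "random_walk"  # "random_walk" | "helix"
    bond_length: float = 3.8  # Å between consecutive Cα atoms
    p_a: float = DEFAULT_P_A
    p_b: float = DEFAULT_P_B
    clustering: SpatialClustering | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        if self.chain_model not in ("random_walk", "helix"):
            raise ValueError("chain_model must be 'random_walk' or 'helix'")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if not (0.0 <= self.p_a <= 1.0 and 0.0 <= self.p_b <= 1.0):
            raise ValueError("selection probabilities must lie in [0, 1]")

    def with_seed(self, seed: int | None) -> "SyntheticSpec":
        return replace(self, seed=seed)


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    if spec.seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[stream])


def generate_structure(spec: SyntheticSpec) -> StructureModel:
    """Generate a Cα chain with exact consecutive-residue spacing.

    ``random_walk`` draws uniformly random step directions of length
    ``bond_length`` (an unconstrained freely-jointed chain; no excluded
    volume). ``helix`` builds an ideal α-helix with the canonical rise
    (1.5 Å) and twist (100°) per residue, the radius set so consecutive Cα
    atoms are exactly ``bond_length`` apart.
    """
    rng = _rng(spec, 0)
    n = spec.n_residues
    if spec.chain_model == "random_walk":
        steps = rng.normal(size=(n - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), np.cumsum(steps * spec.bond_length, axis=0)])
    else:
        twist = math.radians(HELIX_TWIST_DEG)
        chord = math.sqrt(spec.bond_length ** 2 - HELIX_RISE ** 2)
        radius = chord / (2.0 * math.sin(twist / 2.0))
        t = np.arange(n)
        coords = np.column_stack([
            radius * np.cos(twist * t),
            radius * np.sin(twist * t),
            HELIX_RISE * t,
        ])
    seq = rng.choice(list(AMINO_ACIDS_1), size=n)
    residues = tuple(
        ResidueCoordinate(i + 1, _1TO3[seq[i]], *coords[i]) for i in range(n)
    )
    return StructureModel(chain_id="S", residues=residues)


def _selection_probs(
    spec: SyntheticSpec, structure: StructureModel, p: float, focus: int | None
) -> np.ndarray:
    """Per-residue selection probabilities with expected count n*p."""
    n = spec.n_residues
    if spec.clustering is None or focus is None:
        return np.full(n, p)
    d = np.linalg.norm(
        structure.coords() - structure.coords()[focus - 1], axis=1
    )
    w = np.exp(-d / spec.clustering.decay_length)
    target = n * p
    # water-filling: scale weights to the target expected count, capping
    # probabilities at 1 and redistributing the excess outward
    probs = np.zeros(n)
    free = np.ones(n, dtype=bool)
    remaining = target
    for _ in range(n):
        wsum = w[free].sum()
        if wsum <= 0 or remaining <= 0:
            break
        scale = remaining / wsum
        cand = w * scale
        over = free & (cand >= 1.0)
        if not over.any():
            probs[free] = cand[free]
            break
        probs[over] = 1.0
        remaining -= int(over.sum())
        free &= ~over
    return np.clip(probs, 0.0, 1.0)


def generate_sites(
    spec: SyntheticSpec, structure: StructureModel
) -> tuple[SiteSet, SiteSet, PairAlignment]:
    """Draw selected-site sets and a matching gapless paralog alignment.

    With ``clustering=None`` each column is selected independently with
    probability ``p_a`` for paralog A and ``p_b`` for B — exactly the null
    model of the bootstrap runs test. With clustering, per-residue
    probabilities decay exponentially with distance from each paralog's
    focus (normalized to keep the expected counts at ``n*p``; in the limit
    ``decay_length → ∞`` this reduces to the uniform null).

    The alignment has both rows equal to the structure sequence, with row B
    mutated at columns selected in exactly one paralog, so divergent sites
    coincide with the differentially selected ones. Posteriors are drawn
    uniformly in ``[0.75, 1]`` for selected columns.

    Raises
    ------
    ValueError
        If the expected number of selected sites for either paralog is
        below 1.
    """
    n = spec.n_residues
    if n * spec.p_a < 1 or n * spec.p_b < 1:
        raise ValueError("expected selected-site count below 1 for a paralog")
    rng = _rng(spec, 1)
    focus_a = spec.clustering.focus_a if spec.clustering else None
    focus_b = spec.clustering.focus_b if spec.clustering else None
    probs_a = _selection_probs(spec, structure, spec.p_a, focus_a)
    probs_b = _selection_probs(spec, structure, spec.p_b, focus_b)
    sel_a = rng.random(n) < probs_a
    sel_b = rng.random(n) < probs_b
    cols_a = frozenset(int(i) + 1 for i in np.flatnonzero(sel_a))
    cols_b = frozenset(int(i) + 1 for i in np.flatnonzero(sel_b))

    threshold = 0.75
    post_a = {c: float(threshold + (1 - threshold) * rng.random()) for c in sorted(cols_a)}
    post_b = {c: float(threshold + (1 - threshold) * rng.random()) for c in sorted(cols_b)}

    seq = structure.sequence
    row_b = list(seq)
    for col in sorted(cols_a ^ cols_b):
        current = row_b[col - 1]
        alternatives = [aa for aa in AMINO_ACIDS_1 if aa != current]
        row_b[col - 1] = str(rng.choice(alternatives))
    aln = PairAlignment(id_a="paralog_A", id_b="paralog_B",
                        row_a=seq, row_b="".join(row_b))
    sites_a = SiteSet("paralog_A", cols_a, post_a, threshold)
    sites_b = SiteSet("paralog_B", cols_b, post_b, threshold)
    return sites_a, sites_b, aln


def generate_bundle(
    spec: SyntheticSpec,
) -> tuple[StructureModel, PairAlignment, SiteSet, SiteSet]:
    """Structure + alignment + both site sets from one spec."""
    structure = generate_structure(spec)
    sites_a, sites_b, aln = generate_sites(spec, structure)
    return structure, aln, sites_a, sites_b
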