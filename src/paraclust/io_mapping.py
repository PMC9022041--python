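"""Structures, alignments and selected-site lists, plus the mapping between them.

The clustering tests in this package work on three kinds of input: the Cα
trace of a reference structure, a pairwise protein alignment of two
paralogs, and per-paralog lists of alignment columns inferred to be under
positive selection (e.g. codeml M8 BEB sites retained at a posterior
threshold). This module defines the container types and the plumbing that
connects alignment columns to structure residues.

Conventions
-----------
* Alignment columns are 1-based.
* Residue indices are 1-based and chain-sequential (the i-th residue with a
  Cα atom in the chain gets index i), not author PDB numbering; an ``offset``
  parameter on the column→residue mapping reconciles the two.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

__all__ = [
    "ResidueCoordinate",
    "StructureModel",
    "PairAlignment",
    "SiteSet",
    "read_calpha",
    "write_calpha",
    "read_alignment",
    "read_sites",
    "map_columns_to_residues",
    "percent_identity",
    "divergent_sites",
]

GAP = "-"

#: Default Bayes Empirical Bayes posterior threshold for retaining a site.
DEFAULT_POSTERIOR_THRESHOLD = 0.75

#: Default minimum identity between the ungapped reference alignment row and
#: the structure sequence for column→residue mapping to be accepted.
DEFAULT_MAPPING_IDENTITY = 0.95


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueCoordinate:
    """One residue represented by its Cα atom.

    Parameters
    ----------
    residue_index : int
        1-based chain-sequential index.
    residue_name : str
        Three-letter amino-acid code (e.g. ``"ALA"``).
    x, y, z : float
        Cα coordinates in Å.
    """

    residue_index: int
    residue_name: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(
                f"non-finite coordinates for residue {self.residue_index}"
            )

    @property
    def coord(self) -> np.ndarray:
        """Coordinates as a length-3 array (Å)."""
        return np.array([self.x, self.y, self.z], dtype=float)

    def to_dict(self) -> dict:
        return {
            "residue_index": self.residue_index,
            "residue_name": self.residue_name,
            "x": self.x,
            "y": self.y,
            "z": self.z,
        }


@dataclass(frozen=True)
class StructureModel:
    """An ordered Cα trace of one chain."""

    chain_id: str
    residues: tuple[ResidueCoordinate, ...]

    def __post_init__(self) -> None:
        idx = [r.residue_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """One-letter sequence derived from the residue names ('X' if unknown)."""
        return "".join(
            seq1(r.residue_name, undef_code="X") for r in self.residues
        )

    def coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in residue order."""
        return np.array([[r.x, r.y, r.z] for r in self.residues], dtype=float)

    def residue_by_index(self, residue_index: int) -> ResidueCoordinate:
        for r in self.residues:
            if r.residue_index == residue_index:
                return r
        raise KeyError(f"no residue with index {residue_index}")

    def to_dict(self) -> dict:
        return {
            "chain_id": self.chain_id,
            "residues": [r.to_dict() for r in self.residues],
        }


@dataclass(frozen=True)
class PairAlignment:
    """Two gapped paralog rows over shared columns (gap = ``'-'``)."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")
        for i, (ca, cb) in enumerate(zip(self.row_a, self.row_b), start=1):
            if ca == GAP and cb == GAP:
                raise ValueError(f"column {i} is gapped in both rows")

    @property
    def length(self) -> int:
        return len(self.row_a)

    def column(self, col: int) -> tuple[str, str]:
        """Characters of 1-based column ``col``."""
        return self.row_a[col - 1], self.row_b[col - 1]

    def to_dict(self) -> dict:
        return {
            "id_a": self.id_a,
            "id_b": self.id_b,
            "row_a": self.row_a,
            "row_b": self.row_b,
            "length": self.length,
        }


@dataclass(frozen=True)
class SiteSet:
    """Selected alignment columns for one paralog, with posteriors.

    ``columns`` holds the retained 1-based columns; each retained column has
    ``posteriors[column] >= threshold``.
    """

    paralog_id: str
    columns: frozenset[int]
    posteriors: dict[int, float] = field(default_factory=dict)
    threshold: float = DEFAULT_POSTERIOR_THRESHOLD

    def __post_init__(self) -> None:
        for c in self.columns:
            p = self.posteriors.get(c)
            if p is None:
                continue
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"posterior {p} for column {c} outside [0, 1]")
            if p < self.threshold:
                raise ValueError(
                    f"column {c} retained with posterior {p} < threshold "
                    f"{self.threshold}"
                )

    def __len__(self) -> int:
        return len(self.columns)

    def __contains__(self, col: int) -> bool:
        return col in self.columns

    def sorted_columns(self) -> list[int]:
        return sorted(self.columns)

    def to_dict(self) -> dict:
        return {
            "paralog_id": self.paralog_id,
            "columns": self.sorted_columns(),
            "posteriors": {str(c): self.posteriors[c]
                           for c in self.sorted_columns() if c in self.posteriors},
            "threshold": self.threshold,
        }


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_calpha(pdb_text: str, chain_id: str, model_number: int = 1) -> StructureModel:
    """Extract the Cα trace of one chain from PDB text.

    Parameters
    ----------
    pdb_text : str
        Content of a PDB file (ATOM/MODEL records, fixed width).
    chain_id : str
        Chain identifier to read.
    model_number : int, optional
        1-based ordinal of the MODEL block to read; for multi-model (NMR)
        files only this model is used. Default is the first model, which for
        deposited NMR ensembles is conventionally the representative /
        lowest-energy one.

    Returns
    -------
    StructureModel
        One residue per Cα atom, in file order, indexed 1..n chain-sequentially.

    Raises
    ------
    ValueError
        If the requested model or chain is absent, or the chain has no Cα
        atoms. Duplicate Cα atoms (altlocs) keep the first-listed location
        and emit a :class:`UserWarning`.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", io.StringIO(pdb_text))
    models = list(structure.get_models())
    if not models:
        raise ValueError("no ATOM records found in PDB text")
    if not 1 <= model_number <= len(models):
        raise ValueError(
            f"model_number {model_number} out of range (file has {len(models)})"
        )
    model = models[model_number - 1]
    chain = None
    for ch in model.get_chains():
        if ch.id == chain_id:
            chain = ch
            break
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not found in model {model_number}")

    residues: list[ResidueCoordinate] = []
    for res in chain.get_residues():
        hetfield = res.id[0]
        if hetfield != " ":  # skip waters / hetero groups
            continue
        if "CA" not in res:
            continue
        atom = res["CA"]
        if atom.is_disordered():
            alts = sorted(atom.disordered_get_id_list())
            warnings.warn(
                f"residue {res.id[1]} has alternate Cα locations {alts}; "
                f"keeping first ({alts[0]})",
                stacklevel=2,
            )
            atom = atom.disordered_get(alts[0])
        x, y, z = (float(v) for v in atom.coord)
        residues.append(
            ResidueCoordinate(len(residues) + 1, res.resname.strip(), x, y, z)
        )
    if not residues:
        raise ValueError(f"no Cα atoms for chain {chain_id!r}")
    return StructureModel(chain_id=chain_id, residues=tuple(residues))


def write_calpha(model: StructureModel) -> str:
    """Serialize a Cα trace as minimal fixed-width PDB ATOM records."""
    lines = []
    for i, r in enumerate(model.residues, start=1):
        lines.append(
            f"ATOM  {i:>5d}  CA  {r.residue_name:>3s} {model.chain_id:1s}"
            f"{r.residue_index:>4d}    "
            f"{r.x:8.3f}{r.y:8.3f}{r.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {'C':>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_alignment(
    text: str,
    fmt: str = "fasta",
    id_a: str | None = None,
    id_b: str | None = None,
) -> PairAlignment:
    """Read a pairwise alignment (FASTA or Clustal).

    If the file holds more than two rows, ``id_a``/``id_b`` select the two
    paralogs; otherwise the first two rows are used in file order.
    """
    aln = AlignIO.read(io.StringIO(text), fmt)
    records = {rec.id: rec for rec in aln}
    if id_a is None and id_b is None:
        if len(aln) < 2:
            raise ValueError("alignment must contain at least two sequences")
        rec_a, rec_b = aln[0], aln[1]
    else:
        if id_a is None or id_b is None:
            raise ValueError("provide both id_a and id_b, or neither")
        try:
            rec_a, rec_b = records[id_a], records[id_b]
        except KeyError as e:
            raise ValueError(f"sequence id {e.args[0]!r} not in alignment") from e
    return PairAlignment(
        id_a=rec_a.id, id_b=rec_b.id,
        row_a=str(rec_a.seq).upper(), row_b=str(rec_b.seq).upper(),
    )


def read_sites(
    tsv_text: str,
    paralog_id: str = "",
    threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
) -> SiteSet:
    """Parse a TSV site list and apply the posterior threshold.

    The expected format is one header line ``column<TAB>posterior`` followed
    by one row per candidate site. Columns with posterior >= ``threshold``
    (inclusive, matching a BEB cut-off of Pr(ω>1) >= 0.75) are retained.

    Raises
    ------
    ValueError
        On non-integer columns, posteriors outside [0, 1], or duplicate
        columns.
    """
    columns: set[int] = set()
    posteriors: dict[int, float] = {}
    lines = [ln for ln in tsv_text.splitlines() if ln.strip()]
    if lines and lines[0].lower().split("\t")[:2] == ["column", "posterior"]:
        lines = lines[1:]
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed site row: {ln!r}")
        col_str, post_str = parts[0].strip(), parts[1].strip()
        try:
            col_f = float(col_str)
        except ValueError as e:
            raise ValueError(f"non-numeric column {col_str!r}") from e
        if col_f != int(col_f):
            raise ValueError(f"non-integer column {col_str!r}")
        col = int(col_f)
        if col < 1:
            raise ValueError(f"column {col} must be >= 1")
        post = float(post_str)
        if not 0.0 <= post <= 1.0:
            raise ValueError(f"posterior {post} for column {col} outside [0, 1]")
        if col in posteriors:
            raise ValueError(f"duplicate column {col}")
        posteriors[col] = post
        if post >= threshold:
            columns.add(col)
    retained = {c: posteriors[c] for c in columns}
    return SiteSet(
        paralog_id=paralog_id,
        columns=frozenset(columns),
        posteriors=retained,
        threshold=threshold,
    )


def write_sites(sites: SiteSet) -> str:
    """Serialize a SiteSet back to the canonical TSV format."""
    lines = ["column\tposterior"]
    for c in sites.sorted_columns():
        lines.append(f"{c}\t{sites.posteriors.get(c, sites.threshold):g}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Column → residue mapping and divergence summaries
# ---------------------------------------------------------------------------

def map_columns_to_residues(
    aln: PairAlignment,
    reference_row: str,
    structure: StructureModel,
    offset: int = 0,
    min_identity: float = DEFAULT_MAPPING_IDENTITY,
) -> dict[int, int]:
    """Map alignment columns onto structure residue indices.

    The reference paralog row (``"a"`` or ``"b"``) is ungapped and matched
    against ``structure.sequence`` starting at ``offset`` (0-based shift into
    the structure sequence). The i-th non-gap reference column maps to the
    (offset+i)-th structure residue. The mapping is strictly monotone and
    injective; gap columns are unmapped.

    Raises
    ------
    ValueError
        If the ungapped row overruns the structure, or the sequence identity
        over mapped positions is below ``min_identity`` (the error names the
        first mismatching position).
    """
    if reference_row not in ("a", "b"):
        raise ValueError("reference_row must be 'a' or 'b'")
    row = aln.row_a if reference_row == "a" else aln.row_b
    cols = [i for i, ch in enumerate(row, start=1) if ch != GAP]
    ungapped = "".join(row[i - 1] for i in cols)
    seq = structure.sequence
    if offset < 0 or offset + len(ungapped) > len(seq):
        raise ValueError(
            f"reference row of length {len(ungapped)} with offset {offset} "
            f"does not fit structure of length {len(seq)}"
        )
    matches = 0
    first_mismatch = None
    for i, ch in enumerate(ungapped):
        if ch == seq[offset + i]:
            matches += 1
        elif first_mismatch is None:
            first_mismatch = (cols[i], ch, seq[offset + i])
    identity = matches / len(ungapped) if ungapped else 0.0
    if identity < min_identity:
        col, got, want = first_mismatch
        raise ValueError(
            f"reference/structure identity {identity:.1%} below "
            f"{min_identity:.0%}; first mismatch at alignment column {col} "
            f"({got!r} vs structure {want!r})"
        )
    return {
        col: structure.residues[offset + i].residue_index
        for i, col in enumerate(cols)
    }


def percent_identity(aln: PairAlignment, mode: str = "all") -> float:
    """Percent sequence identity between the two alignment rows.

    ``mode`` selects the denominator: ``"all"`` counts every alignment
    column (gap-containing columns score as mismatches), ``"ungapped"``
    counts only columns where neither row is gapped. Both conventions are
    exposed because published pairwise-identity figures rarely state which
    one was used.
    """
    if aln.length == 0:
        raise ValueError("empty alignment")
    if mode not in ("all", "ungapped"):
        raise ValueError("mode must be 'all' or 'ungapped'")
    ident = 0
    ungapped = 0
    for ca, cb in zip(aln.row_a, aln.row_b):
        if ca != GAP and cb != GAP:
            ungapped += 1
            if ca == cb:
                ident += 1
    denom = aln.length if mode == "all" else ungapped
    if denom == 0:
        raise ValueError("no ungapped columns in alignment")
    return 100.0 * ident / denom


def divergent_sites(aln: PairAlignment) -> frozenset[int]:
    """Columns where the paralogs differ (including one-sided gaps).

    Composable with :func:`map_columns_to_residues` to annotate a structure
    with divergent positions, or intersected with a :class:`SiteSet` to
    count how many selected sites are also divergent.
    """
    return frozenset(
        i for i, (ca, cb) in enumerate(zip(aln.row_a, aln.row_b), start=1)
        if ca != cb
    )


def to_json(obj) -> str:
    """JSON serialization for any of the domain types (via ``to_dict``)."""
    return json.dumps(obj.to_dict(), indent=2, sort_keys=True)
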