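"""Run all three clustering tests on one input bundle and aggregate a report.

The report mirrors a full analysis of one paralog pair: both runs-test
variants on the alignment, the plane-partition chi-square on the main
(left/right) and perpendicular (top/bottom) axes for each paralog, and the
nearest-neighbor affiliation test, together with per-residue annotations
(selected/divergent categories) suitable for coloring a structure in a
molecular viewer.

No multiple-testing correction is applied — the individual tests are
reported raw — but the report carries the number of tests run so a reader
can apply one.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io_mapping, neighbor_affiliation, runs, structure_partition
from .io_mapping import PairAlignment, SiteSet, StructureModel

__all__ = ["AnalysisConfig", "AnalysisReport", "analyze", "run_all"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """File-level inputs and options of one full analysis."""

    alignment_path: str
    sites_a_path: str
    sites_b_path: str
    pdb_path: str
    chain_id: str = "A"
    model_number: int = 1
    alignment_format: str = "fasta"
    reference_row: str = "a"
    offset: int = 0
    threshold: float = io_mapping.DEFAULT_POSTERIOR_THRESHOLD
    min_identity: float = io_mapping.DEFAULT_MAPPING_IDENTITY
    n_reps: int = runs.DEFAULT_N_REPS
    seed: int | None = None
    plane_method: str = "ols"
    neighbor_null: str = "chi2"
    n_permutations: int = neighbor_affiliation.DEFAULT_N_PERMUTATIONS


@dataclass(frozen=True)
class AnalysisReport:
    inputs: dict
    results: dict
    annotations: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "results": self.results,
            "annotations": self.annotations,
            "notes": self.notes,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def annotation_tsv(self) -> str:
        """Per-residue categories, one row per annotated residue."""
        lines = ["residue_index\tcategory"]
        for ri, cat in sorted(self.annotations.items()):
            lines.append(f"{ri}\t{cat}")
        return "\n".join(lines) + "\n"

    def p_values(self) -> dict[str, float]:
        out = {}
        for name, res in self.results.items():
            if isinstance(res, dict) and "p_value" in res:
                out[name] = res["p_value"]
        return out


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def analyze(
    structure: StructureModel,
    aln: PairAlignment,
    sites_a: SiteSet,
    sites_b: SiteSet,
    *,
    reference_row: str = "a",
    offset: int = 0,
    min_identity: float = io_mapping.DEFAULT_MAPPING_IDENTITY,
    n_reps: int = runs.DEFAULT_N_REPS,
    seed: int | None = None,
    plane_method: str = "ols",
    neighbor_null: str = "chi2",
    n_permutations: int = neighbor_affiliation.DEFAULT_N_PERMUTATIONS,
    inputs_digest: dict | None = None,
) -> AnalysisReport:
    """Run every test on in-memory inputs and aggregate one report.

    Deterministic given identical inputs and ``seed``: the runs test uses
    ``seed`` and the permutation neighbor null (if requested) ``seed + 1``.
    """
    results: dict = {}

    with _stage("runs_test"):
        rt3 = runs.runs_test(sites_a, sites_b, aln.length,
                                  n_reps=n_reps, seed=seed, exclude_both=False)
        results["runs_three_category"] = rt3.to_dict()
        try:
            rt2 = runs.runs_test(sites_a, sites_b, aln.length,
                                      n_reps=n_reps, seed=seed, exclude_both=True)
            results["runs_two_category"] = rt2.to_dict()
        except ValueError as e:
            # every selected column shared between paralogs
            results["runs_two_category"] = {"error": str(e)}

    with _stage("column_mapping"):
        mapping = io_mapping.map_columns_to_residues(
            aln, reference_row, structure, offset=offset, min_identity=min_identity
        )

    with _stage("plane_partition"):
        plane = structure_partition.fit_best_plane(structure, method=plane_method)
        perp = structure_partition.perpendicular_plane(plane, structure)
        for axis_name, pl in (("main", plane), ("perpendicular", perp)):
            for paralog, sites in (("a", sites_a), ("b", sites_b)):
                residues = {mapping[c] for c in sites.columns if c in mapping}
                counts = structure_partition.partition_counts(structure, pl, residues)
                chi2, p = structure_partition.side_chi_square(counts)
                results[f"plane_{axis_name}_{paralog}"] = {
                    "plane": pl.to_dict(),
                    "counts": counts.to_dict(),
                    "chi2": chi2,
                    "p_value": p,
                }

    with _stage("neighbor_affiliation"):
        instances = neighbor_affiliation.build_instances(
            sites_a, sites_b, mapping, structure
        )
        nres = neighbor_affiliation.neighbor_test(
            instances, null=neighbor_null, n_permutations=n_permutations,
            seed=None if seed is None else seed + 1,
        )
        results["neighbor_affiliation"] = nres.to_dict()

    with _stage("annotations"):
        annotations: dict[int, str] = {}
        shared = sites_a.columns & sites_b.columns
        for col, ri in mapping.items():
            if col in shared:
                annotations[ri] = "both"
            elif col in sites_a.columns:
                annotations[ri] = "a_only"
            elif col in sites_b.columns:
                annotations[ri] = "b_only"
        for col in io_mapping.divergent_sites(aln):
            ri = mapping.get(col)
            if ri is not None and ri not in annotations:
                annotations[ri] = "divergent"

    n_tests = sum(1 for r in results.values()
                  if isinstance(r, dict) and "p_value" in r)
    return AnalysisReport(
        inputs=inputs_digest or {
            "seed": seed, "n_reps": n_reps, "plane_method": plane_method,
            "neighbor_null": neighbor_null, "reference_row": reference_row,
            "offset": offset,
        },
        results=results,
        annotations=annotations,
        notes={
            "n_tests": n_tests,
            "multiple_testing_correction": "none (raw p-values reported)",
            "tie_rules": "plane ties to non-negative side; neighbor distance "
                         "ties to lower residue index, then paralog A",
        },
    )


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(config: AnalysisConfig) -> AnalysisReport:
    """Read every input named by the config and run :func:`analyze`."""
    with _stage("read_inputs"):
        aln = io_mapping.read_alignment(
            Path(config.alignment_path).read_text(), config.alignment_format
        )
        sites_a = io_mapping.read_sites(
            Path(config.sites_a_path).read_text(), "A", config.threshold
        )
        sites_b = io_mapping.read_sites(
            Path(config.sites_b_path).read_text(), "B", config.threshold
        )
        structure = io_mapping.read_calpha(
            Path(config.pdb_path).read_text(), config.chain_id, config.model_number
        )
    digest = {
        "alignment": _sha256(config.alignment_path),
        "sites_a": _sha256(config.sites_a_path),
        "sites_b": _sha256(config.sites_b_path),
        "pdb": _sha256(config.pdb_path),
        "chain_id": config.chain_id,
        "model_number": config.model_number,
        "threshold": config.threshold,
        "seed": config.seed,
        "n_reps": config.n_reps,
        "plane_method": config.plane_method,
        "neighbor_null": config.neighbor_null,
        "reference_row": config.reference_row,
        "offset": config.offset,
    }
    return analyze(
        structure, aln, sites_a, sites_b,
        reference_row=config.reference_row, offset=config.offset,
        min_identity=config.min_identity, n_reps=config.n_reps,
        seed=config.seed, plane_method=config.plane_method,
        neighbor_null=config.neighbor_null,
        n_permutations=config.n_permutations,
        inputs_digest=digest,
    )
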