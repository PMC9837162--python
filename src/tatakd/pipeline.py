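"""End-to-end analysis: read -> filter -> score -> summarize -> test -> report.

A run is described by a :class:`RunConfig` naming either a FASTA +
metadata input pair or a synthetic cohort spec (never both).  Outputs
are plain-text tables plus a machine-readable manifest; a rerun with
the same config and inputs reproduces every output file byte for byte
(no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from ._version import __version__
from .group_stats import FamilyReport, build_family_report
from .promoter_io import Cohort, filter_ambiguous, read_fasta_with_metadata
from .synthetic_data import CohortSpec, generate_cohort
from .tbp_affinity import (
    AffinityEstimate,
    CalibrationAnchors,
    TataMatrix,
    default_matrix,
    estimate_kd,
    load_matrix,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is inconsistent."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    fasta: str | None = None
    metadata: str | None = None
    synthetic: CohortSpec | None = None
    matrix_path: str | None = None  # None -> packaged TATA matrix
    kd_nonspecific: float = 1e-5
    kd_specific: float = 1e-9
    matrix_pseudocount: float = 0.01
    out_dir: str = "tatakd_out"
    species_weighted: bool = False
    bonferroni: bool = False
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        has_files = self.fasta is not None or self.metadata is not None
        if has_files and self.synthetic is not None:
            raise ConfigError("give file inputs or a synthetic spec, not both")
        if not has_files and self.synthetic is None:
            raise ConfigError("need either fasta+metadata or a synthetic spec")
        if has_files and (self.fasta is None or self.metadata is None):
            raise ConfigError("fasta and metadata must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = CohortSpec(**syn)
        return cls(synthetic=syn, **raw)

    def matrix(self) -> TataMatrix:
        if self.matrix_path is None:
            return default_matrix()
        return load_matrix(self.matrix_path, pseudocount=self.matrix_pseudocount)

    def anchors(self) -> CalibrationAnchors:
        return CalibrationAnchors(
            kd_nonspecific=self.kd_nonspecific, kd_specific=self.kd_specific
        )


@dataclass
class RunResult:
    """In-memory view of one completed run."""

    cohort: Cohort
    removed: list[str]
    estimates: dict[str, AffinityEstimate]
    reports: dict[str, FamilyReport]
    out_dir: Path | None = None


def analyze_cohort(
    cohort: Cohort,
    matrix: TataMatrix,
    anchors: CalibrationAnchors,
    species_weighted: bool = False,
    bonferroni: int | None = None,
) -> RunResult:
    """Filter, score and summarize a cohort entirely in memory.

    This is the statistical core of :func:`run`; simulation studies
    call it directly to avoid file I/O per replicate.
    """
    kept, removed = filter_ambiguous(cohort)
    estimates = {
        rec.record_id: estimate_kd(rec.sequence, matrix, anchors) for rec in kept
    }
    reports = build_family_report(
        estimates, kept, species_weighted=species_weighted, bonferroni=bonferroni
    )
    return RunResult(cohort=kept, removed=removed, estimates=estimates,
                     reports=reports)


def _per_promoter_table(result: RunResult) -> pd.DataFrame:
    rows = []
    for rec in result.cohort:
        est = result.estimates[rec.record_id]
        rows.append({
            "record_id": rec.record_id,
            "species": rec.species,
            "family": rec.gene_family.value,
            "group": rec.group.value,
            "kd_nM": est.kd_nM,
            "best_start": est.best_start,
            "best_strand": est.best_strand.value,
            "best_score": est.best_score,
        })
    return pd.DataFrame(rows, columns=[
        "record_id", "species", "family", "group",
        "kd_nM", "best_start", "best_strand", "best_score",
    ])


def _family_summary_table(reports: Mapping[str, FamilyReport]) -> pd.DataFrame:
    frames = []
    for family in sorted(reports):
        rep = reports[family]
        frames.append(rep.species_rows)
        group_rows = [
            {"family": family, "group": g, "species": "(all)",
             "N": s.n, "M0_nM": s.m0, "SEM_nM": s.sem}
            for g, s in sorted(rep.group_summaries.items())
        ]
        frames.append(pd.DataFrame(group_rows, columns=rep.species_rows.columns))
    if not frames:
        return pd.DataFrame(
            columns=["family", "group", "species", "N", "M0_nM", "SEM_nM"])
    return pd.concat(frames, ignore_index=True)


def _tests_table(reports: Mapping[str, FamilyReport]) -> pd.DataFrame:
    rows = []
    for family in sorted(reports):
        t = reports[family].test
        if t is None:
            rows.append({"family": family, "Z": "NA", "p": "NA",
                         "stars": "", "food_minus_nonfood_nM": "NA"})
        else:
            rows.append({
                "family": family,
                "Z": f"{t.z:.4f}",
                "p": f"{t.p_two_sided:.4g}",
                "stars": t.stars,
                "food_minus_nonfood_nM": f"{t.mean_diff:.4f}",
            })
    return pd.DataFrame(rows, columns=[
        "family", "Z", "p", "stars", "food_minus_nonfood_nM"])


def run(config: RunConfig) -> RunResult:
    """Execute a full analysis run and write the report bundle.

    Writes ``per_promoter_kd.tsv``, ``family_summary.tsv``,
    ``tests.tsv``, ``run.log`` (stage counts) and ``manifest.yaml``
    (config + seed + package version) into ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = config.matrix()
    anchors = config.anchors()

    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        cohort = generate_cohort(spec, matrix)
    else:
        cohort = read_fasta_with_metadata(
            config.fasta, config.metadata,
            provenance=f"files:{config.fasta}",
        )
    n_read = len(cohort)

    result = analyze_cohort(
        cohort, matrix, anchors,
        species_weighted=config.species_weighted,
        bonferroni=3 if config.bonferroni else None,
    )
    result.out_dir = out_dir
    n_removed, n_scored = len(result.removed), len(result.cohort)
    assert n_read == n_removed + n_scored

    float_fmt = "%.6g"
    _per_promoter_table(result).to_csv(
        out_dir / "per_promoter_kd.tsv", sep="\t", index=False,
        float_format=float_fmt)
    _family_summary_table(result.reports).to_csv(
        out_dir / "family_summary.tsv", sep="\t", index=False,
        float_format=float_fmt)
    _tests_table(result.reports).to_csv(
        out_dir / "tests.tsv", sep="\t", index=False)

    log_lines = [
        f"records_read\t{n_read}",
        f"records_removed_ambiguous\t{n_removed}",
        f"records_scored\t{n_scored}",
    ]
    for rid in result.removed:
        log_lines.append(f"removed\t{rid}")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines[:3]:
        logger.info(line.replace("\t", " = "))

    manifest = {
        "package": "tatakd",
        "version": __version__,
        "seed": config.seed,
        "config": _config_as_dict(config),
        "counts": {"read": n_read, "removed": n_removed, "scored": n_scored},
    }
    (out_dir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True))
    return result


def _config_as_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("synthetic") is not None:
        d["synthetic"]["families"] = [
            f.value for f in config.synthetic.families]
    return d


def summarize_zprintout(result_or_dir: RunResult | str | Path) -> str:
    """Human-readable per-family test table (Z to 2 decimals, stars)."""
    if isinstance(result_or_dir, RunResult):
        df = _tests_table(result_or_dir.reports)
    else:
        df = pd.read_csv(Path(result_or_dir) / "tests.tsv", sep="\t",
                         dtype=str, keep_default_na=False)
    lines = [f"{'family':<14} {'Z':>6}  {'p':>10}  stars"]
    for row in df.itertuples(index=False):
        try:
            z_txt = f"{float(row.Z):.2f}"
            p_txt = f"{float(row.p):.3g}"
        except ValueError:
            z_txt, p_txt = "NA", "NA"
        lines.append(f"{row.family:<14} {z_txt:>6}  {p_txt:>10}  {row.stars}")
    return "\n".join(lines)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
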