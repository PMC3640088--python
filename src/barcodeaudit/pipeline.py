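"""End-to-end audit run: ingest → distances → gap/errors → mini-barcode →
concordance → contingency stats, fully determined by (inputs, RunConfig)."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from . import concordance as conc
from . import gap as gapmod
from . import minibarcode as mb
from . import pcrstats, seqio
from .distance import AlignmentScoring, build_matrix, write_matrix_tsv
from .records import Dataset, unique_taxa


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for machine parsing."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause

    def as_record(self) -> dict:
        return {"stage": self.stage, "error": str(self.cause), "type": type(self.cause).__name__}


@dataclass
class RunConfig:
    fasta: str = ""
    metadata: str = ""
    taxonomy: str = ""
    out_dir: str = "audit_run"
    threshold_bp: int = 70
    threshold_frac: float = 0.10
    sweep_cutoffs: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 5, 7, 10, 14, 21, 35, 70])
    fp_cutoff_bp: int = 14
    near_miss_bp: int = 1
    nmds_starts: int = 8
    nmds_max_iter: int = 300
    nmds_tol: float = 1e-6
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError(name, exc) from exc
        return inner
    return wrap


@_stage("ingest")
def _ingest(config: RunConfig) -> tuple[Dataset, seqio.JoinReport]:
    seqs = seqio.read_fasta(config.fasta)
    metadata = seqio.read_metadata(config.metadata)
    taxonomy = seqio.read_taxonomy(config.taxonomy)
    return seqio.join_dataset(seqs, metadata, taxonomy)


def run_all(config: RunConfig) -> Path:
    """Execute every stage and write plain-text artifacts to the run directory.

    Reruns with the same inputs and config are byte-identical.  Stage
    failures raise :class:`StageError`; a machine-readable error record is
    left in the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "run_config.json")
    try:
        return _run_all_inner(config, out)
    except StageError as exc:
        (out / "error.json").write_text(json.dumps(exc.as_record(), indent=1))
        raise


def _run_all_inner(config: RunConfig, out: Path) -> Path:
    dataset, join_report = _ingest(config)
    seqio.dataset_to_json(dataset, out / "dataset.json")
    (out / "join_report.json").write_text(json.dumps(dataclasses.asdict(join_report), indent=1))

    matrix = _stage("distances")(build_matrix)(
        dataset, AlignmentScoring(), config.threshold_bp, config.threshold_frac
    )
    write_matrix_tsv(matrix, out / "distances.tsv")

    profile = _stage("gap")(gapmod.divergence_profile)(matrix)
    lines = ["bp_diff\tintra_count\tinter_count"] + [
        f"{int(b)}\t{int(i)}\t{int(e)}"
        for b, i, e in zip(profile.bins, profile.intra_counts, profile.inter_counts)
    ]
    (out / "divergence_profile.tsv").write_text("\n".join(lines) + "\n")

    report = _stage("gap")(gapmod.build_error_report)(
        matrix, dataset, config.fp_cutoff_bp, config.near_miss_bp
    )
    sweep = _stage("gap")(gapmod.threshold_sweep)(matrix, sorted(config.sweep_cutoffs))
    (out / "error_report.json").write_text(json.dumps({
        "false_negatives": [dataclasses.asdict(e) for e in report.false_negatives],
        "false_positives": [dataclasses.asdict(e) for e in report.false_positives],
        "near_misses": [dataclasses.asdict(e) for e in report.near_misses],
        "severity_counts": report.severity_counts(),
        "threshold_sweep": [dataclasses.asdict(p) for p in sweep],
    }, indent=1))

    mb_report = _stage("minibarcode")(mb.minibarcode_report)(
        dataset, None, AlignmentScoring(), config.threshold_bp, config.threshold_frac
    )
    (out / "minibarcode.json").write_text(json.dumps(dataclasses.asdict(mb_report), indent=1))

    tree = _stage("concordance")(conc.upgma)(matrix)
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    flags = []
    for level in ("genus", "family"):
        flags.extend(_stage("concordance")(conc.concordance_flags)(tree, dataset, level))
    flag_lines = ["specimen_id\tlevel\tflag_type\ttaxon\tcontext"] + [
        f"{f.specimen_id}\t{f.level}\t{f.flag_type}\t{f.taxon}\t{f.context}" for f in flags
    ]
    (out / "concordance_flags.tsv").write_text("\n".join(flag_lines) + "\n")

    ordination = None
    if matrix.n >= 4:
        ordination = _stage("concordance")(conc.nmds)(
            matrix, 2, config.nmds_starts, config.nmds_max_iter, config.nmds_tol, config.seed
        )
        ord_lines = [f"#stress={ordination.stress:.8g}",
                     f"#converged={int(ordination.converged)}",
                     "specimen_id\tx\ty"] + [
            f"{sid}\t{x:.8g}\t{y:.8g}"
            for sid, (x, y) in zip(ordination.ids, ordination.coordinates)
        ]
        (out / "ordination.tsv").write_text("\n".join(ord_lines) + "\n")

    stats_summary = {}
    try:
        table = pcrstats.build_table(dataset, row_factor="decade", outcome="pcr_positive")
        res = pcrstats.chi_square_posthoc(table, alpha=config.alpha)
        res.to_frame().to_csv(out / "pcr_by_decade.tsv", sep="\t", index=False)
        stats_summary["decade"] = {"chi2": res.chi2, "df": res.df, "p_value": res.p_value,
                                   "alpha_corrected": res.alpha_corrected}
        strat = pcrstats.stratified_report(dataset, alpha=config.alpha)
        strat.narrative.to_csv(out / "pcr_by_genus_stratified.tsv", sep="\t", index=False)
        stats_summary["genus_strata"] = {
            name: {"chi2": r.chi2, "df": r.df, "p_value": r.p_value}
            for name, r in strat.results.items()
        }
    except ValueError as exc:
        # degenerate metadata (single decade, missing outcomes) is reportable
        stats_summary["skipped"] = str(exc)

    summary = {
        "n_specimens": len(dataset),
        "n_sequenced": len(dataset.sequenced()),
        "n_unique_taxa": unique_taxa(dataset.records),
        "n_retained_pairs": matrix.n_retained,
        "n_nonretained_pairs": matrix.n_nonretained,
        "n_false_negative_species_pairs": len(report.false_negatives),
        "false_negative_severity_counts": report.severity_counts(),
        "n_false_positive_species": len(report.false_positives),
        "n_near_miss_pairs": len(report.near_misses),
        "n_concordance_flags": len(flags),
        "nmds_stress": None if ordination is None else ordination.stress,
        "unresolved_genera": dataset.unresolved_genera(),
        "pcr_stats": stats_summary,
        "join": dataclasses.asdict(join_report),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out
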