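"""Full-run orchestration: simulate (optional), call, evaluate, QC, and
assemble a static report directory.

The report is deliberately flat and machine-readable — TSV tables, a
summary JSON (stable key order, no timestamps, so identical configurations
reproduce identical bytes), PNG figures, and a Markdown index — with the
effective configuration written alongside so any run can be reproduced from
its own report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pysam

from . import evaluate as ev
from . import plotting, qc
from .calls import CallDialect, CnvCall, combine_callers, read_calls
from .config import ConfigError, RunConfig
from .fixtures import calls_from_frame, toy_depth_caller
from .regions import SimulatedDeletion, read_targets, read_truth_tsv
from .simulate import AlignmentSource, SimulationConfig, run_simulation

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _cohort_from_config(config: RunConfig) -> list[AlignmentSource]:
    return [
        AlignmentSource(
            path=Path(path), sample_id=sample, sex=config.sexes.get(sample, "female")
        )
        for sample, path in sorted(config.bams.items())
    ]


def _contig_lengths(config: RunConfig, cohort: Sequence[AlignmentSource]) -> dict[str, int]:
    if config.qc.chrom_sizes:
        out: dict[str, int] = {}
        with open(config.qc.chrom_sizes) as fh:
            for line in fh:
                chrom, length = line.split("\t")
                out[chrom] = int(length)
        return out
    if cohort:
        with pysam.AlignmentFile(str(cohort[0].path), "rb") as af:
            return dict(zip(af.references, af.lengths))
    raise ConfigError("no chrom-sizes table and no BAMs to take contig lengths from")


def _evaluate_one(
    name: str,
    calls: Sequence[CnvCall],
    truth: Sequence[SimulatedDeletion],
    config: RunConfig,
    out_dir: Path,
    known_samples: Sequence[str],
) -> dict:
    labelled = ev.classify_calls(
        calls, truth, overlap_frac=config.evaluation.overlap_frac, known_samples=known_samples
    )
    use_truth = list(truth)
    if config.evaluation.size_by is not None:
        use_truth, labelled = ev.size_stratify(
            use_truth, labelled, by=config.evaluation.size_by,
            size_range=config.evaluation.size_range,
        )
    curve = ev.roc_curve(labelled, use_truth)
    ev.roc_points_frame(curve).to_csv(out_dir / f"roc_{name}.tsv", sep="\t", index=False)
    summary = dataclasses.asdict(ev.sensitivity_precision(labelled, use_truth))
    result = {"summary": summary}
    if labelled:
        bins = ev.calibration_bins(labelled, n_bins=config.evaluation.n_bins)
        ev.calibration_frame(bins).to_csv(out_dir / f"calibration_{name}.tsv", sep="\t", index=False)
        result["_bins"] = bins
    result["_curve"] = curve
    result["_labelled"] = labelled
    return result


def run_full(config: RunConfig, log_path: str | Path | None = None) -> Path:
    """Execute every configured stage and write the report directory."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = None
    if log_path is not None:
        handler = logging.FileHandler(log_path)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("cnvbench").addHandler(handler)

    try:
        targets = read_targets(config.targets)
        cohort = _cohort_from_config(config)

        # --- stage: simulation / truth -----------------------------------
        try:
            if config.simulation.enabled:
                sim = run_simulation(
                    cohort,
                    targets,
                    SimulationConfig(
                        method=config.simulation.method,
                        n_range=config.simulation.n_range,
                        size_range_targets=config.simulation.size_range_targets,
                        seed=config.simulation.seed,
                        p_remove=config.simulation.p_remove,
                        cross_sample_disjoint=config.simulation.cross_sample_disjoint,
                    ),
                    out_dir / "simulated",
                )
                truth = sim.truth
                called_cohort = [
                    AlignmentSource(path=p, sample_id=s, sex=config.sexes.get(s, "female"))
                    for s, p in sorted(sim.sample_paths.items())
                ]
            else:
                assert config.truth is not None
                truth = read_truth_tsv(config.truth)
                called_cohort = cohort
        except Exception as exc:  # noqa: BLE001 — re-raise with stage context
            raise StageError("simulate", exc) from exc

        known_samples = [s.sample_id for s in called_cohort] or sorted(
            {d.sample_id for d in truth}
        )

        # --- stage: call tables ------------------------------------------
        try:
            calls_by_caller: dict[str, list[CnvCall]] = {}
            for decl in config.callers:
                dialect = CallDialect(
                    coords=decl.coords,
                    higher_is_better=decl.higher_is_better,
                    chrom_col=decl.chrom_col,
                    start_col=decl.start_col,
                    end_col=decl.end_col,
                    sample_col=decl.sample_col,
                )
                calls_by_caller[decl.name] = read_calls(
                    decl.path, decl.name, decl.score_column, dialect
                )
            if config.toy_caller.enabled:
                df = toy_depth_caller(
                    called_cohort, targets, z_threshold=config.toy_caller.z_threshold
                )
                calls_by_caller["toy_rd"] = calls_from_frame(df, "toy_rd")
        except Exception as exc:  # noqa: BLE001
            raise StageError("calls", exc) from exc

        # --- stage: evaluation -------------------------------------------
        try:
            summary: dict = {"callers": {}, "combinations": {}}
            curves = {}
            bins_by_caller = {}
            for name, calls in calls_by_caller.items():
                res = _evaluate_one(name, calls, truth, config, out_dir, known_samples)
                summary["callers"][name] = res["summary"]
                curves[name] = res["_curve"]
                if "_bins" in res:
                    bins_by_caller[name] = res["_bins"]
            if config.evaluation.combine and len(calls_by_caller) >= 2:
                for mode in ("union", "intersection"):
                    combined = combine_callers(calls_by_caller, mode=mode)
                    res = _evaluate_one(mode, combined, truth, config, out_dir, known_samples)
                    summary["combinations"][mode] = res["summary"]
                    curves[mode] = res["_curve"]
        except Exception as exc:  # noqa: BLE001
            raise StageError("evaluate", exc) from exc

        # --- stage: qc ----------------------------------------------------
        try:
            counts = qc.sample_counts(calls_by_caller, samples=known_samples)
            counts.to_csv(out_dir / "sample_counts.tsv", sep="\t", index=False)
            lengths = _contig_lengths(config, called_cohort)
            dist = qc.genome_distribution(
                calls_by_caller, lengths, bin_width=config.qc.bin_width
            )
            dist.to_csv(out_dir / "genome_distribution.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("qc", exc) from exc

        # --- stage: report ------------------------------------------------
        try:
            plotting.plot_roc(curves, out_dir / "roc.png")
            if bins_by_caller:
                plotting.plot_calibration(bins_by_caller, out_dir / "calibration.png")
            if not counts.empty:
                plotting.plot_sample_counts(counts, out_dir / "sample_counts.png")
            if not dist.empty:
                plotting.plot_genome_distribution(dist, out_dir / "genome_distribution.png")
            with open(out_dir / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            config.write_yaml(out_dir / "effective_config.yaml")
            _write_index(out_dir, summary, calls_by_caller)
        except Exception as exc:  # noqa: BLE001
            raise StageError("report", exc) from exc
    finally:
        if handler is not None:
            logging.getLogger("cnvbench").removeHandler(handler)
            handler.close()
    return out_dir


def _write_index(out_dir: Path, summary: Mapping, calls_by_caller: Mapping) -> None:
    lines = ["# CNV benchmarking report", ""]
    lines.append("## Accuracy summary")
    lines.append("")
    lines.append("| call set | calls | TP | FP | sensitivity | precision |")
    lines.append("|---|---|---|---|---|---|")
    for section in ("callers", "combinations"):
        for name, s in sorted(summary.get(section, {}).items()):
            sens = "—" if s["sensitivity"] is None else f"{s['sensitivity']:.3f}"
            prec = "—" if s["precision"] is None else f"{s['precision']:.3f}"
            lines.append(
                f"| {name} | {s['n_calls']} | {s['n_tp_calls']} | {s['n_fp_calls']} "
                f"| {sens} | {prec} |"
            )
    lines += [
        "",
        "## Files",
        "",
        "- `summary.json` — accuracy summary per call set",
        "- `roc_<caller>.tsv`, `roc.png` — ranked accuracy curves",
        "- `calibration_<caller>.tsv`, `calibration.png` — quality-score calibration",
        "- `sample_counts.tsv`, `sample_counts.png` — per-sample call counts",
        "- `genome_distribution.tsv`, `genome_distribution.png` — call density in genome bins",
        "- `effective_config.yaml` — resolved configuration; re-running it reproduces this report",
    ]
    (out_dir / "index.md").write_text("\n".join(lines) + "\n")
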