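"""End-to-end orchestration: simulate → experiments → confounder assessment
→ size sweep → clustering → DDx ranking, from one declarative run
configuration and one master seed.

Per-stage seeds are derived by a stable hash of (master_seed, stage name,
experiment name), so stages never share a random stream and any stage can be
reproduced in isolation.  Every TSV artifact carries the master seed in a
header comment; the run summary is machine-readable JSON written with sorted
keys, so identical configurations produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from ._seeding import derive_seed
from .cohort import CohortManifest, read_manifest, write_manifest
from .clustering import confusion_to_distance, to_newick, upgma
from .confounder import (
    ConfounderReport,
    ExperimentResult,
    ExperimentSpec,
    assess_confounder,
    greatest_common_size,
    run_repeated_experiment,
    size_sweep,
)
from .ddx import build_library, rank_case, similarity_flags, topk_frequency
from .metrics import accuracy, expected_random_accuracy
from .model import loo_confusion
from .simulate import ConfounderEffect, SimulationConfig, generate_population

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _simulation_config_from_dict(d: Mapping[str, Any], seed: int) -> SimulationConfig:
    d = dict(d)
    effects = tuple(
        ConfounderEffect(**e) for e in d.pop("confounder_effects", ())
    )
    for key in ("class_labels", "class_sizes", "age_range"):
        if key in d:
            d[key] = tuple(d[key])
    if "class_centroids" in d and d["class_centroids"] is not None:
        d["class_centroids"] = tuple(tuple(c) for c in d["class_centroids"])
    d.setdefault("seed", seed)
    return SimulationConfig(confounder_effects=effects, **d)


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of a full analysis run."""

    seed: int = 0
    out_dir: Path = Path("phenoconfound-run")
    simulation: SimulationConfig | None = None
    manifest_path: Path | None = None
    experiments: tuple[Mapping[str, Any], ...] = ()
    comparisons: tuple[Mapping[str, Any], ...] = ()
    sweep: Mapping[str, Any] | None = None
    cluster: bool = True
    ddx: Mapping[str, Any] | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulation is None and self.manifest_path is None:
            raise ValueError("config needs either a simulation block or a manifest path")


def load_run_config(
    path: str | Path, seed: int | None = None, out_dir: str | Path | None = None
) -> RunConfig:
    """Load a YAML/JSON run configuration (field names mirror RunConfig)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    run_seed = int(seed if seed is not None else raw.get("seed", 0))
    sim = raw.get("simulation")
    return RunConfig(
        seed=run_seed,
        out_dir=Path(out_dir if out_dir is not None else raw.get("out_dir", "phenoconfound-run")),
        simulation=(
            _simulation_config_from_dict(sim, derive_seed(run_seed, "simulate"))
            if sim is not None
            else None
        ),
        manifest_path=Path(raw["manifest"]) if raw.get("manifest") else None,
        experiments=tuple(raw.get("experiments", ())),
        comparisons=tuple(raw.get("comparisons", ())),
        sweep=raw.get("sweep"),
        cluster=bool(raw.get("cluster", True)),
        ddx=raw.get("ddx"),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _write_tsv(frame: pd.DataFrame, path: Path, seed: int, **to_csv_kw) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, sep="\t", **to_csv_kw)


def _experiment_frame(result: ExperimentResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": list(result.labels),
            "mean_tpr": result.mean_tpr,
            "sd_tpr": result.sd_tpr,
            "mean_mcc": result.mean_mcc,
            "sd_mcc": result.sd_mcc,
        }
    )


def _report_frame(report: ConfounderReport) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [a.label for a in report],
            "mcc_confounder_mean": [a.mcc_confounder_mean for a in report],
            "mcc_control_mean": [a.mcc_control_mean for a in report],
            "delta_mcc": [a.delta_mcc for a in report],
            "sd_control": [a.sd_control for a in report],
            "ratio": [a.ratio for a in report],
            "flagged": [a.flagged for a in report],
        }
    )


def _run_stage(stage: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every configured stage; returns the (JSON-serialisable) summary.

    All artifacts are written under ``config.out_dir``; the summary is also
    written as ``summary.json``.  Fully reproducible from (config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    seed = config.seed
    summary: dict[str, Any] = {"seed": seed}

    # -- cohort --------------------------------------------------------------
    if config.simulation is not None:
        manifest = _run_stage("simulate", generate_population, config.simulation)
    else:
        manifest = _run_stage("load-manifest", read_manifest, config.manifest_path)
    write_manifest(manifest, out / "manifest.csv")
    summary["cohort"] = {
        "n_records": len(manifest),
        "class_sizes": manifest.class_sizes(),
        "expected_random_accuracy": expected_random_accuracy(
            list(manifest.class_sizes().values())
        ),
    }

    # -- experiments ---------------------------------------------------------
    results: dict[str, ExperimentResult] = {}
    summary["experiments"] = {}
    for entry in config.experiments:
        name = str(entry.get("name", "experiment"))
        filters = entry.get("filters")
        gcs = _run_stage(f"experiment:{name}", greatest_common_size, manifest, filters)
        sample_size = int(entry.get("sample_size", gcs))
        spec = ExperimentSpec(
            sample_size=sample_size,
            cohort_filters=filters,
            n_iterations=int(entry.get("n_iterations", 5)),
            master_seed=derive_seed(seed, "experiment", name),
        )
        result = _run_stage(
            f"experiment:{name}", run_repeated_experiment, manifest, spec
        )
        results[name] = result
        _write_tsv(_experiment_frame(result), out / f"experiment_{name}.tsv", seed,
                   index=False)
        for i, cm in enumerate(result.confusions):
            cm.to_tsv(out / f"confusion_{name}_iter{i}.tsv")
            cm.to_tsv(out / f"confusion_{name}_iter{i}.probs.tsv", probabilities=True)
        summary["experiments"][name] = {
            "sample_size": sample_size,
            "greatest_common_size": gcs,
            "n_iterations": spec.n_iterations,
            "mean_accuracy": result.mean_accuracy,
            "mean_mcc": dict(zip(result.labels, map(float, result.mean_mcc))),
            "sd_mcc": dict(zip(result.labels, map(float, result.sd_mcc))),
            "mean_tpr": dict(zip(result.labels, map(float, result.mean_tpr))),
        }

    # -- confounder comparisons ----------------------------------------------
    summary["comparisons"] = {}
    for entry in config.comparisons:
        name = str(entry.get("name", "comparison"))
        try:
            confounder = results[str(entry["confounder"])]
            control = results[str(entry["control"])]
        except KeyError as exc:
            raise PipelineError(
                f"stage 'confound:{name}' failed: unknown experiment {exc}"
            ) from exc
        report = _run_stage(f"confound:{name}", assess_confounder, confounder, control)
        _write_tsv(_report_frame(report), out / f"confounder_{name}.tsv", seed,
                   index=False)
        summary["comparisons"][name] = {
            a.label: {
                "delta_mcc": a.delta_mcc,
                "sd_control": a.sd_control,
                "ratio": a.ratio,
                "flagged": a.flagged,
            }
            for a in report
        }

    # -- cohort-size sweep -----------------------------------------------------
    if config.sweep is not None:
        sw = dict(config.sweep)
        sweep_result = _run_stage(
            "sweep",
            size_sweep,
            manifest,
            sizes=tuple(sw.get("sizes", (10, 20, 30, 40))),
            n_iterations=int(sw.get("n_iterations", 5)),
            master_seed=derive_seed(seed, "sweep"),
            cohort_filters=sw.get("filters"),
        )
        frame = pd.DataFrame(
            {
                "class": list(sweep_result.labels),
                "slope": [sweep_result.fits[c].slope for c in sweep_result.labels],
                "intercept": [
                    sweep_result.fits[c].intercept for c in sweep_result.labels
                ],
                "r": [sweep_result.fits[c].r for c in sweep_result.labels],
                "p_value": [sweep_result.fits[c].p_value for c in sweep_result.labels],
            }
        )
        _write_tsv(frame, out / "sweep.tsv", seed, index=False)
        summary["sweep"] = {
            "sizes": list(sweep_result.sizes),
            "fits": {
                c: {
                    "slope": sweep_result.fits[c].slope,
                    "p_value": sweep_result.fits[c].p_value,
                }
                for c in sweep_result.labels
            },
        }

    # -- clustering ------------------------------------------------------------
    if config.cluster:
        cm = _run_stage("cluster", loo_confusion, manifest)
        cm.to_tsv(out / "confusion_full.tsv")
        cm.to_tsv(out / "confusion_full.probs.tsv", probabilities=True)
        dm = _run_stage("cluster", confusion_to_distance, cm)
        dm.to_tsv(out / "distance.tsv")
        tree = _run_stage("cluster", upgma, dm)
        newick = to_newick(tree)
        (out / "dendrogram.nwk").write_text(newick + "\n", encoding="utf-8")
        summary["cluster"] = {
            "newick": newick,
            "full_set_accuracy": accuracy(cm),
        }

    # -- DDx ranking -----------------------------------------------------------
    if config.ddx is not None:
        dd = dict(config.ddx)
        k = int(dd.get("k", 30))
        threshold = float(dd.get("threshold", 0.10))
        label_map = dd.get("label_map")
        library = _run_stage(
            "ddx",
            build_library,
            manifest,
            n_background=int(dd.get("n_background", 295)),
            seed=derive_seed(seed, "ddx"),
            background_separation=float(dd.get("background_separation", 8.0)),
        )
        rankings_by_cohort = {
            cls: [rank_case(r, library) for r in records]
            for cls, records in manifest.by_class().items()
        }
        rows = []
        ddx_summary: dict[str, Any] = {"k": k, "library_size": len(library)}
        for cls, rankings in rankings_by_cohort.items():
            freq_topk, freq_rank1 = topk_frequency(rankings, cls, k, label_map)
            rows.append(
                {
                    "cohort": cls,
                    "syndrome": cls,
                    "freq_topk": freq_topk,
                    "freq_rank1": freq_rank1,
                    "flagged": "",
                }
            )
            ddx_summary[cls] = {
                "correct_topk_frequency": freq_topk,
                "correct_rank1_frequency": freq_rank1,
            }
        for flag in similarity_flags(
            rankings_by_cohort, k=k, threshold=threshold, label_map=label_map
        ):
            rows.append(
                {
                    "cohort": flag.cohort,
                    "syndrome": flag.syndrome,
                    "freq_topk": flag.frequency,
                    "freq_rank1": "",
                    "flagged": flag.flagged,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "ddx.tsv", seed, index=False)
        summary["ddx"] = ddx_summary

    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    return summary
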