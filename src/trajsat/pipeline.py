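"""End-to-end orchestration: simulate -> clean -> speed -> classify -> associate.

One global seed governs every stochastic stage; stage seeds are derived from
it deterministically, so two runs with the same configuration produce
byte-identical artifacts.  Every stage writes its intermediate outputs before
the next stage starts, and a failure aborts with the stage name while the
partial artifacts remain on disk for debugging.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assoc, classify, ingest, synth, viz

logger = logging.getLogger("trajsat.pipeline")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str | Path = "trajsat_run"
    synth: synth.SynthConfig | None = None  # None -> read visits/participants CSVs
    visits_csv: str | Path | None = None
    participants_csv: str | Path | None = None
    classifier: classify.ClassifierConfig = field(default_factory=classify.ClassifierConfig)
    association_mode: str = "both"  # univariate | multivariate | both
    seed: int = 0
    log_level: str = "INFO"


def _stage_seed(seed: int, idx: int) -> int:
    return (seed * 1000003 + idx) % (2**31)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return repr(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return (and write) the run manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn()
            except Exception as exc:
                _write_manifest(outdir, manifest)
                raise PipelineStageError(name, exc) from exc
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
            }
            return out

        return wrap

    # --- simulate (optional) ------------------------------------------------
    if config.synth is not None:
        def _simulate():
            cfg = dataclasses.replace(config.synth, seed=_stage_seed(config.seed, 1))
            cohort = synth.generate_cohort(cfg)
            cohort, _ = synth.inject_timestamp_errors(
                cohort, cfg.corrupt_rates, seed=_stage_seed(config.seed, 2)
            )
            synth.write_cohort_csvs(
                cohort, outdir / "visits.csv", outdir / "participants.csv"
            )
            return cohort

        cohort = stage("simulate")(_simulate)
        records = list(cohort.records)
        participants = cohort.participants
        manifest["stages"]["simulate"]["n_records"] = len(records)
    else:
        def _load():
            recs = ingest.read_visits_csv(config.visits_csv)
            parts = pd.read_csv(config.participants_csv)
            return recs, parts

        records, participants = stage("load")(_load)
        manifest["stages"]["load"]["n_records"] = len(records)

    # --- clean --------------------------------------------------------------
    def _clean():
        kept, report = ingest.clean_visits(records)
        report.to_json(outdir / "clean_report.json")
        return kept, report

    kept, report = stage("clean")(_clean)
    manifest["stages"]["clean"].update(report.as_dict())

    # --- speed --------------------------------------------------------------
    def _speed():
        series = ingest.build_series(kept)
        ingest.write_speed_csv(series, outdir / "speeds.csv")
        return series

    series = stage("speed")(_speed)
    manifest["stages"]["speed"]["n_participants"] = len(series)

    # --- classify -----------------------------------------------------------
    def _classify():
        ccfg = dataclasses.replace(
            config.classifier,
            step1_spec=dataclasses.replace(
                config.classifier.step1_spec, seed=_stage_seed(config.seed, 3)
            ),
        )
        result = classify.two_step_classify(series, ccfg)
        labels = pd.DataFrame(
            {
                "participant_id": list(result.label),
                "satisficer": [int(v) for v in result.label.values()],
                "step1_group": [result.step1_group[p] for p in result.label],
                "step2_subgroup": [
                    "" if result.step2_subgroup[p] is None else result.step2_subgroup[p]
                    for p in result.label
                ],
            }
        ).sort_values("participant_id")
        labels.to_csv(outdir / "labels.csv", index=False)
        (outdir / "provenance.json").write_text(
            json.dumps(result.provenance, indent=2, default=str) + "\n"
        )
        classify.summarize(result).to_csv(outdir / "summary.csv", index=False)
        return result

    result = stage("classify")(_classify)
    manifest["stages"]["classify"]["n_satisficers"] = result.n_satisficers
    manifest["stages"]["classify"]["n_participants"] = result.n_total

    # --- plots --------------------------------------------------------------
    def _plots():
        from .gbtm import GbtmModel
        import numpy as np

        prov = result.provenance
        m = prov["step1_model"]
        model1 = GbtmModel(
            pi=np.array(m["pi"]),
            beta=np.array(m["beta"]),
            sigma=np.array(m["sigma"]).squeeze(),
            shared_sigma=m["shared_sigma"],
            order=m["order"],
            loglik=m["loglik"],
            n_params=m["n_params"],
            bic=m["bic"],
            converged=m["converged"],
            n_participants=m["n_participants"],
        )
        viz.plot_trajectories(
            model1, series, outdir / "step1_trajectories.png",
            title="Step 1: cohort trajectory groups",
        )

    stage("plots")(_plots)

    # --- associate ----------------------------------------------------------
    def _associate():
        panel = assoc.build_panel(result, kept, participants)
        tables = []
        modes = (
            ["univariate", "multivariate"]
            if config.association_mode == "both"
            else [config.association_mode]
        )
        for mode in modes:
            tab = assoc.fit_repeated_logistic(panel, mode=mode)
            tab.to_csv(outdir / f"or_{mode}.csv", index=False)
            tables.append(tab)
        t1 = assoc.table1_summary(result, participants)
        t1.categorical.to_csv(outdir / "table1_categorical.csv", index=False)
        t1.age.to_csv(outdir / "table1_age.csv", index=False)
        return pd.concat(tables, ignore_index=True)

    or_table = stage("associate")(_associate)
    manifest["stages"]["associate"]["n_terms"] = len(or_table)

    # --- report -------------------------------------------------------------
    def _report():
        lines = [
            "# trajsat run report",
            "",
            f"- seed: {config.seed}",
            f"- config hash: {manifest['config_hash']}",
            "",
            "## Cleaning",
            "",
        ]
        lines += [f"- {k}: {v}" for k, v in report.as_dict().items()]
        lines += ["", "## Classification", ""]
        lines += [
            f"- satisficers: {result.n_satisficers}/{result.n_total} "
            f"({classify.percent(result.n_satisficers, result.n_total)}%)",
            f"- step-1 groups: {len(set(result.step1_group.values()))}",
            "",
            "## Associations (odds ratios)",
            "",
            or_table.to_string(index=False),
            "",
        ]
        (outdir / "report.md").write_text("\n".join(lines))

    stage("report")(_report)
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
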