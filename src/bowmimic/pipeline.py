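"""End-to-end orchestration: simulate -> kinematics -> strokes -> metrics -> stats.

Each stage lives in its own module; this layer wires them together for a
whole cohort, keeps per-stage timings and counts, and writes every artifact
with a manifest.  It is also the programmatic surface the analysis scripts
and the acceptance battery drive.
"""

from __future__ import annotations

import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio, stats
from .bayes import SamplerSettings
from .kinematics import (
    AudioSignal,
    BowKinematics,
    MotionTrace,
    bow_contact_kinematics,
    derivatives,
    loudness_envelope,
)
from .metrics import stroke_metrics
from .strokes import gate_length, gate_loudness, pair_strokes, segment_strokes
from .synthetic import CohortBundle, CohortDesign, generate_cohort, generate_questionnaires

__all__ = [
    "performance_kinematics",
    "extract_stroke_metrics",
    "cohort_stroke_table",
    "calibrate_metrics",
    "run_pipeline",
]

log = logging.getLogger(__name__)


def performance_kinematics(trace: MotionTrace, config=None) -> BowKinematics:
    """Bow contact kinematics with derivatives for one performance."""
    config = config or dataio.RunConfig()
    kin = bow_contact_kinematics(trace)
    return derivatives(kin, cutoff=config.smoothing_cutoff)


def extract_stroke_metrics(
    leader: MotionTrace,
    follower: MotionTrace,
    audio: AudioSignal,
    config: dataio.RunConfig | None = None,
):
    """Per-stroke PD / dSI for one leader-follower performance pair.

    Strokes are segmented on the leader, gated by length (default 150 mm)
    and loudness (default 15 % of the performance's median), then paired
    with the follower over identical clock-time windows.
    """
    config = config or dataio.RunConfig()
    kin_l = performance_kinematics(leader, config)
    kin_f = performance_kinematics(follower, config)
    segs = segment_strokes(
        kin_l,
        min_duration=config.min_duration,
        min_excursion=config.min_excursion,
        speed_floor=config.speed_floor,
    )
    segs = gate_length(segs, min_length=config.min_length)
    env = loudness_envelope(audio, leader)
    segs = gate_loudness(segs, env, fraction=config.loudness_fraction)
    pairs = pair_strokes(kin_l, kin_f, segs, n_resample=config.n_resample)
    out = []
    for pair in pairs:
        out.append(
            stroke_metrics(
                pair,
                fs=pair.resample_rate,
                fc=config.sparc_fc,
                amp_threshold=config.sparc_amp_threshold,
                pad_level=config.sparc_pad_level,
            )
        )
    return out


def cohort_stroke_table(
    bundle: CohortBundle, config: dataio.RunConfig | None = None
) -> pd.DataFrame:
    """One row per surviving stroke across the whole cohort."""
    config = config or dataio.RunConfig()
    rows = []
    for cell, leader, follower, audio in bundle.iter_cells():
        for m in extract_stroke_metrics(leader, follower, audio, config):
            rows.append(
                {
                    "participant": cell.participant,
                    "condition": cell.condition,
                    "trial": cell.trial,
                    "piece": cell.piece,
                    "violin_section": cell.violin_section,
                    "stroke_index": m.stroke_index,
                    "direction": m.direction,
                    "length": m.length,
                    "duration": m.duration,
                    "mean_loudness": m.mean_loudness,
                    "PD": m.pd,
                    "si_avatar": m.si_avatar,
                    "si_participant": m.si_participant,
                    "dSI": m.dsi,
                }
            )
    return pd.DataFrame(rows)


def calibrate_metrics(
    stroke_table: pd.DataFrame, design: CohortDesign | None = None
) -> pd.DataFrame:
    """z-scale each metric over all strokes, take cell medians, calibrate.

    Returns one row per participant x condition x trial with calibrated
    PD and dSI columns (group medians per piece x violin-section are zero).
    """
    if len(stroke_table) == 0:
        raise ValueError("empty cells: no strokes survived segmentation and gating")
    out = None
    for metric in ("PD", "dSI"):
        df = stroke_table.copy()
        df["value"] = stats.zscale(df[metric])
        cells = stats.cell_medians(df, design=design)
        cells = stats.group_calibrate(cells)
        cells = cells.rename(columns={"value": metric})
        out = cells if out is None else out.merge(
            cells, on=[c for c in cells.columns if c != metric]
        )
    return out


def run_pipeline(config: dataio.RunConfig, out_dir=None) -> stats.ReportBundle:
    """Execute the full workflow and write artifacts + manifest to disk."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings, counts, files = {}, {}, []

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = _time.perf_counter()
                log.info("stage %s ...", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(_time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s done in %.2f s", name, timings[name])

        return _T()

    design = CohortDesign(
        n_participants=config.n_participants,
        conditions=config.conditions,
        n_trials=config.n_trials,
        seed=config.seed,
    )
    with stage("simulate"):
        bundle = generate_cohort(design)
        questionnaires = generate_questionnaires(design)
        counts["cells"] = len(bundle.cells)
        p = out / "ledger.csv"
        bundle.ledger.to_csv(p, index=False)
        files.append(p)
        p = out / "questionnaires.csv"
        questionnaires.to_csv(p, index=False)
        files.append(p)
        config.to_json(out / "config.json")
        files.append(out / "config.json")

    with stage("metrics"):
        stroke_table = cohort_stroke_table(bundle, config)
        counts["strokes"] = len(stroke_table)
        p = out / "stroke_metrics.csv"
        stroke_table.to_csv(p, index=False)
        files.append(p)

    with stage("calibrate"):
        metric_dataset = calibrate_metrics(stroke_table, design)
        counts["calibrated_rows"] = len(metric_dataset)
        p = out / "calibrated_dataset.csv"
        metric_dataset.to_csv(p, index=False)
        files.append(p)

    with stage("questionnaire_scores"):
        qscores = stats.score_questionnaires(questionnaires)
        p = out / "questionnaire_scores.csv"
        qscores.scores.to_csv(p, index=False)
        files.append(p)

    with stage("stats"):
        wf = stats.WorkflowConfig(
            sampler=SamplerSettings(
                chains=config.chains,
                warmup=config.warmup,
                draws=config.draws,
                seed=config.seed,
            ),
            compare=config.compare,
            seed=config.seed,
        )
        report = stats.run_workflow(metric_dataset, qscores, wf)
        for response, table in report.contrast_tables.items():
            p = out / f"contrasts_{response}.csv"
            table.to_csv(p, index=False)
            files.append(p)
        diag = {
            resp: {k: v for k, v in d.items() if k != "ppc"}
            for resp, d in report.diagnostics.items()
        }
        import json

        p = out / "diagnostics.json"
        p.write_text(json.dumps(diag, indent=2, sort_keys=True) + "\n")
        files.append(p)

    dataio.write_manifest(out, config, files, timings=timings, counts=counts)
    log.info("pipeline complete: %s", counts)
    return report
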