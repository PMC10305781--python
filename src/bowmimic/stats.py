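"""Calibration, questionnaire scoring, and the contrast workflow.

Per-stroke metric values are z-scaled (pooled over all strokes of all
performances for that metric), summarised as one median per participant x
condition x trial cell — the default cohort gives 11 x 2 x 4 = 88 rows —
and calibrated by subtracting the (piece x violin-section) group median, so
stimulus-difficulty offsets cancel.  The calibrated dataset feeds the
hierarchical models in :mod:`bowmimic.bayes`; questionnaires are scored as
per-administration scale means with Cronbach's alpha reliability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import (
    ContrastResult,
    ModelComparison,
    ModelSpec,
    PosteriorSummary,
    SamplerSettings,
    bayes_r2,
    compare_models,
    contrasts,
    default_contrast_labels,
    fit_model,
    posterior_predictive_check,
)

__all__ = [
    "zscale",
    "cell_medians",
    "group_calibrate",
    "cronbach_alpha",
    "QuestionnaireScores",
    "score_questionnaires",
    "WorkflowConfig",
    "ReportBundle",
    "run_workflow",
    # re-exported model layer
    "ModelSpec",
    "SamplerSettings",
    "PosteriorSummary",
    "ContrastResult",
    "ModelComparison",
    "fit_model",
    "contrasts",
    "bayes_r2",
    "posterior_predictive_check",
    "compare_models",
]

log = logging.getLogger(__name__)

CELL_KEYS = ["participant", "condition", "trial"]
GROUP_KEYS = ["piece", "violin_section"]


def zscale(values) -> np.ndarray:
    """Standardise a metric series to mean 0, SD 1 (sample SD).

    Pooled over everything passed in: the intended use is one call per
    metric over all strokes of all performances.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to scale")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (x - x.mean()) / sd


def cell_medians(strokes: pd.DataFrame, design=None, value: str = "value") -> pd.DataFrame:
    """One median per participant x condition x trial cell.

    ``strokes`` holds one row per stroke with the cell keys, the group keys
    (piece, violin_section) and a ``value`` column.  If ``design`` (a
    :class:`~bowmimic.synthetic.CohortDesign`) is given, every design cell
    must have at least one stroke; missing cells raise with their identity.
    """
    req = set(CELL_KEYS + [value])
    if not req <= set(strokes.columns):
        raise ValueError(f"stroke table missing columns: {sorted(req - set(strokes.columns))}")
    keys = CELL_KEYS + [k for k in GROUP_KEYS if k in strokes.columns]
    out = (
        strokes.groupby(keys, as_index=False, sort=True)[value]
        .median()
        .rename(columns={value: "value"})
    )
    if design is not None:
        have = set(map(tuple, out[CELL_KEYS].itertuples(index=False)))
        missing = [c for c in design.cells() if c not in have]
        if missing:
            raise ValueError(f"empty cells (no surviving strokes): {missing}")
    return out


def group_calibrate(dataset: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Subtract the (piece x violin_section) group median from each row.

    After calibration every group's median is exactly zero;
    within-group differences are preserved.
    """
    for k in GROUP_KEYS:
        if k not in dataset.columns:
            raise ValueError(f"dataset missing group column {k!r}")
    out = dataset.copy()
    out[value] = out[value] - out.groupby(GROUP_KEYS)[value].transform("median")
    return out


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a respondents x items matrix.

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total)), with sample
    variances (ddof=1) throughout.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 respondents")
    k = x.shape[1]
    var_total = x.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / var_total))


@dataclass
class QuestionnaireScores:
    """Per-administration scale means plus per-scale reliabilities."""

    scores: pd.DataFrame  # cell keys + WPQ/MPQS/MPQP/MPQ/difficulty columns
    alphas: dict[str, float]


def score_questionnaires(table: pd.DataFrame) -> QuestionnaireScores:
    """Score item-level questionnaire responses.

    Item columns follow the ``SCALE_n`` convention (WPQ on 1-7, MPQS and
    MPQP on 1-5); ``difficulty`` (0-100) passes through.  The MPQ composite
    is the item-pool mean over the MPQS and MPQP items.  Administrations
    with missing items are scored from the available items and logged.
    Cronbach's alpha is computed per scale across administrations.
    """
    item_cols: dict[str, list[str]] = {}
    for col in table.columns:
        if "_" in col:
            scale, _, idx = col.rpartition("_")
            if scale in ("WPQ", "MPQS", "MPQP") and idx.isdigit():
                item_cols.setdefault(scale, []).append(col)
    if not item_cols:
        raise ValueError("no questionnaire item columns (expected e.g. WPQ_1)")

    meta = [c for c in table.columns if c in CELL_KEYS + GROUP_KEYS]
    out = table[meta].copy()
    alphas = {}
    for scale, cols in item_cols.items():
        vals = table[cols].to_numpy(dtype=float)
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            log.warning(
                "%d missing %s items; administrations scored from available items",
                n_missing,
                scale,
            )
        out[scale] = np.nanmean(vals, axis=1)
        complete = ~np.isnan(vals).any(axis=1)
        if complete.sum() >= 2:
            try:
                alphas[scale] = cronbach_alpha(vals[complete])
            except ValueError:
                log.warning("alpha undefined for %s (degenerate responses)", scale)
    if "MPQS" in item_cols and "MPQP" in item_cols:
        pool = table[item_cols["MPQS"] + item_cols["MPQP"]].to_numpy(dtype=float)
        out["MPQ"] = np.nanmean(pool, axis=1)
    if "difficulty" in table.columns:
        out["difficulty"] = table["difficulty"].astype(float)
    return QuestionnaireScores(scores=out, alphas=alphas)


# ---------------------------------------------------------------------------
# workflow


@dataclass
class WorkflowConfig:
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    metric_responses: tuple[str, ...] = ("PD", "dSI")
    questionnaire_responses: tuple[str, ...] = ("WPQ", "MPQS", "MPQP", "difficulty")
    compare: bool = True  # run the Bayes-factor / LOO model comparison
    contrast_labels: list[str] | None = None  # default: full battery
    seed: int = 0


@dataclass
class ReportBundle:
    """Per-response contrast tables, comparisons and diagnostics."""

    contrast_tables: dict[str, pd.DataFrame]
    comparisons: dict[str, ModelComparison | None]
    diagnostics: dict[str, dict]
    fits: dict[str, PosteriorSummary]


def _contrast_table(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Label": [r.label for r in results],
            "Estimate": [round(r.estimate, 4) for r in results],
            "CI.Lower": [round(r.ci_lower, 4) for r in results],
            "CI.Upper": [round(r.ci_upper, 4) for r in results],
            "Post.Prob": [round(r.post_prob, 4) for r in results],
        }
    )


def _analyse_response(
    data: pd.DataFrame, response: str, covariate: str | None, config: WorkflowConfig
) -> tuple[pd.DataFrame, ModelComparison | None, dict, PosteriorSummary]:
    sampler = SamplerSettings(
        chains=config.sampler.chains,
        warmup=config.sampler.warmup,
        draws=config.sampler.draws,
        seed=config.sampler.seed + config.seed,
    )
    fit_simple = fit_model(data, ModelSpec(response=response, sampler=sampler))
    comparison = None
    best = fit_simple
    if config.compare and covariate is not None and covariate in data.columns:
        fit_cov = fit_model(
            data, ModelSpec(response=response, covariate=covariate, sampler=sampler)
        )
        comparison = compare_models(fit_simple, fit_cov, seed=config.seed)
        best = fit_simple if comparison.favors_a else fit_cov
    labels = config.contrast_labels or default_contrast_labels(best)
    table = _contrast_table(contrasts(best, labels))
    r2c, r2m = bayes_r2(best)
    ppc = posterior_predictive_check(best, seed=config.seed)
    diag = {
        "converged": best.converged,
        "max_rhat": max(best.rhat.values()),
        "min_ess": min(best.ess.values()),
        "r2_conditional": r2c,
        "r2_marginal": r2m,
        "ppc": ppc.to_dict(orient="records"),
    }
    return table, comparison, diag, best


def run_workflow(
    metric_dataset: pd.DataFrame,
    questionnaire_scores: QuestionnaireScores | pd.DataFrame,
    config: WorkflowConfig | None = None,
) -> ReportBundle:
    """Fit, compare, diagnose and contrast every response.

    ``metric_dataset`` holds one row per cell with calibrated metric
    columns (e.g. PD, dSI); metric models optionally add perceived
    difficulty as covariate, questionnaire models add the cell's PD.
    Returns one contrast table per response, shaped Label / Estimate /
    CI.Lower / CI.Upper / Post.Prob.
    """
    config = config or WorkflowConfig()
    qs = (
        questionnaire_scores.scores
        if isinstance(questionnaire_scores, QuestionnaireScores)
        else questionnaire_scores
    )
    tables, comparisons, diagnostics, fits = {}, {}, {}, {}

    difficulty = None
    if qs is not None and "difficulty" in qs.columns:
        difficulty = qs[CELL_KEYS + ["difficulty"]]

    for response in config.metric_responses:
        if response not in metric_dataset.columns:
            raise ValueError(f"metric column {response!r} not in metric dataset")
        data = metric_dataset.copy()
        covariate = None
        if difficulty is not None:
            data = data.merge(difficulty, on=CELL_KEYS, how="left")
            covariate = "difficulty"
        try:
            tables[response], comparisons[response], diagnostics[response], fits[response] = (
                _analyse_response(data, response, covariate, config)
            )
        except Exception as err:
            raise RuntimeError(f"workflow failed at metric response {response!r}: {err}") from err

    if qs is not None:
        pd_cells = None
        if "PD" in metric_dataset.columns:
            pd_cells = metric_dataset[CELL_KEYS + ["PD"]]
        for response in config.questionnaire_responses:
            if response not in qs.columns:
                continue
            data = qs.copy()
            covariate = None
            if pd_cells is not None and response != "PD":
                data = data.merge(pd_cells, on=CELL_KEYS, how="left")
                covariate = "PD"
            try:
                tables[response], comparisons[response], diagnostics[response], fits[response] = (
                    _analyse_response(data, response, covariate, config)
                )
            except Exception as err:
                raise RuntimeError(
                    f"workflow failed at questionnaire response {response!r}: {err}"
                ) from err
    return ReportBundle(
        contrast_tables=tables, comparisons=comparisons, diagnostics=diagnostics, fits=fits
    )
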