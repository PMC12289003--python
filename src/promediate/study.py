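"""Replicated simulation study: simulate -> (render -> extract) -> fit -> score.

Each replication draws a fresh cohort from the known data-generating process,
optionally routes it through transcript rendering and extraction, fits the
Gibbs sampler, and records posterior means and 95% equal-tailed intervals.
Estimator quality per quantity is then summarized exactly as a Monte-Carlo
simulation study reports it:

    Bias           = mean_r(estimate_r - truth)
    RMSE           = sqrt(mean_r((estimate_r - truth)^2))
    Coverage       = mean_r(1{lower_r <= truth <= upper_r})
    Interval_Width = mean_r(upper_r - lower_r)

computed over converged replications only (split R-hat < 1.01 for every
quantity), with the excluded count carried on the result. Replication ``r``
uses seed master_seed + r; within a replication the cohort seed and MCMC seed
are split off that seed so both pipeline paths share identical randomness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dialogue import simulate_cohort, simulate_ground_truth
from .errors import ConfigError, PromediateError, StudyFailureError
from .extraction import AnalysisTable, extract_cohort
from .model import FitSummary, fit_mediation, summarize
from .params import MediationParams, StudyConfig

__all__ = [
    "TABLE_QUANTITIES",
    "ReplicationResult",
    "MetricsTable",
    "true_value_of",
    "compute_metrics",
    "run_study",
    "replication_frame",
]

#: Row set and order of the reported metrics table (the ten estimands).
TABLE_QUANTITIES = (
    "a", "b", "cprime", "d", "im", "iy", "sigma_m", "sigma_y",
    "indirect effect", "total effect",
)

#: Metrics-table row name -> posterior-draw quantity name.
_DRAW_NAME = {q: q for q in TABLE_QUANTITIES[:8]}
_DRAW_NAME["indirect effect"] = "indirect"
_DRAW_NAME["total effect"] = "total"


@dataclass(frozen=True)
class ReplicationResult:
    """One replication's fit summary plus its seed and convergence flag."""

    replication_id: int
    seed: int
    summary: FitSummary
    converged: bool


@dataclass(frozen=True)
class MetricsTable:
    """Bias/RMSE/Coverage/Interval_Width per estimand, plus exclusion counts."""

    table: pd.DataFrame  # index TABLE_QUANTITIES; columns bias, rmse, coverage, interval_width
    n_converged: int
    n_excluded: int


def true_value_of(params: MediationParams, quantity: str) -> float:
    """The true value of any reported estimand under a known parameter vector."""
    direct = {
        "a": params.a, "b": params.b, "cprime": params.c_prime, "d": params.d,
        "im": params.i_m, "iy": params.i_y,
        "sigma_m": params.sigma_m, "sigma_y": params.sigma_y,
        "direct effect": params.c_prime,
        "indirect effect": params.a * params.b,
        "total effect": params.c_prime + params.a * params.b,
        # draw-name aliases
        "direct": params.c_prime,
        "indirect": params.a * params.b,
        "total": params.c_prime + params.a * params.b,
    }
    try:
        return float(direct[quantity])
    except KeyError:
        raise ConfigError(f"unknown quantity {quantity!r}") from None


def compute_metrics(
    params: MediationParams, results: list[ReplicationResult]
) -> MetricsTable:
    """Score the replications against the known truth.

    Only converged replications contribute; the number excluded is reported.
    Raises :class:`StudyFailureError` when fewer than two replications
    converged (no meaningful Monte-Carlo average exists).
    """
    converged = [r for r in results if r.converged]
    n_excluded = len(results) - len(converged)
    if len(converged) < 2:
        raise StudyFailureError(
            f"only {len(converged)} of {len(results)} replications converged; "
            "cannot compute study metrics"
        )
    rows = []
    for quantity in TABLE_QUANTITIES:
        truth = true_value_of(params, quantity)
        name = _DRAW_NAME[quantity]
        est = np.array([r.summary.row(name)["mean"] for r in converged])
        lo = np.array([r.summary.row(name)["ci_lower"] for r in converged])
        hi = np.array([r.summary.row(name)["ci_upper"] for r in converged])
        rows.append(
            {
                "quantity": quantity,
                "bias": float(np.mean(est - truth)),
                "rmse": float(np.sqrt(np.mean((est - truth) ** 2))),
                "coverage": float(np.mean((lo <= truth) & (truth <= hi))),
                "interval_width": float(np.mean(hi - lo)),
            }
        )
    table = pd.DataFrame(rows).set_index("quantity")
    return MetricsTable(
        table=table, n_converged=len(converged), n_excluded=n_excluded
    )


def _split_seeds(rep_seed: int) -> tuple[int, int]:
    """Cohort and MCMC seeds for one replication (stable 31-bit splits)."""
    state = np.random.SeedSequence(rep_seed).generate_state(2)
    return int(state[0] % (2**31)), int(state[1] % (2**31))


def run_replication(config: StudyConfig, r: int) -> ReplicationResult:
    """Execute replication ``r`` of a study (exposed for incremental reruns)."""
    rep_seed = config.master_seed + r
    cohort_seed, mcmc_seed = _split_seeds(rep_seed)
    cohort_cfg = dataclasses.replace(config.cohort, seed=cohort_seed)
    if config.use_transcript_path:
        transcripts, _ = simulate_cohort(cohort_cfg)
        table = extract_cohort(transcripts)
    else:
        records = simulate_ground_truth(cohort_cfg)
        table = AnalysisTable.from_ground_truth(
            records, fatigue_threshold=cohort_cfg.fatigue_threshold
        )
    mcmc_cfg = dataclasses.replace(config.mcmc, seed=mcmc_seed)
    draws = fit_mediation(table, priors=config.priors, mcmc=mcmc_cfg)
    summary = summarize(draws)
    return ReplicationResult(
        replication_id=r, seed=rep_seed, summary=summary,
        converged=summary.converged,
    )


def run_study(config: StudyConfig) -> tuple[MetricsTable, list[ReplicationResult]]:
    """Run all replications and score them; deterministic given the config.

    A failing replication aborts the study with its replication ID and seed
    in the message — a simulation study must never silently drop cohorts.
    """
    results: list[ReplicationResult] = []
    for r in range(config.n_replications):
        try:
            results.append(run_replication(config, r))
        except PromediateError as exc:
            raise StudyFailureError(
                f"replication {r} (seed {config.master_seed + r}) failed: {exc}"
            ) from exc
    metrics = compute_metrics(config.cohort.params, results)
    return metrics, results


def replication_frame(results: list[ReplicationResult]) -> pd.DataFrame:
    """Long-format per-replication table (one row per replication x quantity)."""
    rows = []
    for r in results:
        for quantity in TABLE_QUANTITIES:
            s = r.summary.row(_DRAW_NAME[quantity])
            rows.append(
                {
                    "replication_id": r.replication_id,
                    "seed": r.seed,
                    "quantity": quantity,
                    "post_mean": s["mean"],
                    "ci_lower": s["ci_lower"],
                    "ci_upper": s["ci_upper"],
                    "rhat": s["rhat"],
                    "converged": r.converged,
                }
            )
    return pd.DataFrame(rows)
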