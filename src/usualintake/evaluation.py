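"""The replication study: generate, estimate, exclude, score.

For each scenario, ``replicates`` synthetic samples are generated, all
three estimators are run on every sample, and samples for which at least
one method estimated the between-person variance as zero are excluded
from the analysis for all methods.  Accuracy is summarized per method and
statistic by

    bias          B   = sum_j (theta_hat_j - theta) / N
    relative bias RB  = |B / theta| * 100                 (percent)
    MSE               = sum_j (theta_hat_j - theta)^2 / N

against the true value theta from the quadrature oracle, together with a
Bonferroni-corrected t confidence interval for the mean bias (the family
being the methods compared within one scenario-statistic panel).

Seeding is hierarchical: study seed -> per-(scenario, replicate) data
substream -> per-person substream; the NCI-style pseudo-person draw gets
its own substream so method order can never affect the data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import METHODS, EstimatorConfig, UsualIntakeEstimate
from .oracle import TrueDistribution, true_distribution
from .scenario_sim import ScenarioSpec, generate_dataset

__all__ = [
    "ReplicateOutcome",
    "StudyResult",
    "run_replicate",
    "compute_metrics",
    "bonferroni_ci",
    "run_study",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicateOutcome:
    """All methods' estimates on one simulated sample."""

    replicate_index: int
    estimates: dict[str, UsualIntakeEstimate]
    excluded: bool
    errors: dict[str, str] = dataclasses.field(default_factory=dict)


@dataclass(frozen=True)
class StudyResult:
    """Outputs of a full scenarios-by-replicates run.

    metrics       : summary table under the all-methods exclusion rule
    metrics_all   : same summary over all available samples (no exclusion)
    replicates    : tidy per-replicate table (scenario, replicate, method,
                    statistic, estimate, bias, excluded) — boxplot-ready
    exclusions    : per-scenario count of excluded samples
    """

    metrics: pd.DataFrame
    metrics_all: pd.DataFrame
    replicates: pd.DataFrame
    exclusions: pd.DataFrame


def _substream_seed(*keys: int) -> int:
    """A reproducible 31-bit seed derived from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] >> 1)


def run_replicate(
    spec: ScenarioSpec,
    replicate_index: int,
    seed: int,
    config: EstimatorConfig = EstimatorConfig(),
) -> ReplicateOutcome:
    """Generate one sample and run all three estimators on it.

    The sample is excluded when any method's between-person variance
    estimate is zero (degenerate), or when any estimator fails outright.
    Deterministic given ``(spec, replicate_index, seed)``.
    """
    data_seed = _substream_seed(seed, replicate_index, 0)
    nci_seed = _substream_seed(seed, replicate_index, 1)
    data = generate_dataset(spec, data_seed)
    cfg = replace(config, nci_seed=nci_seed)

    estimates: dict[str, UsualIntakeEstimate] = {}
    errors: dict[str, str] = {}
    for name, fn in METHODS.items():
        try:
            estimates[name] = fn(data, cfg)
        except Exception as exc:  # noqa: BLE001 — per-method failures never abort
            logger.warning(
                "%s failed on %s replicate %d: %s", name, spec.label, replicate_index, exc
            )
            errors[name] = str(exc)

    excluded = bool(errors) or any(e.degenerate for e in estimates.values())
    return ReplicateOutcome(replicate_index, estimates, excluded, errors)


def bonferroni_ci(biases, n_methods: int, level: float = 0.95) -> tuple[float, float]:
    """Bonferroni-corrected t confidence interval for a mean bias.

    Each of the ``n_methods`` intervals is built at level
    ``1 - (1 - level)/n_methods`` so the family holds jointly at ``level``.
    """
    biases = np.asarray(biases, dtype=float)
    if biases.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    if n_methods < 1:
        raise ValueError("n_methods must be >= 1")
    alpha = 1.0 - level
    n = biases.size
    tq = stats.t.ppf(1.0 - alpha / (2.0 * n_methods), df=n - 1)
    center = float(biases.mean())
    half = float(tq * biases.std(ddof=1) / np.sqrt(n))
    return center - half, center + half


def _stat_names_for(config: EstimatorConfig) -> list[str]:
    names = ["mean"]
    for p in config.percentile_probs:
        pct = 100.0 * p
        names.append(f"P{pct:g}")
    return names


def compute_metrics(
    outcomes,
    truth: TrueDistribution,
    scenario_label: str = "",
    n_methods_family: int = len(METHODS),
    level: float = 0.95,
    apply_exclusion: bool = True,
) -> pd.DataFrame:
    """Bias / relative bias / MSE / Bonferroni CI per method and statistic.

    Only non-excluded outcomes enter when ``apply_exclusion`` (a method's
    rows still skip replicates where that method itself failed).
    """
    usable = [o for o in outcomes if not (apply_exclusion and o.excluded)]
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable replicates")

    stat_names = sorted(
        {"mean"} | {f"P{100 * p:g}" for o in usable for e in o.estimates.values() for p in e.percentiles},
        key=lambda s: -1.0 if s == "mean" else float(s[1:]),
    )

    rows = []
    for method in METHODS:
        per_rep = [o.estimates[method] for o in usable if method in o.estimates]
        if len(per_rep) < 2:
            continue
        for stat_name in stat_names:
            theta = truth.statistic(stat_name)
            est = np.array([e.statistic(stat_name) for e in per_rep])
            errs = est - theta
            bias = float(errs.mean())
            lo, hi = bonferroni_ci(errs, n_methods_family, level)
            rows.append(
                {
                    "scenario": scenario_label,
                    "method": method,
                    "statistic": stat_name,
                    "N": len(per_rep),
                    "bias": bias,
                    "rel_bias_pct": abs(bias / theta) * 100.0,
                    "mse": float((errs**2).mean()),
                    "ci_low": lo,
                    "ci_high": hi,
                    "truth": theta,
                }
            )
    return pd.DataFrame(rows)


def run_study(
    specs,
    replicates: int,
    seed: int,
    config: EstimatorConfig = EstimatorConfig(),
    oracle_nodes: int = 150,
) -> StudyResult:
    """Run the full scenarios-by-replicates cross and summarize it.

    Per-replicate estimator failures are logged and counted as excluded;
    they never abort the study.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    specs = list(specs)

    metric_frames, metric_all_frames, rep_rows, excl_rows = [], [], [], []
    for s_idx, spec in enumerate(specs):
        truth = true_distribution(spec, config.percentile_probs, oracle_nodes)
        outcomes = [
            run_replicate(spec, r, _substream_seed(seed, s_idx), config)
            for r in range(replicates)
        ]
        n_excluded = sum(o.excluded for o in outcomes)
        excl_rows.append(
            {"scenario": spec.label, "replicates": replicates, "excluded": n_excluded}
        )
        metric_frames.append(
            compute_metrics(outcomes, truth, spec.label, apply_exclusion=True)
        )
        metric_all_frames.append(
            compute_metrics(outcomes, truth, spec.label, apply_exclusion=False)
        )
        for o in outcomes:
            for method, est in o.estimates.items():
                for stat_name in _stat_names_for(config):
                    theta = truth.statistic(stat_name)
                    val = est.statistic(stat_name)
                    rep_rows.append(
                        {
                            "scenario": spec.label,
                            "replicate": o.replicate_index,
                            "method": method,
                            "statistic": stat_name,
                            "estimate": val,
                            "bias": val - theta,
                            "excluded": o.excluded,
                        }
                    )

    return StudyResult(
        metrics=pd.concat(metric_frames, ignore_index=True),
        metrics_all=pd.concat(metric_all_frames, ignore_index=True),
        replicates=pd.DataFrame(rep_rows),
        exclusions=pd.DataFrame(excl_rows),
    )


def write_study(result: StudyResult, out_dir, manifest: dict | None = None) -> None:
    """Write summary.csv / summary_all.csv / replicates.csv / exclusions.csv."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out / "summary.csv", index=False)
    result.metrics_all.to_csv(out / "summary_all.csv", index=False)
    result.replicates.to_csv(out / "replicates.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    if manifest is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
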