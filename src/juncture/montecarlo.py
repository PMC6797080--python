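"""Monte Carlo recovery study: repeated draw → truth → fit cycles.

Each repetition draws a fresh hierarchical sample, computes the true
average effects *in that sample* by potential-outcome replay, and fits
every estimand of the canonical roster:

=============  =========  ======================  ==============
estimand       estimator  specifications          cluster SE
=============  =========  ======================  ==============
D2→X4, D2→X5   linear     short                   organization
X4→T1, X5→T1   probit     short + full            —
T1→Y2          linear     short + full            —
=============  =========  ======================  ==============

Summaries report, per (estimand, specification), the mean relative bias
(estimate − truth)/truth across repetitions, its empirical standard error
(the sample SD across repetitions), and the 95% confidence interval
mean ± 1.96·SE/√R.  A ratio-of-means aggregation is reported as a
secondary column.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimate import EstimandSpec, build_specification, fit
from .model_spec import JunctureModel, validate_claims, _model_to_payload
from .simulate import (
    CANONICAL_ESTIMANDS,
    PopulationConfig,
    draw_population,
    true_sample_effects,
)

__all__ = [
    "MonteCarloResult",
    "BiasSummary",
    "MonteCarloRunError",
    "SummaryError",
    "default_roster",
    "repetition_seed",
    "run",
    "summarize",
    "render_bias_figure",
]

logger = logging.getLogger("juncture.montecarlo")

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class MonteCarloRunError(RuntimeError):
    """More than 1% of repetitions failed: misconfigured model/coefficients."""


class SummaryError(ValueError):
    """Summary undefined (e.g. a zero truth makes relative bias undefined)."""


@dataclass
class MonteCarloResult:
    records: pd.DataFrame  # rep, seed, estimand, specification, estimate, se, n_used, truth
    failures: list  # (rep, seed, reason)
    n_repetitions: int
    master_seed: int
    model_hash: str

    def __post_init__(self):
        if self.n_repetitions < 2:
            raise ValueError("repetition count must be at least 2")


@dataclass
class BiasSummary:
    table: pd.DataFrame  # indexed by (estimand, specification)
    n_repetitions: int
    failures: int

    @property
    def max_abs_mean_rel_bias(self) -> float:
        return float(self.table["mean_rel_bias"].abs().max())

    @property
    def n_ci_excluding_zero(self) -> int:
        lo, hi = self.table["ci_low"], self.table["ci_high"]
        return int(((lo > 0) | (hi < 0)).sum())


def default_roster(model: JunctureModel) -> list:
    """Certified estimand specifications for the canonical roster.

    Organization-level strategy effects are identified with the short
    specification only (the full specification adds no further named
    covariate of interest there); practitioner- and patient-level effects
    are fitted under both short and full specifications.
    """
    specs = []
    for treatment, outcome, _ in CANONICAL_ESTIMANDS:
        modes = (
            ("short",)
            if model.level_of(treatment) == "organization"
            else ("short", "full")
        )
        for mode in modes:
            specs.append(build_specification(model, treatment, outcome, mode))
    return specs


def model_digest(model: JunctureModel) -> str:
    payload = json.dumps(_model_to_payload(model), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def repetition_seed(master_seed: int, rep: int) -> int:
    """Counter-based substream seed: any repetition is reproducible alone."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(rep),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run(
    model: JunctureModel,
    n_repetitions: int,
    master_seed: int = 0,
    roster: Optional[Sequence[EstimandSpec]] = None,
    check_claims: bool = True,
    progress_every: int = 0,
) -> MonteCarloResult:
    """Execute the Monte Carlo study.

    Deterministic given ``master_seed``; repetitions use independent
    counter-based substreams, so results do not depend on execution order.
    Failed repetitions (degenerate samples) are recorded and excluded; more
    than 1% failures aborts the run as a misconfiguration signal.
    """
    if n_repetitions < 2:
        raise ValueError("n_repetitions must be at least 2")
    if check_claims:
        report = validate_claims(model)
        if not report.all_passed:
            raise MonteCarloRunError(
                "model fails identification claims:\n" + report.summary()
            )
    if roster is None:
        roster = default_roster(model)

    rows = []
    failures = []
    for rep in range(n_repetitions):
        seed = repetition_seed(master_seed, rep)
        try:
            config = PopulationConfig.from_model(model, seed=seed)
            dataset = draw_population(model, config)
            truths = true_sample_effects(model, dataset)
            for spec in roster:
                est = fit(model, dataset, spec)
                rows.append(
                    {
                        "rep": rep,
                        "seed": seed,
                        "estimand": spec.estimand_id,
                        "specification": spec.specification,
                        "estimate": est.estimate,
                        "se": est.se,
                        "n_used": est.n_used,
                        "truth": truths[spec.estimand_id],
                    }
                )
        except Exception as exc:  # degenerate sample: record, never resample
            failures.append((rep, seed, f"{type(exc).__name__}: {exc}"))
            rows = [r for r in rows if r["rep"] != rep]
        if progress_every and (rep + 1) % progress_every == 0:
            logger.info("repetition %d/%d complete", rep + 1, n_repetitions)

    if len(failures) > 0.01 * n_repetitions:
        detail = "; ".join(f[2] for f in failures[:3])
        raise MonteCarloRunError(
            f"{len(failures)} of {n_repetitions} repetitions failed "
            f"(> 1%): {detail}"
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "rep", "seed", "estimand", "specification",
            "estimate", "se", "n_used", "truth",
        ],
    )
    return MonteCarloResult(
        records=records,
        failures=failures,
        n_repetitions=n_repetitions,
        master_seed=master_seed,
        model_hash=model_digest(model),
    )


def summarize(result: MonteCarloResult) -> BiasSummary:
    """Per-(estimand, specification) relative-bias summary.

    Relative bias is aggregated as the mean of per-repetition ratios
    (each repetition has its own sample truth); the ratio of mean error to
    mean truth is reported alongside as ``rel_bias_ratio_of_means``.
    """
    rec = result.records
    if rec.empty:
        raise SummaryError("no successful repetitions to summarize")
    if (rec["truth"] == 0).any() or rec["truth"].isna().any():
        bad = rec.loc[(rec["truth"] == 0) | rec["truth"].isna(), "estimand"].unique()
        raise SummaryError(
            f"zero/undefined sample truth for {sorted(bad)}: relative bias is "
            "undefined; change the structural coefficients"
        )
    rec = rec.assign(rel_bias=(rec["estimate"] - rec["truth"]) / rec["truth"])

    def agg(group: pd.DataFrame) -> pd.Series:
        r = len(group)
        mean = group["rel_bias"].mean()
        emp_se = group["rel_bias"].std(ddof=1)
        half = Z95 * emp_se / np.sqrt(r)
        return pd.Series(
            {
                "mean_rel_bias": mean,
                "empirical_se": emp_se,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "rel_bias_ratio_of_means": (group["estimate"] - group["truth"]).mean()
                / group["truth"].mean(),
                "empirical_se_estimate": group["estimate"].std(ddof=1),
                "mean_truth": group["truth"].mean(),
                "repetitions": r,
            }
        )

    table = (
        rec.groupby(["estimand", "specification"], sort=True)
        .apply(agg, include_groups=False)
        .astype({"repetitions": int})
    )
    return BiasSummary(
        table=table,
        n_repetitions=result.n_repetitions,
        failures=len(result.failures),
    )


def render_bias_figure(summary: BiasSummary, path) -> None:
    """Point-with-95%-CI plot of mean relative bias per (estimand, spec).

    Also writes the underlying table as CSV next to the figure.
    """
    if summary.table.empty:
        raise SummaryError("empty summary: nothing to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = summary.table.reset_index()
    labels = [
        f"{e.replace('->', '→')}\n({s})"
        for e, s in zip(table["estimand"], table["specification"])
    ]
    x = np.arange(len(table))
    fig, ax = plt.subplots(figsize=(1.4 * len(table) + 2, 4.5))
    ax.errorbar(
        x,
        table["mean_rel_bias"],
        yerr=[
            table["mean_rel_bias"] - table["ci_low"],
            table["ci_high"] - table["mean_rel_bias"],
        ],
        fmt="o",
        capsize=4,
        color="black",
    )
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(x)
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_ylabel("relative effect bias")
    ax.set_title(
        f"Monte Carlo relative bias ({summary.n_repetitions} repetitions, "
        f"{summary.failures} failed)"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    csv_path = str(path)
    for ext in (".png", ".pdf", ".svg"):
        if csv_path.endswith(ext):
            csv_path = csv_path[: -len(ext)]
            break
    table.to_csv(csv_path + ".csv", index=False)
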