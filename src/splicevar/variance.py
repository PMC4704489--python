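"""Variance-response tables and the control vs single-cell comparison.

:func:`build_responses` turns per-exon, per-condition summaries into the
gamma mixed model's unit of analysis: one row per cassette exon x condition
holding the across-cell variance of transformed inclusion (the response),
its covariates (conservation, mean expression, condition), and a prior
weight proportional to the number of cells behind the variance.

:func:`compare_experiments` contrasts the single-cell experiment with the
diluted-bulk technical control: per exon x condition, the natural-log fold
change of mean expression and of the variance of transformed inclusion are
modeled with Gaussian linear mixed models (random intercept per exon); a
positive variance-ratio intercept means single cells vary more than the
technical floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["build_responses", "compare_experiments", "ExperimentComparison"]

MIN_VARIANCE = 1e-12  # responses at/below this are outside usable gamma support


def build_responses(
    summaries: pd.DataFrame,
    conservation: pd.DataFrame,
    conservation_as: str = "group",
    min_variance: float = MIN_VARIANCE,
) -> pd.DataFrame:
    """One gamma-model row per exon x condition, with weights.

    ``summaries`` is the output of :func:`splicevar.inclusion.summarize_exons`
    (columns exon_id, condition, n_samples, var_t, mean_expression).
    ``conservation`` maps exon_id to either a categorical ``group`` or a
    continuous ``score`` (``conservation_as`` chooses which enters the
    model). Rows whose variance is at or below ``min_variance`` are excluded
    (logged via warning); weights are n_samples divided by the mean
    n_samples over the *final* table, so they average to 1.
    """
    if conservation_as not in ("group", "score"):
        raise ValueError("conservation_as must be 'group' or 'score'")
    cons_col = conservation_as
    if cons_col not in conservation.columns:
        raise ValueError(f"conservation table lacks a {cons_col!r} column")
    cons = conservation[["exon_id", cons_col]].drop_duplicates("exon_id")
    missing = set(summaries["exon_id"]) - set(cons["exon_id"])
    if missing:
        raise ValueError(
            f"no conservation annotation for exons: {sorted(missing)[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    table = summaries.drop(columns=[cons_col], errors="ignore").merge(
        cons, on="exon_id", how="left"
    )
    degenerate = table["var_t"] <= min_variance
    if degenerate.any():
        dropped = table.loc[degenerate, ["exon_id", "condition"]]
        warnings.warn(
            f"excluding {int(degenerate.sum())} zero/near-zero-variance "
            f"responses (gamma support): "
            + ", ".join(f"{r.exon_id}/{r.condition}" for r in dropped.itertuples())
        )
        table = table.loc[~degenerate]
    table = table.reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("no usable variance responses remain")
    table["weight"] = table["n_samples"] / table["n_samples"].mean()
    cols = [
        "exon_id",
        "condition",
        "var_t",
        cons_col,
        "mean_expression",
        "n_samples",
        "weight",
    ]
    return table[cols]


@dataclass
class ExperimentComparison:
    """Paired fold-change models contrasting two qPCR experiments."""

    table: pd.DataFrame
    expression_fit: object  # statsmodels MixedLMResults
    variance_fit: object

    @property
    def expression_intercept(self) -> tuple[float, float]:
        """(estimate, two-sided p) for the mean-expression log fold change."""
        return (
            float(self.expression_fit.params["Intercept"]),
            float(self.expression_fit.pvalues["Intercept"]),
        )

    @property
    def variance_intercept(self) -> tuple[float, float]:
        """(estimate, two-sided p) for the inclusion-variance log fold change."""
        return (
            float(self.variance_fit.params["Intercept"]),
            float(self.variance_fit.pvalues["Intercept"]),
        )


def compare_experiments(
    single: pd.DataFrame,
    control: pd.DataFrame,
    conservation: pd.DataFrame | None = None,
) -> ExperimentComparison:
    """Model log fold changes between single-cell and control experiments.

    Inputs are exon x condition summary tables (as from
    :func:`splicevar.inclusion.summarize_exons`), matched on exon_id and
    condition. Model 1: ln(mean expression ratio) ~ group + condition.
    Model 2: ln(variance ratio of transformed inclusion) ~ group + condition
    + ln(expression ratio). Both carry a random intercept per exon and are
    fit by ML so intercept tests are comparable. Rows with a non-positive
    variance in either experiment are excluded (logged).
    """
    import statsmodels.formula.api as smf

    merged = single.merge(
        control, on=["exon_id", "condition"], suffixes=("_sc", "_ctrl")
    )
    if len(merged) == 0:
        raise ValueError("no matched exon x condition rows between experiments")
    bad = (merged["var_t_sc"] <= 0) | (merged["var_t_ctrl"] <= 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} rows with non-positive variance "
            "in one of the experiments"
        )
        merged = merged.loc[~bad].reset_index(drop=True)
    tab = merged.assign(
        log_expr_fc=np.log(merged["mean_expression_sc"] / merged["mean_expression_ctrl"]),
        log_var_fc=np.log(merged["var_t_sc"] / merged["var_t_ctrl"]),
    )
    if conservation is not None:
        cons = conservation[["exon_id", "group"]].drop_duplicates("exon_id")
        tab = tab.merge(cons, on="exon_id", how="left")
        if tab["group"].isna().any():
            raise ValueError("conservation groups missing for some exons")
        fe = "C(group) + C(condition)"
    else:
        fe = "C(condition)"

    def fit(formula, response):
        if np.ptp(tab[response].to_numpy()) == 0.0:
            # degenerate case (e.g. identical experiments): the model is a
            # constant; report it as the intercept with an untestable p-value
            return _ConstantFit(float(tab[response].iloc[0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.mixedlm(formula, tab, groups=tab["exon_id"]).fit(reml=False)

    expr_fit = fit(f"log_expr_fc ~ {fe}", "log_expr_fc")
    var_fit = fit(f"log_var_fc ~ {fe} + log_expr_fc", "log_var_fc")
    return ExperimentComparison(table=tab, expression_fit=expr_fit, variance_fit=var_fit)


class _ConstantFit:
    """Stand-in result for a constant response (no variation to model)."""

    def __init__(self, value: float):
        self.params = pd.Series({"Intercept": value})
        self.pvalues = pd.Series({"Intercept": np.nan})
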