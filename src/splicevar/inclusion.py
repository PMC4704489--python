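"""Cassette-exon inclusion levels (PSI) from qPCR expression indices.

With primer pairs calibrated near 100% efficiency, ``2^Et - 1`` approximates
the number of template molecules of an isoform. Treating each transcript of
the gene as an independent Bernoulli trial (included with probability p),
the maximum-likelihood estimate of the inclusion level is

    p_hat = (2^EtI - 1) / (2^EtI + 2^EtS - 2)

with EtI/EtS the expression indices of the included/skipped isoform, and
n_hat = 2^EtI + 2^EtS - 2 the total-expression proxy. Under this Bernoulli
model Var(p_hat) = p(1-p)/n, so the angular transform t = arcsin(sqrt(p_hat))
stabilizes the variance to approximately 1/(4n) independent of p — the
across-cell variance of t is the pipeline's measure of splicing precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr import compute_et
from .synthetic import QpcrPlate

__all__ = [
    "estimate_inclusion",
    "arcsin_transform",
    "records_from_plate",
    "filter_no_alt_splicing",
    "summarize_exons",
    "binomial_variance_curve",
    "overdispersion_test",
]


def estimate_inclusion(et_included, et_skipped):
    """ML inclusion estimate p_hat and total-expression proxy n_hat.

    Vectorized; where both Et are 0 (neither isoform detected) the estimate
    is undefined and returned as NaN — such records are excluded downstream.
    """
    et_i = np.asarray(et_included, dtype=float)
    et_s = np.asarray(et_skipped, dtype=float)
    if np.any(et_i < 0) or np.any(et_s < 0):
        raise ValueError("Et values must be non-negative")
    expr_i = np.exp2(et_i) - 1.0
    expr_s = np.exp2(et_s) - 1.0
    n_hat = expr_i + expr_s
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(n_hat > 0, expr_i / np.where(n_hat > 0, n_hat, 1.0), np.nan)
    if p_hat.ndim == 0:
        return float(p_hat), float(n_hat)
    return p_hat, n_hat


def arcsin_transform(p, mode: str = "sqrt"):
    """Variance-stabilizing angular transform t = arcsin(sqrt(p)).

    ``mode='sqrt'`` is the standard angular transform for binomial
    proportions (t in [0, pi/2], Var(t) ~ 1/(4n)); ``mode='linear'`` applies
    a literal arcsin(p), kept for sensitivity analysis only.
    """
    p = np.asarray(p, dtype=float)
    valid = np.isnan(p) | ((p >= 0.0) & (p <= 1.0))
    if not np.all(valid):
        raise ValueError("inclusion levels must lie in [0, 1]")
    if mode == "sqrt":
        t = np.arcsin(np.sqrt(p))
    elif mode == "linear":
        t = np.arcsin(p)
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    return float(t) if t.ndim == 0 else t


def records_from_plate(
    plate: QpcrPlate, transform_mode: str = "sqrt"
) -> pd.DataFrame:
    """Per cell x exon inclusion records from a (preprocessed) plate.

    Pairs each exon's included and skipped wells within a sample. Wells at
    Ct = Cmax contribute Et = 0 (zero expression); a sample x exon with a
    *missing* well (removed by filtering) is skipped. Records where neither
    isoform was detected carry p_hat = NaN and are dropped.

    The exon id is the assay id up to the last ':' (e.g. ``EX001:inc``).
    """
    wells = plate.wells[plate.wells["isoform_role"].isin(["included", "skipped"])]
    wells = wells.assign(
        exon_id=wells["assay_id"].str.rsplit(":", n=1).str[0],
        et=compute_et(wells["Ct"].to_numpy(), plate.c_max),
    )
    wide = wells.pivot_table(
        index=["sample_id", "cell_type", "exon_id"],
        columns="isoform_role",
        values="et",
        aggfunc="mean",
    )
    wide = wide.dropna(subset=["included", "skipped"]).reset_index()
    p_hat, n_hat = estimate_inclusion(
        wide["included"].to_numpy(), wide["skipped"].to_numpy()
    )
    rec = wide.rename(columns={"included": "et_included", "skipped": "et_skipped"})
    rec["p_hat"] = p_hat
    rec["n_hat"] = n_hat
    rec = rec.dropna(subset=["p_hat"]).reset_index(drop=True)
    rec["t"] = arcsin_transform(rec["p_hat"].to_numpy(), mode=transform_mode)
    return rec[
        [
            "exon_id",
            "sample_id",
            "cell_type",
            "et_included",
            "et_skipped",
            "p_hat",
            "n_hat",
            "t",
        ]
    ]


def filter_no_alt_splicing(records: pd.DataFrame) -> pd.DataFrame:
    """Drop exon x cell-type groups with no evidence of alternative splicing.

    A group in which the exon is only ever fully included (all p_hat = 1) or
    only ever fully skipped (all p_hat = 0) — or that is empty — is removed.
    """
    def has_evidence(g: pd.DataFrame) -> bool:
        p = g["p_hat"]
        return len(p) > 0 and not (np.all(p == 1.0) or np.all(p == 0.0))

    keep = records.groupby(["exon_id", "cell_type"], sort=False).filter(has_evidence)
    return keep.reset_index(drop=True)


def summarize_exons(records: pd.DataFrame, min_samples: int = 3) -> pd.DataFrame:
    """Across-cell summary per exon x cell type.

    Sample mean and unbiased sample variance (denominator n-1) of p_hat and
    of the transformed inclusion t, plus mean total expression. Groups with
    fewer than ``min_samples`` cells are discarded.
    """
    grouped = records.groupby(["exon_id", "cell_type"])
    out = grouped.agg(
        n_samples=("p_hat", "size"),
        mean_p=("p_hat", "mean"),
        var_p=("p_hat", lambda s: s.var(ddof=1)),
        mean_t=("t", "mean"),
        var_t=("t", lambda s: s.var(ddof=1)),
        mean_expression=("n_hat", "mean"),
    ).reset_index()
    out = out[out["n_samples"] >= min_samples].reset_index(drop=True)
    return out.rename(columns={"cell_type": "condition"})


def binomial_variance_curve(p, n):
    """Expected Var(p_hat) = p(1-p)/n under the Bernoulli splicing model."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    v = p * (1.0 - p) / n
    return float(v) if v.ndim == 0 else v


def overdispersion_test(k, n):
    """Chi-square test of binomial dispersion of inclusion across samples.

    Null: each sample's included count k_r ~ Binomial(n_r, p_bar) with a
    common inclusion level p_bar = sum(k)/sum(n). The Pearson statistic
    sum_r (k_r - n_r p_bar)^2 / (n_r p_bar (1 - p_bar)) is referred to
    chi-square on R-1 df; small p-values indicate more across-sample
    variability than binomial sampling alone explains.

    Returns (statistic, df, p_value); all-NaN when p_bar is 0 or 1 (test
    undefined: no variability is possible under the null).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if k.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k_r <= n_r and n_r >= 1")
    p_bar = k.sum() / n.sum()
    if p_bar <= 0.0 or p_bar >= 1.0:
        return np.nan, k.size - 1, np.nan
    statistic = float(np.sum((k - n * p_bar) ** 2 / (n * p_bar * (1.0 - p_bar))))
    df = k.size - 1
    return statistic, df, float(stats.chi2.sf(statistic, df))
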