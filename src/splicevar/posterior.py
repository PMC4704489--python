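"""Propagating PSI-posterior uncertainty into across-cell variance.

Bayesian PSI inference from RNA-seq (MISO-style) yields, per cassette exon
and cell, S samples from the posterior of the inclusion level rather than a
point estimate. To carry that measurement uncertainty into the across-cell
variance of arcsine-transformed inclusion, each draw of the *variance
posterior* picks one transformed posterior sample per cell (with
replacement) and takes the unbiased sample variance across the R cells;
repeating many times gives posterior samples of the variance itself, which
are summarized by their mean and 95% credible interval, and over which the
gamma mixed model can be refit to obtain posterior distributions of its
coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inclusion import arcsin_transform

__all__ = [
    "PosteriorInclusionMatrix",
    "VariancePosterior",
    "draw_variance_posterior",
    "summarize_posterior",
    "fit_glmm_per_posterior",
]

MIN_CELLS = 3  # same minimum-sample rule as the qPCR branch


@dataclass
class PosteriorInclusionMatrix:
    """Cells x posterior draws of the inclusion level for one cassette exon."""

    exon_id: str
    cells: list[str]
    draws: np.ndarray  # shape (R cells, S draws), values in [0, 1]
    conditions: list[str] | None = None  # per-cell population label
    mean_expression: float = np.nan  # per-gene expression (e.g. mean FPKM)
    true_inclusion: np.ndarray | None = None  # synthetic ground truth, if any

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        r, s = self.draws.shape
        if r != len(self.cells):
            raise ValueError("draws rows must match the cell list")
        if s < 2:
            raise ValueError("need at least 2 posterior draws per cell")
        if np.any((self.draws < 0) | (self.draws > 1)):
            raise ValueError("posterior draws must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset(self, condition: str) -> "PosteriorInclusionMatrix":
        """Restrict to cells of one population."""
        if self.conditions is None:
            raise ValueError("matrix has no per-cell condition labels")
        idx = [i for i, c in enumerate(self.conditions) if c == condition]
        return PosteriorInclusionMatrix(
            exon_id=self.exon_id,
            cells=[self.cells[i] for i in idx],
            draws=self.draws[idx],
            conditions=[condition] * len(idx),
            mean_expression=self.mean_expression,
            true_inclusion=(
                self.true_inclusion[idx] if self.true_inclusion is not None else None
            ),
        )


@dataclass
class VariancePosterior:
    """Posterior samples of the across-cell variance of transformed inclusion."""

    exon_id: str
    samples: np.ndarray
    mean: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise ValueError("variance samples must be non-negative")
        self.mean = float(self.samples.mean())
        self.ci_low, self.ci_high = (
            float(np.quantile(self.samples, 0.025)),
            float(np.quantile(self.samples, 0.975)),
        )


def draw_variance_posterior(
    matrix: PosteriorInclusionMatrix,
    n_draws: int = 1000,
    rng: np.random.Generator | int | None = None,
    min_cells: int = MIN_CELLS,
) -> VariancePosterior | None:
    """Sample the posterior of the across-cell variance of arcsin(sqrt(p)).

    Each of the ``n_draws`` iterations picks, independently per cell and
    with replacement, one of that cell's S transformed posterior samples and
    computes the unbiased (R-1 denominator) sample variance across cells.
    Exons with fewer than ``min_cells`` cells (3 by default, the pipeline's
    minimum-sample rule) are skipped (returns None with a warning).
    """
    if matrix.n_cells < min_cells:
        warnings.warn(
            f"exon {matrix.exon_id}: fewer than {min_cells} cells, skipped"
        )
        return None
    rng = np.random.default_rng(rng)
    t = arcsin_transform(matrix.draws)  # (R, S)
    r, s = t.shape
    pick = rng.integers(0, s, size=(n_draws, r))
    chosen = t[np.arange(r)[None, :], pick]  # (n_draws, R)
    variances = chosen.var(axis=1, ddof=1)
    return VariancePosterior(exon_id=matrix.exon_id, samples=variances)


def summarize_posterior(vp: VariancePosterior) -> tuple[float, float, float]:
    """Posterior mean and central 95% credible interval of the variance."""
    if vp.samples.size < 2:
        raise ValueError("need at least 2 posterior samples")
    return vp.mean, vp.ci_low, vp.ci_high


def fit_glmm_per_posterior(
    matrices: list[PosteriorInclusionMatrix],
    conservation: pd.DataFrame,
    n_fits: int = 50,
    fixed=("score", "mean_expression", "condition"),
    rng: np.random.Generator | int | None = None,
    max_failure_rate: float = 0.2,
    by_condition: bool = True,
) -> pd.DataFrame:
    """Posterior distribution of gamma-model coefficients over variance draws.

    For each of ``n_fits`` posterior samples, a variance response is drawn
    for every exon x population (one transformed posterior sample per cell,
    unbiased variance across cells), the response table is assembled
    (continuous conservation ``score``, per-gene ``mean_expression``,
    population as ``condition``, weights = cells / mean cells) and the
    weighted gamma mixed model is refit. Returns one row per coefficient
    with the across-fit mean, SE and 95% credible interval.

    Individual fit failures are dropped with a warning; if more than
    ``max_failure_rate`` of fits fail, the run aborts.
    """
    from .glmm import fit_gamma_glmm

    rng = np.random.default_rng(rng)
    cons = conservation.drop_duplicates("exon_id").set_index("exon_id")

    units = []  # (exon_id, condition, transformed draws (R,S), mean_expr, score)
    for m in matrices:
        conds = (
            sorted(set(m.conditions))
            if (by_condition and m.conditions is not None)
            else [None]
        )
        for cond in conds:
            sub = m.subset(cond) if cond is not None else m
            if sub.n_cells < MIN_CELLS:
                continue
            if m.exon_id not in cons.index:
                raise ValueError(f"no conservation score for exon {m.exon_id}")
            units.append(
                (
                    m.exon_id,
                    cond if cond is not None else "all",
                    arcsin_transform(sub.draws),
                    sub.mean_expression,
                    float(cons.loc[m.exon_id, "score"]),
                    sub.n_cells,
                )
            )
    if not units:
        raise ValueError("no exon x population with enough cells")

    coef_draws: list[pd.Series] = []
    n_failed = 0
    for _ in range(n_fits):
        rows = []
        for exon_id, cond, t, expr, score, n_cells in units:
            r, s = t.shape
            pick = rng.integers(0, s, size=r)
            var = t[np.arange(r), pick].var(ddof=1)
            rows.append(
                {
                    "exon_id": exon_id,
                    "condition": cond,
                    "var_t": var,
                    "score": score,
                    "mean_expression": expr,
                    "n_samples": n_cells,
                }
            )
        tab = pd.DataFrame(rows)
        tab = tab[tab["var_t"] > 1e-12].reset_index(drop=True)
        tab["weight"] = tab["n_samples"] / tab["n_samples"].mean()
        use_fixed = [
            f for f in fixed if f != "condition" or tab["condition"].nunique() > 1
        ]
        try:
            fit = fit_gamma_glmm(tab, fixed=use_fixed, compute_se=False)
            coef_draws.append(fit.params)
        except Exception as exc:  # noqa: BLE001 — individual fits may fail
            n_failed += 1
            warnings.warn(f"posterior fit failed and was dropped: {exc}")
    if n_failed > max_failure_rate * n_fits:
        raise RuntimeError(
            f"{n_failed}/{n_fits} posterior fits failed (> {max_failure_rate:.0%})"
        )
    coefs = pd.DataFrame(coef_draws)
    out = pd.DataFrame(
        {
            "coef_mean": coefs.mean(),
            "coef_se": coefs.std(ddof=1),
            "ci_low": coefs.quantile(0.025),
            "ci_high": coefs.quantile(0.975),
            "n_fits": len(coefs),
        }
    )
    out.index.name = "coefficient"
    return out
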