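"""Synthetic single-cell splicing data with the statistical structure the
analysis assumes.

Three generators stand in for the study's data sources:

* :func:`generate_qpcr_plate` — a microfluidic single-cell RT-qPCR plate:
  per cell and cassette exon, a total isoform-molecule count ``n`` is drawn
  from a configurable expression model, a per-cell *dispersed* inclusion
  level ``u`` uniformly from ``[max(pi - delta, 0), min(pi + delta, 1)]``,
  and the included count ``k ~ Binomial(n, u)``. Wells report
  ``Ct = Cmax - Et`` with ``Et = log2(count + 1)`` plus log2-scale Gaussian
  technical noise; wells below a detection threshold are emitted at
  ``Ct = Cmax`` (non-detect).
* :func:`generate_control_plate` — technical replicates of diluted bulk
  RNA: one fixed inclusion level per exon (no cell-to-cell dispersion),
  reduced expression, so only binomial sampling and technical noise remain.
* :func:`generate_conservation_profiles` — per-exon flanking-intronic-region
  (FIR) position-wise conservation scores in [0,1]: right-skewed across
  exons, upstream/downstream correlated through a shared per-exon latent
  level, with the "conserved" group occupying the upper tail.
* :func:`generate_posterior_inclusion` — Beta-shaped per-cell PSI posteriors
  (the shape of Bayesian PSI inference output from RNA-seq), narrower at
  higher read depth, plus a per-gene expression level.

Every generator is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "QpcrPlate",
    "SyntheticTruth",
    "generate_qpcr_plate",
    "generate_control_plate",
    "generate_conservation_profiles",
    "generate_posterior_inclusion",
]

PLATE_COLUMNS = [
    "sample_id",
    "assay_id",
    "isoform_role",
    "Ct",
    "ct_quality",
    "peak_ratio",
    "cell_type",
]

HOUSEKEEPING_GENES = ("GAPDH", "RPS13", "RPL29")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for all synthetic generators.

    Defaults mirror the scale of the single-cell assay being emulated:
    two groups of 22 cassette exons, three cell types, 27 cells each,
    Cmax = 30 cycles, per-exon dispersion delta uniform on [0.01, 0.05].
    """

    n_exons_per_group: int = 22
    group_labels: tuple[str, str] = ("conserved", "non_conserved")
    n_cells_per_condition: int = 27
    conditions: tuple[str, ...] = ("293T", "MCF7", "U937")
    pi_range: tuple[float, float] = (0.0, 1.0)
    delta_range: tuple[float, float] = (0.01, 0.05)
    # total isoform-molecule count per cell x exon; log-normal with natural-log
    # parameters (median exp(mu) ~ 1100 molecules, spanning ~1e2..1e5)
    expression_model: dict = field(
        default_factory=lambda: {"family": "lognormal", "mu": 7.0, "sigma": 1.5}
    )
    technical_noise_sd: float = 0.25  # log2-scale (cycles) noise on Et
    dropout_et_threshold: float = 1.0  # Et below this emitted at Ct = Cmax
    conservation_model: dict = field(
        default_factory=lambda: {
            "a": 1.2,
            "b": 3.0,
            "kappa": 8.0,
            "side_sd": 0.05,
            "fir_length": 200,
        }
    )
    c_max: float = 30.0
    # PSI-posterior branch: pseudo read depth (Beta concentration) and draws
    posterior_depth: float = 50.0
    posterior_draws: int = 100
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pi_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("pi_range must be an interval inside [0, 1]")
        dlo, dhi = self.delta_range
        if not (0.0 <= dlo <= dhi <= 0.5):
            raise ValueError("delta_range must be an interval inside [0, 0.5]")
        if self.n_exons_per_group < 1 or self.n_cells_per_condition < 1:
            raise ValueError("counts must be >= 1")
        if self.technical_noise_sd < 0:
            raise ValueError("technical_noise_sd must be non-negative")
        if len(self.group_labels) != 2:
            raise ValueError("exactly two group labels are required")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with fields replaced."""
        return replace(self, **kwargs)


@dataclass
class QpcrPlate:
    """Tidy per-well Ct measurements with quality metadata.

    ``wells`` columns: sample_id, assay_id, isoform_role in
    {included, skipped, hkg}, Ct, ct_quality, peak_ratio, cell_type.
    ``Ct = c_max`` encodes non-detection.
    """

    wells: pd.DataFrame
    c_max: float = 30.0

    def __post_init__(self) -> None:
        missing = set(PLATE_COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate is missing columns: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.wells["sample_id"].unique())

    def subset_samples(self, sample_ids: Sequence[str]) -> "QpcrPlate":
        keep = self.wells["sample_id"].isin(set(sample_ids))
        return QpcrPlate(self.wells.loc[keep].reset_index(drop=True), self.c_max)


@dataclass
class SyntheticTruth:
    """Ground truth paired with a generated plate.

    ``exons``: exon_id, group, pi (true inclusion), delta (dispersion).
    ``counts``: sample_id, cell_type, exon_id, u (dispersed inclusion),
    n (total molecules), k (included molecules).
    """

    exons: pd.DataFrame
    counts: pd.DataFrame


def _draw_counts(model: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw integer total-molecule counts from a distribution spec."""
    family = model.get("family", "lognormal")
    if family == "lognormal":
        raw = rng.lognormal(model.get("mu", 7.0), model.get("sigma", 1.5), size)
        counts = np.rint(raw)
    elif family == "fixed":
        counts = np.full(size, float(model["n"]))
    elif family == "loguniform":
        lo, hi = math.log(model["low"]), math.log(model["high"])
        counts = np.rint(np.exp(rng.uniform(lo, hi, size)))
    elif family == "poisson":
        counts = rng.poisson(model["lam"], size).astype(float)
    else:
        raise ValueError(f"unknown expression model family: {family!r}")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or np.any(counts != np.rint(counts)):
        raise ValueError("expression model produced negative or non-integer counts")
    return np.maximum(counts, 1.0).astype(np.int64)


def _exon_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = 2 * config.n_exons_per_group
    ids = [f"EX{i + 1:03d}" for i in range(n)]
    groups = [config.group_labels[0]] * config.n_exons_per_group + [
        config.group_labels[1]
    ] * config.n_exons_per_group
    pi = rng.uniform(*config.pi_range, n)
    delta = rng.uniform(*config.delta_range, n)
    return pd.DataFrame({"exon_id": ids, "group": groups, "pi": pi, "delta": delta})


def _dispersed_inclusion(
    pi: np.ndarray, delta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    lo = np.maximum(pi - delta, 0.0)
    hi = np.minimum(pi + delta, 1.0)
    return rng.uniform(lo, hi)


def _emit_wells(
    sample_id: str,
    cell_type: str,
    exon_ids: Sequence[str],
    k: np.ndarray,
    n: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Convert per-exon counts to included/skipped wells on the Ct scale."""
    rows = []
    for exon, ki, ni in zip(exon_ids, k, n):
        for role, count in (("included", ki), ("skipped", ni - ki)):
            et = math.log2(count + 1.0)
            if config.technical_noise_sd > 0:
                et += rng.normal(0.0, config.technical_noise_sd)
            et = min(max(et, 0.0), config.c_max)
            if et < config.dropout_et_threshold:
                et = 0.0  # non-detect: Ct = Cmax
            rows.append(
                {
                    "sample_id": sample_id,
                    "assay_id": f"{exon}:{'inc' if role == 'included' else 'skp'}",
                    "isoform_role": role,
                    "Ct": config.c_max - et,
                    "ct_quality": rng.uniform(0.85, 1.0),
                    "peak_ratio": rng.uniform(0.9, 1.0),
                    "cell_type": cell_type,
                }
            )
    return rows


def _emit_hkg_wells(
    sample_id: str, cell_type: str, config: SimulationConfig, rng: np.random.Generator
) -> list[dict]:
    rows = []
    for hkg in HOUSEKEEPING_GENES:
        count = float(_draw_counts(config.expression_model, 1, rng)[0])
        et = math.log2(count + 1.0)
        if config.technical_noise_sd > 0:
            et += rng.normal(0.0, config.technical_noise_sd)
        et = min(max(et, 0.0), config.c_max)
        rows.append(
            {
                "sample_id": sample_id,
                "assay_id": f"{hkg}:hkg",
                "isoform_role": "hkg",
                "Ct": config.c_max - et,
                "ct_quality": rng.uniform(0.85, 1.0),
                "peak_ratio": rng.uniform(0.9, 1.0),
                "cell_type": cell_type,
            }
        )
    return rows


def generate_qpcr_plate(config: SimulationConfig) -> tuple[QpcrPlate, SyntheticTruth]:
    """Simulate a single-cell RT-qPCR plate and its ground truth.

    Per exon, the true inclusion level pi and dispersion delta are drawn once;
    per cell, the realized inclusion u is uniform on
    [max(pi-delta, 0), min(pi+delta, 1)] and the included count is
    Binomial(n, u) with n from the expression model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    exons = _exon_table(config, rng)
    well_rows: list[dict] = []
    count_rows: list[dict] = []
    pi = exons["pi"].to_numpy()
    delta = exons["delta"].to_numpy()
    for cond in config.conditions:
        for c in range(config.n_cells_per_condition):
            sample_id = f"{cond}_c{c + 1:02d}"
            n = _draw_counts(config.expression_model, len(exons), rng)
            u = _dispersed_inclusion(pi, delta, rng)
            k = rng.binomial(n, u)
            well_rows.extend(
                _emit_wells(sample_id, cond, exons["exon_id"], k, n, config, rng)
            )
            well_rows.extend(_emit_hkg_wells(sample_id, cond, config, rng))
            for exon, ui, ni, ki in zip(exons["exon_id"], u, n, k):
                count_rows.append(
                    {
                        "sample_id": sample_id,
                        "cell_type": cond,
                        "exon_id": exon,
                        "u": ui,
                        "n": int(ni),
                        "k": int(ki),
                    }
                )
    plate = QpcrPlate(pd.DataFrame(well_rows, columns=PLATE_COLUMNS), config.c_max)
    truth = SyntheticTruth(exons=exons, counts=pd.DataFrame(count_rows))
    return plate, truth


def generate_control_plate(
    config: SimulationConfig,
    expression_scale: float = 0.1,
    pi: pd.Series | None = None,
) -> tuple[QpcrPlate, SyntheticTruth]:
    """Simulate the diluted-bulk control experiment.

    Replicates of one condition share a single fixed inclusion level per exon
    (delta forced to 0), with total counts scaled down by ``expression_scale``
    relative to the single-cell expression model — only binomial sampling and
    technical noise remain as sources of variation. Pass ``pi`` (indexed by
    exon_id) to reuse the inclusion levels of a paired single-cell plate.
    """
    config.validate()
    if not (0 < expression_scale):
        raise ValueError("expression_scale must be positive")
    rng = np.random.default_rng(config.seed + 1)
    exons = _exon_table(config, rng)
    exons["delta"] = 0.0
    if pi is not None:
        exons["pi"] = exons["exon_id"].map(pi).to_numpy()
        if exons["pi"].isna().any():
            raise ValueError("pi override does not cover all exons")
    well_rows: list[dict] = []
    count_rows: list[dict] = []
    p = exons["pi"].to_numpy()
    for cond in config.conditions:
        for r in range(config.n_cells_per_condition):
            sample_id = f"ctrl_{cond}_r{r + 1:02d}"
            n = _draw_counts(config.expression_model, len(exons), rng)
            n = np.maximum(np.rint(n * expression_scale), 1.0).astype(np.int64)
            k = rng.binomial(n, p)
            well_rows.extend(
                _emit_wells(sample_id, cond, exons["exon_id"], k, n, config, rng)
            )
            well_rows.extend(_emit_hkg_wells(sample_id, cond, config, rng))
            for exon, pi_i, ni, ki in zip(exons["exon_id"], p, n, k):
                count_rows.append(
                    {
                        "sample_id": sample_id,
                        "cell_type": cond,
                        "exon_id": exon,
                        "u": pi_i,
                        "n": int(ni),
                        "k": int(ki),
                    }
                )
    plate = QpcrPlate(pd.DataFrame(well_rows, columns=PLATE_COLUMNS), config.c_max)
    return plate, SyntheticTruth(exons=exons, counts=pd.DataFrame(count_rows))


def generate_conservation_profiles(config: SimulationConfig) -> pd.DataFrame:
    """Per-exon FIR position-wise conservation scores.

    A per-exon latent conservation level m is Beta(a, b)-distributed
    (right-skewed for a < b); the conserved group occupies the upper half of
    the latent distribution. Upstream and downstream side means are the
    shared m plus independent Gaussian jitter (``side_sd``), which induces
    the positive up/down correlation; position scores are Beta-distributed
    around the side mean with concentration ``kappa``.

    Returns a long-format frame: exon_id, group, side in {up, down},
    position (0-based), score.
    """
    config.validate()
    cm = config.conservation_model
    a, b = cm.get("a", 1.2), cm.get("b", 3.0)
    kappa = cm.get("kappa", 8.0)
    side_sd = cm.get("side_sd", 0.05)
    fir_length = int(cm.get("fir_length", 200))
    if not (1 <= fir_length <= 200):
        raise ValueError("fir_length must be in [1, 200]")
    rng = np.random.default_rng(config.seed + 2)
    from scipy import stats as _st

    n_group = config.n_exons_per_group
    # conserved exons sample the upper half of the latent Beta distribution
    u = np.concatenate(
        [rng.uniform(0.5, 1.0, n_group), rng.uniform(0.0, 0.5, n_group)]
    )
    m = _st.beta.ppf(u, a, b)
    exon_ids = [f"EX{i + 1:03d}" for i in range(2 * n_group)]
    groups = [config.group_labels[0]] * n_group + [config.group_labels[1]] * n_group
    frames = []
    eps = 1e-4
    for exon, grp, mi in zip(exon_ids, groups, m):
        for side in ("up", "down"):
            ms = float(np.clip(mi + rng.normal(0.0, side_sd), eps, 1 - eps))
            scores = rng.beta(ms * kappa, (1.0 - ms) * kappa, fir_length)
            frames.append(
                pd.DataFrame(
                    {
                        "exon_id": exon,
                        "group": grp,
                        "side": side,
                        "position": np.arange(fir_length),
                        "score": scores,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_posterior_inclusion(config: SimulationConfig) -> list:
    """Beta-shaped per-cell PSI posteriors for every exon (RNA-seq branch).

    For each cell the posterior is Beta(u*d, (1-u)*d) around the cell's
    dispersed inclusion u with pseudo-depth d = ``posterior_depth``; its mean
    is exactly u and its variance u(1-u)/(d+1), so deeper depth gives a
    narrower posterior. Cells with u of exactly 0 or 1 get a degenerate
    posterior. Returns a list of
    :class:`splicevar.posterior.PosteriorInclusionMatrix`.
    """
    from .posterior import PosteriorInclusionMatrix

    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    exons = _exon_table(config, rng)
    s = int(config.posterior_draws)
    d = float(config.posterior_depth)
    matrices = []
    cell_ids = []
    cell_conditions = []
    for cond in config.conditions:
        for c in range(config.n_cells_per_condition):
            cell_ids.append(f"{cond}_c{c + 1:02d}")
            cell_conditions.append(cond)
    for _, row in exons.iterrows():
        u = _dispersed_inclusion(
            np.full(len(cell_ids), row["pi"]),
            np.full(len(cell_ids), row["delta"]),
            rng,
        )
        draws = np.empty((len(cell_ids), s))
        for i, ui in enumerate(u):
            if ui <= 0.0 or ui >= 1.0:
                draws[i] = ui
            else:
                draws[i] = rng.beta(ui * d, (1.0 - ui) * d, s)
        matrices.append(
            PosteriorInclusionMatrix(
                exon_id=row["exon_id"],
                cells=list(cell_ids),
                draws=draws,
                conditions=list(cell_conditions),
                mean_expression=float(rng.lognormal(2.5, 1.0)),
                true_inclusion=u,
            )
        )
    return matrices
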