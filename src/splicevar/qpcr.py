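"""Quality filtering of single-cell RT-qPCR plates and Ct-to-Et conversion.

The filtering cascade, applied in order:

1. :func:`filter_failed_wells` — drop wells whose Ct call failed software QC
   (Ct quality must exceed 0.65 and melt-peak ratio 0.8, strictly).
2. :func:`failure_scores` + :func:`remove_failed_samples` — flag single-cell
   cDNA samples with amplification failure. An assay detected in most cells
   but undetected in one cell penalizes that cell by the assay's detection
   frequency; a cell accumulating an outlying total penalty S_r is removed.
3. :func:`detect_lod` — per assay, find the limit of detection: expression
   indices Et = Cmax - Ct at or below 8 cycles may be noise, so candidate
   LODs sweep upward from the lowest observed Et and Grubbs-flagged low
   outliers are removed.
4. :func:`select_samples_by_hkg` — keep the cells whose housekeeping-gene
   expression sits closest to the across-cell median (even cDNA yield).

``Ct = Cmax`` encodes non-detection throughout; after filtering such wells
count as zero expression (Et = 0), not as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outliers import grubbs_test, iterative_grubbs
from .synthetic import QpcrPlate

__all__ = [
    "SampleQc",
    "PreprocessResult",
    "filter_failed_wells",
    "compute_et",
    "failure_scores",
    "remove_failed_samples",
    "detect_lod",
    "select_samples_by_hkg",
    "preprocess_plate",
]

CT_QUALITY_MIN = 0.65  # strict: quality must be > 0.65
PEAK_RATIO_MIN = 0.8  # strict: peak ratio must be > 0.8
ET_LOD_CEILING = 8.0  # Et values at or below this may not be reliable


@dataclass(frozen=True)
class SampleQc:
    """Failure-of-expression score for one cDNA sample."""

    sample_id: str
    s_r: float
    retained: bool = True


@dataclass
class PreprocessResult:
    """A filtered plate plus a log of every removal with its rule."""

    plate: QpcrPlate
    sample_qc: pd.DataFrame  # sample_id, S_r, retained, removal_reason
    lod_per_assay: pd.DataFrame  # assay_id, lod, n_removed
    removals: list = field(default_factory=list)  # (rule, detail) tuples


def filter_failed_wells(plate: QpcrPlate) -> QpcrPlate:
    """Drop wells the Ct-calling software would mark failed.

    Retained wells must have ct_quality strictly above 0.65 and melt-peak
    ratio strictly above 0.8.
    """
    wells = plate.wells
    for col in ("ct_quality", "peak_ratio"):
        if wells[col].isna().any():
            bad = wells.loc[wells[col].isna()].iloc[0]
            raise ValueError(
                f"well {bad['sample_id']}/{bad['assay_id']} is missing {col}"
            )
    keep = (wells["ct_quality"] > CT_QUALITY_MIN) & (
        wells["peak_ratio"] > PEAK_RATIO_MIN
    )
    return QpcrPlate(wells.loc[keep].reset_index(drop=True), plate.c_max)


def compute_et(ct, c_max: float = 30.0):
    """Expression index Et = Cmax - Ct (cycles below the cycle ceiling)."""
    ct = np.asarray(ct, dtype=float)
    if np.any(ct > c_max):
        raise ValueError(f"Ct above Cmax={c_max}: non-detection must be coded as Cmax")
    et = c_max - ct
    return float(et) if et.ndim == 0 else et


def failure_scores(plate: QpcrPlate) -> list[SampleQc]:
    """Failure-of-expression score S_r per single-cell cDNA sample.

    For assay x and sample r, I_{x,r} = 1 if Ct < Cmax (detected) else 0;
    the assay's detection frequency is I_x = sum_r I_{x,r} / R. Each
    undetected well is penalized by its assay's detection frequency,
    s_{x,r} = I_x if Ct = Cmax else 0, and S_r = sum_x s_{x,r}: a sample in
    which commonly detected assays fail scores high.

    Housekeeping wells participate like any other assay.
    """
    wells = plate.wells
    detected = wells["Ct"] < plate.c_max
    i_x = detected.groupby(wells["assay_id"]).mean()
    penalty = np.where(detected, 0.0, wells["assay_id"].map(i_x))
    s_r = pd.Series(penalty, index=wells.index).groupby(wells["sample_id"]).sum()
    return [SampleQc(sid, float(val)) for sid, val in s_r.sort_index().items()]


def remove_failed_samples(
    qc: list[SampleQc], alpha: float = 0.05, method: str = "grubbs"
) -> tuple[list[str], list[SampleQc]]:
    """Samples whose S_r is a significant upper outlier are removed.

    Iterated one-sided (upper) Grubbs test at ``alpha``. Returns the retained
    sample ids and the QC records with ``retained`` updated.
    """
    if method != "grubbs":
        raise ValueError(f"unknown method {method!r}")
    if len(qc) < 3:
        raise ValueError("need at least 3 samples for outlier screening")
    scores = np.array([q.s_r for q in qc])
    removed_idx = set(iterative_grubbs(scores, alpha=alpha, alternative="max"))
    updated = [
        SampleQc(q.sample_id, q.s_r, retained=(i not in removed_idx))
        for i, q in enumerate(qc)
    ]
    retained = [q.sample_id for q in updated if q.retained]
    return retained, updated


def detect_lod(
    et_values,
    sample_ids=None,
    et_ceiling: float = ET_LOD_CEILING,
    alpha: float = 0.05,
):
    """Limit of detection for one assay by iterative Grubbs screening.

    Candidate LODs sweep the sorted observed Et values up to ``et_ceiling``
    in ascending order; at each step any value at or below the candidate
    that Grubbs flags as a significant *low* outlier of the remaining
    distribution is removed. Returns ``(lod, removed_sample_ids)`` where
    ``lod`` is the largest removed Et (None if nothing was removed).

    Fewer than 3 values: the assay cannot be screened, returns (None, []).
    """
    et = np.asarray(et_values, dtype=float)
    if sample_ids is None:
        sample_ids = list(range(et.size))
    sample_ids = list(sample_ids)
    if et.size < 3:
        return None, []
    live = np.arange(et.size)
    removed: list[int] = []
    lod = None
    candidates = np.unique(et[et <= et_ceiling])
    for cand in candidates:
        while live.size >= 3:
            res = grubbs_test(et[live], alpha=alpha, alternative="min")
            if not (res.is_outlier and et[live][res.index] <= cand):
                break
            removed.append(int(live[res.index]))
            lod = max(lod, et[live][res.index]) if lod is not None else et[live][res.index]
            live = np.delete(live, res.index)
    return (float(lod) if lod is not None else None), [sample_ids[i] for i in removed]


def select_samples_by_hkg(hkg_expression: pd.DataFrame, k: int) -> list[str]:
    """Keep the k samples with the most even housekeeping-gene expression.

    ``hkg_expression``: samples x genes (rows indexed by sample_id). Per gene
    the across-sample median is taken; each sample is scored by its maximal
    absolute deviation from the medians over genes, and the k smallest win.
    Ties are broken by sample_id order.
    """
    if k > len(hkg_expression):
        raise ValueError(f"k={k} exceeds the number of samples ({len(hkg_expression)})")
    if hkg_expression.shape[1] < 1:
        raise ValueError("need at least one housekeeping gene")
    medians = hkg_expression.median(axis=0)
    max_dist = (hkg_expression - medians).abs().max(axis=1)
    order = max_dist.to_frame("d").reset_index(names="sample_id")
    order = order.sort_values(["d", "sample_id"], kind="mergesort")
    return order["sample_id"].head(k).tolist()


def _hkg_expression_table(plate: QpcrPlate) -> pd.DataFrame:
    hkg = plate.wells[plate.wells["isoform_role"] == "hkg"]
    et = compute_et(hkg["Ct"].to_numpy(), plate.c_max)
    tab = hkg.assign(et=et).pivot_table(
        index="sample_id", columns="assay_id", values="et", aggfunc="mean"
    )
    return tab.fillna(0.0)


def preprocess_plate(
    plate: QpcrPlate,
    alpha: float = 0.05,
    et_ceiling: float = ET_LOD_CEILING,
    hkg_top_k: int | None = None,
    per_cell_type: bool = True,
) -> PreprocessResult:
    """Run the full filtering cascade on a plate.

    Order: failed wells -> HKG-based sample selection (if ``hkg_top_k``)
    -> failure-of-expression screening -> per-assay LOD screening. The
    failure score and LOD are computed within each cell type when
    ``per_cell_type`` (each cell type was assayed on its own array).
    """
    removals: list = []
    plate = filter_failed_wells(plate)

    if hkg_top_k is not None:
        kept: list[str] = []
        for _, sub in plate.wells.groupby("cell_type"):
            tab = _hkg_expression_table(QpcrPlate(sub.reset_index(drop=True), plate.c_max))
            kept.extend(select_samples_by_hkg(tab, min(hkg_top_k, len(tab))))
        dropped = set(plate.sample_ids) - set(kept)
        for sid in sorted(dropped):
            removals.append(("hkg_selection", sid))
        plate = plate.subset_samples(kept)

    groups = (
        [g for _, g in plate.wells.groupby("cell_type")]
        if per_cell_type
        else [plate.wells]
    )
    qc_rows = []
    retained_all: list[str] = []
    for sub in groups:
        sub_plate = QpcrPlate(sub.reset_index(drop=True), plate.c_max)
        qc = failure_scores(sub_plate)
        if len(qc) >= 3:
            retained, qc = remove_failed_samples(qc, alpha=alpha)
        else:
            retained = [q.sample_id for q in qc]
        retained_all.extend(retained)
        for q in qc:
            qc_rows.append(
                {
                    "sample_id": q.sample_id,
                    "S_r": q.s_r,
                    "retained": q.retained,
                    "removal_reason": "" if q.retained else "failure_score",
                }
            )
            if not q.retained:
                removals.append(("failure_score", q.sample_id))
    plate = plate.subset_samples(retained_all)

    lod_rows = []
    drop_wells = set()
    wells = plate.wells
    group_cols = ["cell_type", "assay_id"] if per_cell_type else ["assay_id"]
    for key, sub in wells[wells["isoform_role"] != "hkg"].groupby(group_cols):
        detected = sub[sub["Ct"] < plate.c_max]
        if len(detected) < 3:
            continue
        et = compute_et(detected["Ct"].to_numpy(), plate.c_max)
        lod, removed = detect_lod(
            et, detected["sample_id"].tolist(), et_ceiling=et_ceiling, alpha=alpha
        )
        assay = key[-1] if isinstance(key, tuple) else key
        lod_rows.append({"assay_id": assay, "lod": lod, "n_removed": len(removed)})
        if removed:
            idx = detected.index[detected["sample_id"].isin(set(removed))]
            drop_wells.update(idx)
            for sid in removed:
                removals.append(("lod", f"{assay}:{sid}"))
    plate = QpcrPlate(wells.drop(index=list(drop_wells)).reset_index(drop=True), plate.c_max)

    return PreprocessResult(
        plate=plate,
        sample_qc=pd.DataFrame(
            qc_rows, columns=["sample_id", "S_r", "retained", "removal_reason"]
        ),
        lod_per_assay=pd.DataFrame(lod_rows, columns=["assay_id", "lod", "n_removed"]),
        removals=removals,
    )
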