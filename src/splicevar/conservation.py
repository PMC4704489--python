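"""Evolutionary conservation of cassette-exon flanking intronic regions.

Each cassette exon carries up to 200 bp of flanking intron on each side
(FIRs, taken in transcript orientation: on the minus strand the genomic
downstream interval is the transcript-upstream FIR). Per-position
conservation scores in [0,1] (phastCons-style) are averaged per side after
masking positions that overlap protein-coding regions of other transcripts;
exons with more than 100 bp of coding overlap on either side are excluded
outright. Exons are then ranked by combined (mean of the two sides)
conservation to define conserved / non-conserved groups.

Intervals are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CassetteExon",
    "apply_coding_overlap_filter",
    "score_fir",
    "summarize_conservation",
    "correlate_fir",
    "assign_groups",
]

MAX_FIR_LENGTH = 200
MAX_CODING_OVERLAP = 100  # more than this on either side excludes the exon


@dataclass(frozen=True)
class CassetteExon:
    """A cassette exon with its flanking intronic regions.

    ``upstream_fir``/``downstream_fir`` are genomic 0-based half-open
    intervals in *transcript* orientation: for a minus-strand exon the
    transcript-upstream FIR lies genomically downstream of the exon body.
    If omitted they default to the (up to) 200 bp immediately flanking the
    exon, clipped at position 0.
    """

    exon_id: str
    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    upstream_fir: tuple[int, int] = field(default=None)  # type: ignore[assignment]
    downstream_fir: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.start < self.end:
            raise ValueError("require start < end")
        left = (max(self.start - MAX_FIR_LENGTH, 0), self.start)
        right = (self.end, self.end + MAX_FIR_LENGTH)
        up, down = (left, right) if self.strand == "+" else (right, left)
        if self.upstream_fir is None:
            object.__setattr__(self, "upstream_fir", up)
        if self.downstream_fir is None:
            object.__setattr__(self, "downstream_fir", down)
        for name in ("upstream_fir", "downstream_fir"):
            s, e = getattr(self, name)
            if not (1 <= e - s <= MAX_FIR_LENGTH):
                raise ValueError(f"{name} length must be in [1, {MAX_FIR_LENGTH}]")
            if s < self.end and e > self.start:
                raise ValueError(f"{name} overlaps the exon body")


def _masked_positions(fir: tuple[int, int], coding) -> set[int]:
    s, e = fir
    masked: set[int] = set()
    for iv in coding:
        cs, ce = int(iv[0]), int(iv[1])
        if cs > ce:
            raise ValueError(f"malformed coding interval ({cs}, {ce})")
        lo, hi = max(s, cs), min(e, ce)
        if lo < hi:
            masked.update(range(lo, hi))
    return masked


def apply_coding_overlap_filter(
    exon: CassetteExon, coding_intervals
) -> tuple[bool, set[int], set[int]]:
    """Mask FIR positions overlapping coding regions; exclude heavy overlap.

    Returns ``(kept, masked_up, masked_down)`` with masked positions as
    genomic coordinates. The exon is kept only if the masked count is at
    most 100 on both sides (exactly 100 is still kept).
    """
    masked_up = _masked_positions(exon.upstream_fir, coding_intervals)
    masked_down = _masked_positions(exon.downstream_fir, coding_intervals)
    kept = len(masked_up) <= MAX_CODING_OVERLAP and len(masked_down) <= MAX_CODING_OVERLAP
    return kept, masked_up, masked_down


def score_fir(
    exon: CassetteExon,
    position_scores: dict[int, float],
    masked_up: set[int] = frozenset(),
    masked_down: set[int] = frozenset(),
) -> dict:
    """Per-side mean conservation over unmasked, scored FIR positions.

    ``position_scores`` maps genomic position to a score in [0,1]; positions
    without a score are treated as masked (excluded from the mean), never as
    zero. A side with no scored position yields a NaN mean.
    """
    out = {"exon_id": exon.exon_id}
    for side, fir, masked in (
        ("up", exon.upstream_fir, masked_up),
        ("down", exon.downstream_fir, masked_down),
    ):
        vals = []
        n_unscored = 0
        for pos in range(fir[0], fir[1]):
            if pos in masked:
                continue
            score = position_scores.get(pos)
            if score is None:
                n_unscored += 1
                continue
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"conservation score out of [0,1] at {pos}: {score}")
            vals.append(score)
        out[f"{side}stream_mean"] = float(np.mean(vals)) if vals else np.nan
        out[f"n_scored_positions_{side}"] = len(vals)
        out[f"masked_{side}"] = len(masked) + n_unscored
    out["group"] = "unassigned"
    return out


def summarize_conservation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Conservation summaries from a long-format profile table.

    ``profiles`` columns: exon_id, side in {up, down}, position, score
    (the synthetic generator's format). Returns one row per exon with
    upstream/downstream means and scored-position counts.
    """
    bad = ~profiles["score"].between(0.0, 1.0)
    if bad.any():
        raise ValueError("conservation scores outside [0,1]")
    agg = (
        profiles.groupby(["exon_id", "side"])["score"]
        .agg(["mean", "size"])
        .unstack("side")
    )
    out = pd.DataFrame(
        {
            "exon_id": agg.index,
            "upstream_mean": agg[("mean", "up")].to_numpy(),
            "downstream_mean": agg[("mean", "down")].to_numpy(),
            "n_scored_positions_up": agg[("size", "up")].fillna(0).astype(int).to_numpy(),
            "n_scored_positions_down": agg[("size", "down")].fillna(0).astype(int).to_numpy(),
        }
    ).reset_index(drop=True)
    out["masked_up"] = 0
    out["masked_down"] = 0
    out["group"] = "unassigned"
    return out


def correlate_fir(summaries: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between upstream and downstream mean conservation."""
    ok = summaries.dropna(subset=["upstream_mean", "downstream_mean"])
    if len(ok) < 3:
        raise ValueError("need at least 3 exons with both FIR means defined")
    rho, p = stats.spearmanr(ok["upstream_mean"], ok["downstream_mean"])
    return float(rho), float(p)


def assign_groups(
    summaries: pd.DataFrame, k_per_group: int, strategy: str = "tails"
) -> pd.DataFrame:
    """Label the top/bottom ``k_per_group`` exons by combined conservation.

    Combined conservation is the unweighted mean of the upstream and
    downstream means. The top k become 'conserved', the bottom k
    'non_conserved', the rest 'unassigned'; ties are broken by exon_id
    lexicographic order so the labelling is deterministic.
    """
    if strategy != "tails":
        raise ValueError(f"unknown strategy {strategy!r}")
    ok = summaries.dropna(subset=["upstream_mean", "downstream_mean"])
    if 2 * k_per_group > len(ok):
        raise ValueError("k_per_group must be at most half the scored exons")
    combined = (ok["upstream_mean"] + ok["downstream_mean"]) / 2.0
    ranked = ok.assign(_c=combined)
    top = ranked.sort_values(["_c", "exon_id"], ascending=[False, True], kind="mergesort")
    conserved = set(top["exon_id"].head(k_per_group))
    bottom = ranked.loc[~ranked["exon_id"].isin(conserved)].sort_values(
        ["_c", "exon_id"], ascending=[True, True], kind="mergesort"
    )
    non_conserved = set(bottom["exon_id"].head(k_per_group))
    out = summaries.copy()
    out["group"] = np.select(
        [out["exon_id"].isin(conserved), out["exon_id"].isin(non_conserved)],
        ["conserved", "non_conserved"],
        default="unassigned",
    )
    return out
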