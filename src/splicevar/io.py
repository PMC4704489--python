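"""Tidy TSV readers/writers for every table the pipeline exchanges.

All on-disk formats are plain tab-separated text:

* plates — sample_id, assay_id, isoform_role, Ct, ct_quality, peak_ratio,
  cell_type (``Ct = Cmax`` encodes non-detection);
* conservation profiles — exon_id, side in {up, down}, position, score;
* posterior matrices — exon_id, cell_id, draw_index, psi (long format),
  with per-cell condition and per-gene expression in a companion table;
* generic frames (truth, summaries, responses, QC reports) round-trip via
  :func:`read_table` / :func:`write_table`.

Configs are YAML mappings of :class:`~splicevar.synthetic.SimulationConfig`
fields; the seed must always be explicit in the file.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml

from .posterior import PosteriorInclusionMatrix
from .synthetic import PLATE_COLUMNS, QpcrPlate, SimulationConfig

__all__ = [
    "read_plate",
    "write_plate",
    "read_config",
    "write_config",
    "read_posterior_matrices",
    "write_posterior_matrices",
    "read_table",
    "write_table",
]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_plate(plate: QpcrPlate, path) -> None:
    write_table(plate.wells[PLATE_COLUMNS], path)


def read_plate(path, c_max: float = 30.0) -> QpcrPlate:
    return QpcrPlate(read_table(path), c_max=c_max)


def write_config(config: SimulationConfig, path) -> None:
    data = {f.name: getattr(config, f.name) for f in dc_fields(config)}
    # tuples serialize as lists; normalized back on read
    data = {
        k: list(v) if isinstance(v, tuple) else v for k, v in data.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_config(path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "seed" not in data:
        raise ValueError("config file must state the seed explicitly")
    kwargs = {}
    for f in dc_fields(SimulationConfig):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def write_posterior_matrices(matrices, draws_path, cells_path) -> None:
    """Long-format draws plus a per-exon/cell metadata table."""
    draw_rows = []
    meta_rows = []
    for m in matrices:
        for i, cell in enumerate(m.cells):
            for s, psi in enumerate(m.draws[i]):
                draw_rows.append(
                    {"exon_id": m.exon_id, "cell_id": cell, "draw_index": s, "psi": psi}
                )
            meta_rows.append(
                {
                    "exon_id": m.exon_id,
                    "cell_id": cell,
                    "condition": m.conditions[i] if m.conditions else "all",
                    "mean_expression": m.mean_expression,
                }
            )
    write_table(pd.DataFrame(draw_rows), draws_path)
    write_table(pd.DataFrame(meta_rows), cells_path)


def read_posterior_matrices(draws_path, cells_path) -> list[PosteriorInclusionMatrix]:
    draws = read_table(draws_path)
    meta = read_table(cells_path).set_index(["exon_id", "cell_id"])
    matrices = []
    for exon_id, sub in draws.groupby("exon_id", sort=True):
        wide = sub.pivot(index="cell_id", columns="draw_index", values="psi")
        cells = list(wide.index)
        conds = [meta.loc[(exon_id, c), "condition"] for c in cells]
        expr = float(meta.loc[(exon_id, cells[0]), "mean_expression"])
        matrices.append(
            PosteriorInclusionMatrix(
                exon_id=exon_id,
                cells=cells,
                draws=wide.to_numpy(),
                conditions=conds,
                mean_expression=expr,
            )
        )
    return matrices
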