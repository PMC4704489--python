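import numpy as np
import pandas as pd
import pytest

from splicevar.synthetic import QpcrPlate, SimulationConfig, generate_qpcr_plate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but realistic plate: 2x4 exons, 2 conditions, 12 cells each."""
    return SimulationConfig(
        n_exons_per_group=4,
        n_cells_per_condition=12,
        conditions=("293T", "MCF7"),
        seed=101,
    )


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Noise-free, dropout-free configuration (exact round trips)."""
    return SimulationConfig(
        n_exons_per_group=3,
        n_cells_per_condition=8,
        conditions=("293T",),
        technical_noise_sd=0.0,
        dropout_et_threshold=0.0,
        pi_range=(0.2, 0.8),
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_plate(clean_config):
    return generate_qpcr_plate(clean_config)


def make_plate(rows, c_max: float = 30.0) -> QpcrPlate:
    """Build a plate from (sample, assay, role, Ct) tuples with passing QC."""
    wells = pd.DataFrame(
        [
            {
                "sample_id": s,
                "assay_id": a,
                "isoform_role": r,
                "Ct": ct,
                "ct_quality": 0.9,
                "peak_ratio": 0.95,
                "cell_type": "293T",
            }
            for s, a, r, ct in rows
        ]
    )
    return QpcrPlate(wells, c_max=c_max)


@pytest.fixture(scope="session")
def gamma_mixed_table():
    """A table generated from the gamma mixed model itself (known truth)."""
    rng = np.random.default_rng(11)
    rows = []
    for e in range(25):
        b = rng.normal(0, 0.5)
        for c in ("A", "B", "C"):
            x = rng.normal()
            mu = np.exp(-2 + 0.4 * (c == "B") - 0.6 * (c == "C") + 0.3 * x + b)
            rows.append(
                {
                    "exon_id": f"E{e:02d}",
                    "condition": c,
                    "x": x,
                    "var_t": rng.gamma(3.0, mu / 3.0),
                    "weight": 1.0,
                }
            )
    return pd.DataFrame(rows)
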