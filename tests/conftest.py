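import numpy as np
import pandas as pd
import pytest

from panelmark import io
from panelmark.simulate import GeneratorConfig, simulate_panel


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return io.load_table1_fixture()


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return io.load_table2_fixture()


@pytest.fixture(scope="session")
def human_de() -> pd.DataFrame:
    return io.load_human_de_fixture()


def make_two_group_panel(seed: int = 20240817, n_probes: int = 40, n_per: int = 4):
    """Seeded heterogeneous-variance two-group panel (reference-oracle recipe).

    The first five probes carry true log2 effects [1.5, -1.2, 0.8, 0.5, 2.0];
    per-probe noise SDs are uniform in [0.2, 0.8].
    """
    rng = np.random.default_rng(seed)
    baseline = rng.normal(7, 1, n_probes)
    logfc = np.zeros(n_probes)
    logfc[:5] = [1.5, -1.2, 0.8, 0.5, 2.0]
    sd = 0.2 + 0.6 * rng.random(n_probes)
    arm = np.array([0] * n_per + [1] * n_per)
    x = (
        baseline[:, None]
        + logfc[:, None] * arm[None, :]
        + rng.normal(0, 1, (n_probes, 2 * n_per)) * sd[:, None]
    )
    values = pd.DataFrame(
        x,
        index=pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id"),
        columns=[f"c{i}" for i in range(n_per)] + [f"t{i}" for i in range(n_per)],
    )
    meta = pd.DataFrame(
        {
            "strain": ["s"] * 2 * n_per,
            "treatment": ["control"] * n_per + ["treated"] * n_per,
            "replicate": list(range(1, n_per + 1)) * 2,
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    return io.ExpressionPanel(values=values, sample_meta=meta), logfc


@pytest.fixture()
def two_group_panel():
    return make_two_group_panel()


def recovery_config(seed: int = 0) -> GeneratorConfig:
    """A clearly-detectable planted-effect scenario for recovery checks.

    Effects are sized so that, at the panel's sample sizes, each planted
    probe is essentially always detectable (per-probe power > 99% at the
    default thresholds): |logFC| >= 1.3 against an estimate SE of ~0.05, and
    trait correlations near 0.55 against a detection cutoff of ~0.34.
    """
    return GeneratorConfig(
        n_probes=120,
        n_de=8,
        n_trait=3,
        n_overlap=2,
        n_duplicate_symbols=1,
        logfc_range=(1.3, 2.0),
        trait_r_target=0.55,
        seed=seed,
    )


@pytest.fixture()
def small_panel():
    cfg = GeneratorConfig(n_strains=12, n_probes=30, n_de=4, n_trait=2,
                          n_overlap=1, n_duplicate_symbols=0, seed=11)
    return simulate_panel(cfg)
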