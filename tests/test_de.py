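"""Differential expression: fold changes, moderated t, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelmark import de
from panelmark.errors import ContractError, DegenerateDataError
from panelmark.io import ExpressionPanel
from panelmark.simulate import GeneratorConfig, simulate_panel


def _panel_from_arrays(control: np.ndarray, treated: np.ndarray) -> ExpressionPanel:
    n_probes = control.shape[0]
    values = pd.DataFrame(
        np.hstack([control, treated]),
        index=pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id"),
        columns=[f"c{j}" for j in range(control.shape[1])]
        + [f"t{j}" for j in range(treated.shape[1])],
    )
    meta = pd.DataFrame(
        {
            "strain": ["s"] * values.shape[1],
            "treatment": ["control"] * control.shape[1] + ["treated"] * treated.shape[1],
            "replicate": list(range(control.shape[1])) + list(range(treated.shape[1])),
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    return ExpressionPanel(values=values, sample_meta=meta)


class TestLogFoldChange:
    def test_identical_arms_give_zero(self):
        x = np.random.default_rng(0).normal(7, 1, (3, 4))
        panel = _panel_from_arrays(x, x.copy())
        assert de.log_fold_change(panel, "p1") == 0.0

    def test_exact_unit_shift(self):
        x = np.random.default_rng(1).normal(7, 1, (3, 4))
        panel = _panel_from_arrays(x, x + 1.0)
        assert de.log_fold_change(panel, "p2") == pytest.approx(1.0, abs=1e-12)

    def test_equals_brute_force_mean_difference(self):
        rng = np.random.default_rng(2)
        c, t = rng.normal(7, 1, (5, 3)), rng.normal(7, 1, (5, 3))
        panel = _panel_from_arrays(c, t)
        for i in range(5):
            oracle = t[i].sum() / 3 - c[i].sum() / 3
            assert de.log_fold_change(panel, f"p{i}") == pytest.approx(oracle, abs=1e-12)

    def test_empty_arm_is_contract_error(self):
        x = np.random.default_rng(0).normal(7, 1, (3, 4))
        panel = _panel_from_arrays(x, x)
        panel.sample_meta["treatment"] = "control"
        with pytest.raises(ContractError):
            de.log_fold_change(panel, "p0")


class TestModeratedT:
    def test_d0_zero_equals_ordinary_pooled_t(self, two_group_panel):
        panel, _ = two_group_panel
        table = de.run_de(panel, d0=0.0).set_index("probe_id")
        c = panel.values[panel.arm_columns("control")].to_numpy()
        t = panel.values[panel.arm_columns("treated")].to_numpy()
        for i in range(panel.n_probes):
            ref = stats.ttest_ind(t[i], c[i], equal_var=True)
            row = table.loc[f"p{i}"]
            assert row["t"] == pytest.approx(ref.statistic, abs=1e-12)
            assert row["p_value"] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_identical_variances_are_a_shrinkage_fixed_point(self):
        s2 = np.full(30, 0.7)
        for d0 in (0.0, 1.0, 4.0, 100.0, np.inf):
            out = de.squeeze_variances(s2, 6.0, d0, s02=0.7)
            np.testing.assert_allclose(out, s2, atol=1e-14)

    def test_infinite_d0_shrinks_all_variances_to_prior(self):
        s2 = np.random.default_rng(3).chisquare(4, 20) / 4
        out = de.squeeze_variances(s2, 6.0, np.inf, s02=0.25)
        np.testing.assert_allclose(out, 0.25)

    def test_matches_reference_ebayes_implementation(self, two_group_panel):
        """Frozen oracle: Bioconductor limma 3.58.1 eBayes on this exact panel."""
        panel, _ = two_group_panel
        table = de.run_de(panel).set_index("probe_id")
        assert table.attrs["d0"] == pytest.approx(4.37644725117, rel=1e-6)
        assert table.attrs["s02"] == pytest.approx(0.195157867164, rel=1e-6)
        frozen = {  # probe: (logFC, t_mod, p)
            "p0": (1.832156147170, 6.911735768468, 3.43128510642e-05),
            "p1": (-1.320508344707, -5.850303003275, 1.39660768390e-04),
            "p2": (0.688726547735, 2.291023186598, 4.40410450852e-02),
            "p3": (0.974602395224, 3.741723653726, 3.59832597237e-03),
            "p4": (0.926079074230, 2.166590843643, 5.45302113922e-02),
            "p9": (-0.132470399173, -0.331880325124, 7.46586103148e-01),
            "p19": (-0.345892079667, -0.962763381845, 3.57565878873e-01),
            "p39": (0.791424949078, 1.787442552105, 1.03065489890e-01),
        }
        for probe, (lfc, t_mod, p) in frozen.items():
            row = table.loc[probe]
            assert row["logFC"] == pytest.approx(lfc, rel=1e-9)
            assert row["t"] == pytest.approx(t_mod, rel=1e-6)
            assert row["p_value"] == pytest.approx(p, rel=1e-6)

    def test_prior_estimates_recover_generating_hyperparameters(self):
        """(d0, s02) moment estimates vs generating values d0=4, s02=0.04."""
        rng = np.random.default_rng(42)
        d0s, s02s = [], []
        for _ in range(200):
            sig2 = 0.04 * 4 / rng.chisquare(4, 50)
            s2 = sig2 * rng.chisquare(6, 50) / 6
            d0, s02 = de.estimate_prior(s2, 6.0)
            d0s.append(min(d0, 50.0))
            s02s.append(s02)
        # estimator is right-skewed at 50 probes: check the median and the
        # scale estimate's mean (bands ≈ ±3 MC SEs around the oracle run)
        assert 3.0 < np.median(d0s) < 5.5
        assert np.mean(s02s) == pytest.approx(0.04, rel=0.15)

    def test_all_zero_variances_is_degenerate(self):
        x = np.ones((4, 3))
        panel = _panel_from_arrays(x, x + 1.0)
        with pytest.raises(DegenerateDataError):
            de.run_de(panel)


class TestBHAdjust:
    def test_single_p_is_unchanged(self):
        np.testing.assert_allclose(de.bh_adjust([0.03]), [0.03])

    def test_hand_enumerated_step_up(self):
        # p(i)*m/i = [.04,.04,.04,.04] -> min-accumulate from the right = .04
        np.testing.assert_allclose(
            de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-15
        )

    def test_never_below_input_and_capped_at_one(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(rng.integers(1, 60))
            adj = de.bh_adjust(p)
            assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_matches_brute_force_step_up_oracle(self):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            out = np.empty(m)
            for rank0, idx in enumerate(order):
                # smallest m*p(j)/j over all j at or after this rank
                out[idx] = min(
                    m * p[order[j]] / (j + 1) for j in range(rank0, m)
                )
            return np.minimum(out, 1.0)

        rng = np.random.default_rng(8)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(de.bh_adjust(p), oracle(p), atol=1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.random(100)
            np.testing.assert_allclose(
                de.bh_adjust(p), sm.multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ContractError):
            de.bh_adjust([0.5, 1.2])


class TestRunDE:
    def test_planted_probe_ranks_first(self):
        cfg = GeneratorConfig(n_strains=10, n_probes=60, n_de=1, n_trait=0,
                              n_overlap=0, n_duplicate_symbols=0,
                              logfc_range=(2.0, 2.0), expr_noise_sd=0.3, seed=13)
        panel, annot, _, truth = simulate_panel(cfg)
        table = de.run_de(panel, annot)
        (probe,) = truth.de_genes
        assert table.iloc[0]["probe_id"] == probe
        assert table.iloc[0]["p_adj"] < 1e-6

    def test_duplicate_probes_of_one_symbol_sit_adjacent(self):
        cfg = GeneratorConfig(n_strains=20, n_probes=50, n_de=2, n_trait=0,
                              n_overlap=0, n_duplicate_symbols=1,
                              logfc_range=(1.5, 1.5), seed=14)
        panel, annot, _, _ = simulate_panel(cfg)
        table = de.run_de(panel, annot)
        top2 = table.head(2)
        assert top2["symbol"].nunique() == 1  # shared symbol, as for Timp1
        assert abs(top2["logFC"].iloc[0] - top2["logFC"].iloc[1]) < 0.3

    def test_sign_of_t_matches_sign_of_logfc(self, two_group_panel):
        panel, _ = two_group_panel
        table = de.run_de(panel)
        nz = table[table["logFC"] != 0]
        assert (np.sign(nz["t"]) == np.sign(nz["logFC"])).all()
        assert (table["p_adj"] >= table["p_value"] - 1e-15).all()

    def test_sorted_by_absolute_logfc_descending(self, two_group_panel):
        panel, _ = two_group_panel
        table = de.run_de(panel)
        assert (np.diff(table["logFC"].abs()) <= 1e-12).all()
        by_p = de.run_de(panel, sort="p")
        assert (np.diff(by_p["p_value"]) >= -1e-15).all()
        with pytest.raises(ContractError):
            de.run_de(panel, sort="fc")
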