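import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import t as t_dist

import circadyn as cd
from circadyn.association import (correlate_deltas, delta_table,
                                  fpg_element_corr, pearson,
                                  trajectory_group_counts,
                                  trajectory_summary)

from conftest import SEED


def pearson_oracle(x, y):
    """Direct-formula Pearson R and two-sided t-based p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    tt = r * np.sqrt((n - 2) / max(1 - r * r, 1e-300))
    return r, 2 * t_dist.sf(abs(tt), n - 2)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_small_case_matches_formula(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        r, p = pearson(x, y)
        ro, po = pearson_oracle(x, y)
        assert r == pytest.approx(ro, abs=1e-12)
        assert p == pytest.approx(po, abs=1e-12)

    @given(st.integers(0, 1000))
    def test_matches_direct_formula_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 100))
        x, y = rng.normal(size=n), rng.normal(size=n)
        r, p = pearson(x, y)
        ro, po = pearson_oracle(x, y)
        assert r == pytest.approx(ro, abs=1e-12)
        assert p == pytest.approx(po, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])

    def test_type_one_error_rate_calibrated(self):
        """Null rejection rate of p < 0.05 is 5% (2,000 simulations)."""
        rng = np.random.default_rng(SEED)
        hits = 0
        for _ in range(2000):
            x, y = rng.normal(size=35), rng.normal(size=35)
            _, p = pearson(x, y)
            hits += p < 0.05
        assert abs(hits / 2000 - 0.05) <= 0.02


class TestCorrelateDeltas:
    def _table(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n, 3)),
                          columns=["dEPM", "dFPG", "dISSI2"])
        return df

    def test_identical_columns_give_unit_cell(self):
        df = self._table()
        df["dFPG"] = df["dEPM"]
        corr = correlate_deltas(df)
        assert corr.r.loc["dEPM", "dFPG"] == pytest.approx(1.0)

    def test_matrix_symmetric_unit_diagonal(self):
        corr = correlate_deltas(self._table())
        assert np.allclose(corr.r, corr.r.T, equal_nan=True)
        assert np.allclose(np.diag(corr.r), 1.0)

    def test_constant_column_flagged_na_others_fine(self):
        df = self._table()
        df["dISSI2"] = 5.0
        corr = correlate_deltas(df)
        assert np.isnan(corr.r.loc["dEPM", "dISSI2"])
        assert not np.isnan(corr.r.loc["dEPM", "dFPG"])

    def test_too_few_complete_pairs_na(self):
        df = self._table(n=5)
        df.loc[0:2, "dFPG"] = np.nan
        corr = correlate_deltas(df)
        assert corr.n.loc["dEPM", "dFPG"] == 2
        assert np.isnan(corr.r.loc["dEPM", "dFPG"])


def test_generator_coupling_sign_recovered_across_seeds():
    """Cohorts generated with positive EPM/HOMA-IR coupling yield a
    positive sample correlation in >= 95% of seeds."""
    import circadyn.catalog_metrics as cm
    import circadyn.clinical as cl
    cfg = cd.SimConfig(n_patients=35, records_per_sample=100)
    pos = 0
    n_seeds = 40
    for seed in range(n_seeds):
        sim = cd.simulate_cohort(cfg, seed=10_000 + seed)
        ind = cl.indices_table(sim.meals)
        pre = pd.Series({c.patient_id: cm.epm(c)
                         for c in sim.catalogs.values()
                         if c.timepoint == "pre"})
        post = pd.Series({c.patient_id: cm.epm(c)
                          for c in sim.catalogs.values()
                          if c.timepoint == "post"})
        dtab = delta_table(pre, post, cl.delta_frame(ind))
        corr = correlate_deltas(dtab)
        pos += corr.r.loc["dEPM", "dHOMA_IR"] > 0
    assert pos / n_seeds >= 0.95


class TestFpgElementCorr:
    def test_affine_fraction_r_one(self):
        fpg = pd.Series(np.linspace(5, 12, 10),
                        index=[f"s{i}" for i in range(10)])
        frac = pd.DataFrame({"exon_fraction": 0.01 * fpg + 0.05,
                             "intron_fraction": 1 - (0.01 * fpg + 0.05)})
        tab = fpg_element_corr(frac, fpg).set_index("element")
        assert tab.loc["exon_fraction", "r"] == pytest.approx(1.0)
        # partition anti-symmetry
        assert tab.loc["intron_fraction", "r"] == pytest.approx(-1.0)

    def test_independent_fraction_null(self):
        rng = np.random.default_rng(SEED)
        idx = [f"s{i}" for i in range(1000)]
        fpg = pd.Series(rng.normal(8, 2, 1000), index=idx)
        frac = pd.DataFrame({"exon_fraction": rng.uniform(0, 1, 1000),
                             "intron_fraction": rng.uniform(0, 1, 1000)},
                            index=idx)
        tab = fpg_element_corr(frac, fpg).set_index("element")
        assert abs(tab.loc["exon_fraction", "r"]) < 0.1
        assert tab.loc["exon_fraction", "p"] > 0.01


class TestTrajectory:
    def test_flags(self):
        fu = pd.DataFrame({
            "patient_id": ["a", "b"],
            "label": ["remission", "non_remission"],
            "epm_pre": [100.0, 100.0],
            "epm_post": [150.0, 150.0],
            "epm_M12": [80.0, 120.0],
        })
        tab = trajectory_summary(fu).set_index("patient_id")
        assert bool(tab.loc["a", "post_gt_pre"]) and bool(tab.loc["a", "m12_lt_pre"])
        assert bool(tab.loc["b", "post_gt_pre"]) and not bool(tab.loc["b", "m12_lt_pre"])

    def test_missing_timepoint_excluded(self):
        fu = pd.DataFrame({
            "patient_id": ["a", "b"],
            "label": ["remission", "remission"],
            "epm_pre": [100.0, 100.0],
            "epm_post": [150.0, np.nan],
            "epm_M12": [80.0, 90.0],
        })
        tab = trajectory_summary(fu)
        assert list(tab["patient_id"]) == ["a"]
        assert tab.attrs["excluded"] == ["b"]

    def test_remission_patients_end_below_baseline(self, small_cohort):
        tab = trajectory_summary(small_cohort.followup)
        rem = tab[tab["label"] == "remission"]
        assert rem["m12_lt_pre"].all()
        counts = trajectory_group_counts(tab)
        assert counts.set_index("label").loc["remission", "n_m12_lt_pre"] \
            == len(rem)
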