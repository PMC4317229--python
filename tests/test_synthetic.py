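"""Synthetic study generator: IIV sampling, error model, censoring,
ADA contamination and the exclusion filter."""

import numpy as np
import pandas as pd
import pytest

from tmddpk.synthetic import (
    BodyWeightSummary,
    DATASET_COLUMNS,
    IIVSpec,
    ResidualErrorSpec,
    StudyDataset,
    apply_residual_error,
    censor_lloq,
    exclude_ada_points,
    generate_dataset,
    packaged_designs,
    sample_individuals,
    simulate_ada_impact,
    vpc_percentiles,
)
from tmddpk.units import molar_to_ngml, ngml_to_molar


class TestSampleIndividuals:
    def test_zero_cv_gives_typical(self, monkey):
        inds, _ = sample_individuals(5, monkey, IIVSpec(0, 0, 0, 0), rng=0)
        for p in inds:
            assert p.cl == monkey.cl and p.vc == monkey.vc and p.rtot == monkey.rtot

    def test_lognormal_cv_of_clearance(self, monkey, iiv):
        inds, _ = sample_individuals(10_000, monkey, iiv, rng=1)
        cl = np.array([p.cl for p in inds])
        cv = cl.std(ddof=1) / cl.mean()
        assert cv == pytest.approx(0.441, rel=0.05)

    def test_cl_vc_log_correlation(self, monkey, iiv):
        inds, _ = sample_individuals(10_000, monkey, iiv, rng=2)
        r = np.corrcoef(
            np.log([p.cl for p in inds]), np.log([p.vc for p in inds])
        )[0, 1]
        assert r == pytest.approx(0.642, abs=0.05)

    def test_body_weights_in_range(self, monkey, iiv):
        _, bw = sample_individuals(500, monkey, iiv, rng=3)
        assert bw.min() >= 2.1 and bw.max() <= 6.4
        assert np.median(bw) == pytest.approx(2.8, abs=0.35)

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            IIVSpec(corr_cl_vc=1.5)


class TestResidualError:
    def test_zero_error_exact(self):
        c = np.array([0.0, 1.0, 50.0])
        dv, floored = apply_residual_error(c, ResidualErrorSpec(0.0, 0.0), rng=0)
        np.testing.assert_array_equal(dv, c)
        assert not floored.any()

    def test_empirical_sd_matches_error_model(self):
        # var(DV) = (C*cv)^2 + sd^2 at C = 100 nM
        spec = ResidualErrorSpec(0.201, 1.11)
        c = np.full(100_000, 100.0)
        dv, _ = apply_residual_error(c, spec, rng=4)
        expected_sd = np.sqrt((100 * 0.201) ** 2 + 1.11**2)
        assert dv.std(ddof=1) == pytest.approx(expected_sd, rel=0.02)

    def test_zero_concentration_additive_only(self):
        spec = ResidualErrorSpec(0.201, 1.11)
        dv, floored = apply_residual_error(np.zeros(50_000), spec, rng=5)
        # before flooring mean is 0; after flooring it is E|e|/2-ish but
        # the unfloored half must follow the additive SD
        assert floored.mean() == pytest.approx(0.5, abs=0.02)
        assert dv[dv > 0].std(ddof=1) < 1.11


class TestCensorLloq:
    def make_ds(self, dv_ngml):
        n = len(dv_ngml)
        tab = pd.DataFrame(
            {
                "ID": np.arange(n), "TIME": np.arange(n, dtype=float),
                "AMT": np.nan, "DV": ngml_to_molar(np.asarray(dv_ngml, float)),
                "EVID": 0, "MDV": 0, "ROUTE": "IV", "BW": 2.8, "STUDY": "T",
                "GROUP": 0, "DOSE_MGKG": 1.0, "LLOQ": 2.0, "BLQ": 0,
                "ADA": 0, "EXCL": 0, "EXPECTED": np.nan,
            },
            columns=DATASET_COLUMNS,
        )
        return StudyDataset(tab)

    def test_strictly_below_rule(self):
        ds = censor_lloq(self.make_ds([0.5, 1.9, 2.0, 3.0, 30.0]), 2.0)
        assert ds.table["BLQ"].sum() == 2
        assert ds.table.loc[ds.table["BLQ"] == 1, "MDV"].eq(1).all()

    def test_all_above_unchanged(self):
        ds = censor_lloq(self.make_ds([5.0, 10.0]), 2.0)
        assert ds.table["BLQ"].sum() == 0

    def test_below_limit_flagged(self):
        ds = censor_lloq(self.make_ds([1.0]), 2.0)
        assert ds.table["BLQ"].iloc[0] == 1


class TestGenerateDataset:
    @pytest.fixture(scope="class")
    def full_program(self):
        return generate_dataset(seed=11)

    def test_program_size(self, full_program):
        tab = full_program.table
        obs = tab[tab["EVID"] == 0]
        assert tab["ID"].nunique() == 119
        assert abs(len(obs) - 1743) / 1743 < 0.10

    def test_determinism(self):
        a = generate_dataset(seed=3, designs=packaged_designs()[:1])
        b = generate_dataset(seed=3, designs=packaged_designs()[:1])
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_no_ada_at_high_dose(self, full_program):
        obs = full_program.table.query("EVID == 0 and DOSE_MGKG >= 80")
        assert obs["ADA"].sum() == 0

    def test_blq_only_below_lloq(self, full_program):
        obs = full_program.table.query("EVID == 0 and BLQ == 1")
        assert (molar_to_ngml(obs["DV"].to_numpy()) < obs["LLOQ"].to_numpy()).all()

    def test_every_observation_belongs_to_dosed_animal(self, full_program):
        tab = full_program.table
        dosed = set(tab.loc[tab["EVID"] == 1, "ID"])
        assert set(tab.loc[tab["EVID"] == 0, "ID"]) <= dosed


class TestAdaImpact:
    def test_fraction_zero_unchanged(self):
        design = packaged_designs()[0]
        base = generate_dataset([design], ada=None, seed=5)
        spec_off = dict(low=0.0, mid=0.0, high=0.0)
        out = simulate_ada_impact(base, affected_fraction_by_dose=spec_off, seed=5)
        pd.testing.assert_frame_equal(out.table, censor_lloq(base).table)

    def test_post_onset_below_counterfactual(self):
        design = packaged_designs()[0]
        base = generate_dataset(
            [design], ada=None, resid=ResidualErrorSpec(0.0, 0.0), seed=6
        )
        out = simulate_ada_impact(base, seed=6)
        merged = base.table.join(out.table, rsuffix="_ada")
        hit = merged[(merged["ADA_ada"] == 1) & (merged["EVID"] == 0)]
        assert len(hit) > 0
        assert (hit["DV_ada"] <= hit["DV"] + 1e-12).all()
        assert (hit["DV_ada"] < hit["DV"]).any()

    def test_exclusion_fraction_brackets_default_calibration(self):
        # default generator settings should exclude ~5-9% of observations
        fractions = []
        for seed in range(4):
            ds = generate_dataset(seed=seed)
            _, report = exclude_ada_points(ds)
            fractions.append(report["fraction_excluded"])
        assert 0.05 <= np.mean(fractions) <= 0.09


class TestExcludeAdaPoints:
    def toy(self, n=1743, n_excl=120):
        from _toydata import toy_exclusion_dataset

        return toy_exclusion_dataset(n, n_excl)

    def test_worked_example_percentage(self):
        _, report = exclude_ada_points(self.toy())
        assert report["n_excluded"] == 120
        assert report["percent_excluded"] == pytest.approx(6.88, abs=0.005)

    def test_no_ada_no_exclusions(self):
        ds = self.toy()
        ds.table["ADA"] = 0
        _, report = exclude_ada_points(ds)
        assert report["n_excluded"] == 0

    def test_infinite_threshold_no_exclusions(self):
        _, report = exclude_ada_points(self.toy(), deviation_threshold=1e12)
        assert report["n_excluded"] == 0

    def test_idempotent(self):
        ds1, r1 = exclude_ada_points(self.toy())
        ds2, r2 = exclude_ada_points(ds1)
        assert r1["n_excluded"] == r2["n_excluded"]
        pd.testing.assert_frame_equal(ds1.table, ds2.table)


class TestVPC:
    fixed_bw = BodyWeightSummary(median=2.8, low=2.1, high=6.4, log_sd=0.0)

    def test_zero_variability_bands_coincide(self, monkey):
        # no IIV, no residual error, fixed body weight: degenerate bands
        design = packaged_designs()[0]
        bands = vpc_percentiles(
            monkey, IIVSpec(0, 0, 0, 0), ResidualErrorSpec(0, 0),
            design, n_reps=3, seed=0, bw=self.fixed_bw,
        )
        np.testing.assert_allclose(bands["p10"], bands["p90"], rtol=1e-9)
        np.testing.assert_allclose(bands["p10"], bands["p50"], rtol=1e-9)

    def test_bands_widen_with_error_magnitude(self, monkey, iiv):
        design = packaged_designs()[0]
        narrow = vpc_percentiles(
            monkey, iiv, ResidualErrorSpec(0.201, 1.11), design, n_reps=40, seed=1
        )
        wide = vpc_percentiles(
            monkey, iiv, ResidualErrorSpec(0.402, 1.11), design, n_reps=40, seed=1
        )
        spread_n = (narrow["p90"] - narrow["p10"]).to_numpy()
        spread_w = (wide["p90"] - wide["p10"]).to_numpy()
        # where the proportional component dominates the additive floor the
        # widening must be systematic; globally the mean spread must grow
        prop_dominated = narrow["p50"].to_numpy() > 5.0 * 1.11
        assert prop_dominated.sum() > 10
        ratio = spread_w[prop_dominated] / spread_n[prop_dominated]
        assert np.mean(ratio >= 1.0) > 0.85  # up to Monte-Carlo noise
        assert np.all(ratio > 0.9)
        assert spread_w.mean() > spread_n.mean()
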