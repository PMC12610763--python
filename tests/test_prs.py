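"""PRS scoring, standardization, and theoretical-OR absolute risk."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from riskoverlap import (PRSParams, WeightSet, mean_relative_risk,
                         prs_five_year_risk, read_weights, rr_vs_middle_quintile,
                         score_prs, score_prs_cohort, standardize)
from riskoverlap.prs import control_moments

from conftest import flat_rate_table


def brute_force_scores(dosages: pd.DataFrame, weights: WeightSet) -> pd.Series:
    """Per-subject loop oracle with the same matching/imputation rules."""
    subjects = [c for c in dosages.columns if c not in ("effect_allele",
                                                        "other_allele")]
    means = {}
    rows = {}
    for vid in dosages.index:
        d = pd.to_numeric(dosages.loc[vid, subjects], errors="coerce")
        means[vid] = d.dropna().mean()
        rows[vid] = d
    out = {}
    for subj in subjects:
        total = 0.0
        for _, w in weights.variants.iterrows():
            vid = w["variant_id"]
            if vid not in dosages.index:
                continue
            ea = dosages.loc[vid, "effect_allele"]
            oa = dosages.loc[vid, "other_allele"]
            if ea == w["effect_allele"] and oa == w["other_allele"]:
                flip = False
            elif ea == w["other_allele"] and oa == w["effect_allele"]:
                flip = True
            else:
                continue
            d = rows[vid][subj]
            if np.isnan(d):
                d = means[vid]
            if flip:
                d = 2.0 - d
            total += w["weight"] * d
        out[subj] = total
    return pd.Series(out)


def make_weights(rows):
    return WeightSet(pd.DataFrame(rows, columns=["variant_id", "effect_allele",
                                                 "other_allele", "weight"]))


def make_dosages(rows, subjects):
    df = pd.DataFrame(rows, columns=["variant_id", "effect_allele",
                                     "other_allele", *subjects])
    return df.set_index("variant_id")


class TestScorePrs:
    def test_direct_weighted_sum(self):
        weights = make_weights([("v1", "A", "G", 0.1), ("v2", "C", "T", -0.2),
                                ("v3", "A", "C", 0.3)])
        dosages = make_dosages([("v1", "A", "G", 0.0), ("v2", "C", "T", 1.0),
                                ("v3", "A", "C", 2.0)], ["s1"])
        rep = score_prs(dosages, weights)
        assert rep.raw["s1"] == pytest.approx(0.4)
        assert rep.n_matched == 3 and rep.n_skipped == 0

    def test_mean_imputation_of_missing_entry(self):
        weights = make_weights([("v1", "A", "G", 1.0)])
        dosages = make_dosages([("v1", "A", "G", 0.0, 1.0, 1.0, 2.0, np.nan)],
                               ["s1", "s2", "s3", "s4", "s5"])
        rep = score_prs(dosages, weights)
        assert rep.raw["s5"] == pytest.approx(1.0)  # mean of {0,1,1,2}

    def test_allele_flip(self):
        weights = make_weights([("v1", "A", "G", 0.5)])
        dosages = make_dosages([("v1", "G", "A", 2.0)], ["s1"])  # swapped
        rep = score_prs(dosages, weights)
        assert rep.raw["s1"] == pytest.approx(0.0)  # dose flipped to 0
        assert rep.n_flipped == 1

    def test_absent_variant_logged_and_skipped(self):
        weights = make_weights([("v1", "A", "G", 0.5), ("vX", "A", "G", 9.9)])
        dosages = make_dosages([("v1", "A", "G", 1.0)], ["s1"])
        rep = score_prs(dosages, weights)
        assert rep.n_skipped == 1
        assert rep.skipped_variants[0][0] == "vX"
        assert rep.raw["s1"] == pytest.approx(0.5)

    def test_ambiguous_strand_configurable(self):
        weights = make_weights([("v1", "A", "T", 0.5)])
        dosages = make_dosages([("v1", "A", "T", 2.0)], ["s1"])
        keep = score_prs(dosages, weights)
        drop = score_prs(dosages, weights, drop_ambiguous=True)
        assert keep.n_ambiguous == 1 and keep.raw["s1"] == pytest.approx(1.0)
        assert drop.raw["s1"] == 0.0

    def test_zero_weights_annihilate(self):
        weights = make_weights([("v1", "A", "G", 0.0), ("v2", "C", "T", 0.0)])
        dosages = make_dosages([("v1", "A", "G", 2.0), ("v2", "C", "T", 1.0)],
                               ["s1"])
        assert score_prs(dosages, weights).raw["s1"] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n_var, n_sub = 25, 12
        subjects = [f"s{i}" for i in range(n_sub)]
        wrows, drows = [], []
        bases = np.array(["A", "C", "G", "T"])
        for i in range(n_var):
            ea, oa = rng.choice(bases, 2, replace=False)
            w = rng.normal()
            wrows.append((f"v{i}", ea, oa, w))
            dose = rng.integers(0, 3, n_sub).astype(float)
            dose[rng.random(n_sub) < 0.2] = np.nan
            if rng.random() < 0.3:
                ea, oa = oa, ea  # swapped in the dosage file
            drows.append((f"v{i}", ea, oa, *dose))
        weights = make_weights(wrows)
        dosages = make_dosages(drows, subjects)
        rep = score_prs(dosages, weights)
        oracle = brute_force_scores(dosages, weights)
        pd.testing.assert_series_equal(rep.raw.sort_index(), oracle.sort_index(),
                                       check_names=False, atol=1e-12, rtol=0)

    def test_vcf_dosage_input_matches_matrix_route(self, tmp_path):
        pytest.importorskip("cyvcf2")
        from riskoverlap import read_dosages_vcf

        vcf = tmp_path / "panel.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\trs1\tG\tA\t.\t.\t.\tGT:DS\t0/1:1.0\t1/1:2.0\n"
            "1\t200\trs2\tT\tC\t.\t.\t.\tGT:DS\t0/0:0.0\t0/1:0.9\n")
        dosages = read_dosages_vcf(vcf)
        weights = make_weights([("rs1", "A", "G", 0.5), ("rs2", "C", "T", 1.0)])
        rep = score_prs(dosages, weights)
        assert rep.raw["s1"] == pytest.approx(0.5 * 1.0 + 1.0 * 0.0)
        assert rep.raw["s2"] == pytest.approx(0.5 * 2.0 + 1.0 * 0.9)

    def test_pgs_catalog_style_weight_file(self, tmp_path):
        path = tmp_path / "weights.txt"
        path.write_text("# PGS weight file\n"
                        "rsID\teffect_allele\tother_allele\teffect_weight\n"
                        "rs1\tA\tG\t0.25\n")
        ws = read_weights(path)
        assert len(ws) == 1
        assert ws.variants["weight"].iloc[0] == 0.25


class TestStandardize:
    PARAMS = PRSParams(mu_ctrl=1.5, sd_ctrl=0.5, beta=np.log(1.6))

    def test_center_and_one_sd(self):
        z, pct = standardize([1.5, 2.0], self.PARAMS)
        assert z[0] == 0 and pct[0] == 0.5
        assert z[1] == pytest.approx(1.0)
        assert pct[1] == pytest.approx(0.841345, abs=1e-6)

    def test_control_moments_give_unit_controls(self):
        rng = np.random.default_rng(3)
        raw = np.concatenate([rng.normal(2, 0.7, 500), rng.normal(2.5, 0.7, 500)])
        is_ctrl = np.arange(1000) < 500
        mu, sd = control_moments(raw, is_ctrl)
        z, _ = standardize(raw, PRSParams(mu, sd))
        assert z[:500].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[:500].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            PRSParams(mu_ctrl=0, sd_ctrl=0)

    def test_percentile_uniform_for_normal_scores(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(1.5, 0.5, 20_000)
        _, pct = standardize(raw, self.PARAMS)
        assert stats.kstest(pct, "uniform").pvalue > 0.001


def quad_band_constant(beta, lo=0.4, hi=0.6):
    """Oracle: adaptive integration of exp(beta u) phi(u) over the band."""
    qlo, qhi = stats.norm.ppf(lo), stats.norm.ppf(hi)
    val, _ = quad(lambda u: np.exp(beta * u) * stats.norm.pdf(u), qlo, qhi,
                  epsabs=1e-14, epsrel=1e-14)
    return val / (hi - lo)


class TestTheoreticalOr:
    @pytest.mark.parametrize("beta", [0.0, 0.25, 0.47, 1.0])
    def test_matches_adaptive_quadrature(self, beta):
        params = PRSParams(0, 1, beta=beta)
        for z in (-2.0, 0.0, 1.3):
            want = np.exp(beta * z) / quad_band_constant(beta)
            assert rr_vs_middle_quintile(z, params) == pytest.approx(
                want, abs=1e-10, rel=1e-10)

    def test_zero_beta_degenerates_to_unity(self):
        params = PRSParams(0, 1, beta=0.0)
        assert np.allclose(rr_vs_middle_quintile([-3, 0, 3], params), 1.0)

    def test_center_value_for_published_effect(self):
        params = PRSParams(0, 1, beta=np.log(1.6))
        assert rr_vs_middle_quintile(0.0, params) == pytest.approx(0.9977, abs=5e-4)

    def test_strictly_increasing_in_z(self):
        params = PRSParams(0, 1, beta=0.3)
        z = np.linspace(-3, 3, 50)
        assert np.all(np.diff(rr_vs_middle_quintile(z, params)) > 0)

    def test_mean_relative_risk_monte_carlo(self):
        params = PRSParams(0, 1, beta=np.log(1.6))
        rng = np.random.default_rng(9)
        mc = rr_vs_middle_quintile(rng.normal(size=2_000_000), params).mean()
        assert mean_relative_risk(params) == pytest.approx(mc, rel=2e-3)
        assert mean_relative_risk(params) == pytest.approx(1.114, abs=2e-3)


class TestAbsoluteRisk:
    def test_zero_beta_gives_common_risk(self):
        params = PRSParams(0, 1, beta=0.0)
        rates = flat_rate_table(h1=0.01, h2=0.0)
        ar5 = prs_five_year_risk([-2, 0, 2], 40.0, params, rates)
        assert np.allclose(ar5, 1 - np.exp(-0.05))

    def test_population_mean_risk_conservation(self):
        """The population-mean constraint conserves the average incidence
        hazard exactly (E[rr(Z)]/m = 1); on the five-year-risk scale the
        cohort average matches the unstratified rr=1 projection up to the
        small Jensen gap of the nonlinear risk formula (<1% here)."""
        params = PRSParams(0, 1, beta=np.log(1.6))
        rates = flat_rate_table(h1=0.01, h2=0.005)
        rng = np.random.default_rng(17)
        z = rng.normal(size=200_000)
        eff = rr_vs_middle_quintile(z, params) / mean_relative_risk(params)
        assert eff.mean() == pytest.approx(1.0, abs=3e-3)  # MC error only
        mean_risk = prs_five_year_risk(z, 40.0, params, rates).mean()
        ref = 1 * 0.01 / 0.015 * (1 - np.exp(-0.015 * 5))
        assert mean_risk == pytest.approx(ref, rel=1e-2)

    def test_strictly_increasing_in_z(self, white_rates):
        params = PRSParams(0, 1, beta=0.4)
        ar5 = prs_five_year_risk(np.linspace(-3, 3, 30), 50.0, params, white_rates)
        assert np.all(np.diff(ar5) > 0)

    def test_mid_quintile_baseline_is_higher(self, white_rates):
        params = PRSParams(0, 1, beta=0.4)
        pm = prs_five_year_risk([0.0], 50.0, params, white_rates,
                                baseline="population-mean")
        mq = prs_five_year_risk([0.0], 50.0, params, white_rates,
                                baseline="mid-quintile")
        assert mq[0] > pm[0]  # mean rr > 1 so the population-mean route rescales down


class TestCohortScoring:
    def test_control_z_moments_and_columns(self, small_cohort,
                                           rates_by_population):
        scored, params = score_prs_cohort(small_cohort, rates_by_population)
        for ancestry in ("European", "Asian"):
            sub = scored.data[(scored.data["ancestry"] == ancestry)
                              & (scored.data["status"] == "control")]
            assert sub["prs_z"].mean() == pytest.approx(0.0, abs=1e-10)
            assert sub["prs_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        for col in ("prs_z", "prs_pct", "prs_rr", "prs_ar5"):
            assert np.isfinite(scored.data[col]).all()

    def test_cases_enriched_for_high_scores(self, small_cohort,
                                            rates_by_population):
        scored, _ = score_prs_cohort(small_cohort, rates_by_population)
        eur = scored.data[scored.data["ancestry"] == "European"]
        assert (eur.loc[eur["status"] == "invasive", "prs_z"].mean()
                > eur.loc[eur["status"] == "control", "prs_z"].mean() + 0.2)
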