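import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort
from neurocongruence._errors import DegenerateInputError, ValidationError
from neurocongruence.volumetrics import (
    ModelSpec,
    apply_qc_exclusions,
    fdr_adjust,
    fit_sex_effect,
    fit_sex_effects_table,
    harmonize_batches,
    levene_variance_test,
    residualize,
    subset_one_per_family,
    summarize_sex_bias,
    zscore_response,
)
from oracles import bh_stepup_reference, levene_reference, ols_reference


class TestQcExclusions:
    def test_threshold_removes_bad_reconstructions(self):
        t = pd.DataFrame({"euler": [-50, -300], "x": [1, 2]})
        out = apply_qc_exclusions(t, euler_threshold=-200)
        assert list(out["euler"]) == [-50]

    def test_identity_when_all_pass(self):
        t = pd.DataFrame({"euler": [-10, -100, 0]})
        assert len(apply_qc_exclusions(t, -200)) == 3

    def test_empty_table(self):
        t = pd.DataFrame({"euler": pd.Series(dtype=float)})
        assert len(apply_qc_exclusions(t, -200)) == 0

    def test_missing_column(self):
        with pytest.raises(ValidationError):
            apply_qc_exclusions(pd.DataFrame({"x": [1]}), -200)


class TestZScore:
    def test_symmetric_case(self):
        assert np.allclose(zscore_response([2, 4, 6]), [-1, 0, 1])

    def test_mean_zero_unit_sd(self, rng):
        z = zscore_response(rng.normal(3, 7, size=40))
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_constant_input_is_an_error(self):
        with pytest.raises(DegenerateInputError):
            zscore_response([5, 5, 5])


class TestFitSexEffect:
    def test_toy_design_matches_normal_equations(self, toy_subjects):
        spec = ModelSpec(response="vol_roi", include_ttv=False)
        res = fit_sex_effect(toy_subjects, spec)
        y = zscore_response(toy_subjects["vol_roi"].to_numpy())
        male = (toy_subjects["sex"] == "M").astype(float)
        agec = toy_subjects["age"] - toy_subjects["age"].mean()
        X = [[1.0, m, a] for m, a in zip(male, agec)]
        beta = ols_reference(X, list(y))
        assert res.beta_sex == pytest.approx(beta[1], abs=1e-12)

    def test_null_effect_recovery(self):
        t = make_cohort(n_per_sex=250, beta=0.0, seed=3)
        spec = ModelSpec(response="vol_roi", qc_col="euler")
        res = fit_sex_effect(t, spec)
        se = abs(res.beta_sex / res.t) if res.t != 0 else 1.0
        assert abs(res.beta_sex) < 3 * se

    def test_beta_invariant_to_affine_response_rescaling(self, toy_subjects):
        spec = ModelSpec(response="vol_roi", include_ttv=False)
        base = fit_sex_effect(toy_subjects, spec).beta_sex
        scaled = toy_subjects.assign(vol_roi=3.5 * toy_subjects["vol_roi"] + 11.0)
        assert fit_sex_effect(scaled, spec).beta_sex == pytest.approx(base, abs=1e-12)

    def test_categorical_strain_covariate(self):
        t = make_cohort(n_per_sex=60, beta=0.4, seed=5)
        t["strain"] = np.where(np.arange(len(t)) % 2 == 0, "B6J", "B6N")
        spec = ModelSpec(response="vol_roi", qc_col="strain", qc_categorical=True)
        res = fit_sex_effect(t, spec)
        assert np.isfinite(res.beta_sex) and 0 < res.p <= 1

    def test_single_sex_rejected(self, toy_subjects):
        t = toy_subjects.assign(sex="F")
        with pytest.raises(ValidationError):
            fit_sex_effect(t, ModelSpec(response="vol_roi", include_ttv=False))


class TestFdr:
    def test_single_p(self):
        q, sig = fdr_adjust([0.03])
        assert q[0] == pytest.approx(0.03)
        assert sig[0]

    def test_stepup_hand_case(self):
        q, _ = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_identical_ps(self):
        q, _ = fdr_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_matches_bruteforce_on_permutations(self):
        base = [0.001, 0.011, 0.04, 0.049, 0.3, 0.9]
        for perm in itertools.islice(itertools.permutations(base), 0, 720, 7):
            q, _ = fdr_adjust(list(perm))
            assert np.allclose(q, bh_stepup_reference(list(perm)), atol=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.5])


class TestResidualize:
    def test_matches_hand_ols(self):
        t = pd.DataFrame({"c": [1.0, 2, 3, 4, 5], "vol_r": [2.0, 2, 5, 4, 9]})
        res = residualize(t, ["c"], ["vol_r"])["vol_r"]
        X = [[1.0, c] for c in t["c"]]
        b = ols_reference(X, list(t["vol_r"]))
        expected = t["vol_r"] - (b[0] + b[1] * t["c"])
        assert np.allclose(res, expected, atol=1e-12)

    def test_orthogonal_to_covariates(self, rng):
        t = pd.DataFrame({
            "a": rng.normal(size=30), "b": rng.normal(size=30),
            "vol_r": rng.normal(size=30),
        })
        res = residualize(t, ["a", "b"], ["vol_r"])["vol_r"]
        assert res @ t["a"] == pytest.approx(0, abs=1e-9)
        assert res @ t["b"] == pytest.approx(0, abs=1e-9)

    def test_null_covariates_leave_centered_volumes(self, rng):
        # covariate independent of the volume: residuals track the centered
        # volumes up to the O(1/sqrt(n)) chance association
        t = pd.DataFrame({"c": rng.normal(size=500), "vol_r": rng.normal(size=500)})
        res = residualize(t, ["c"], ["vol_r"])["vol_r"]
        centered = t["vol_r"] - t["vol_r"].mean()
        assert np.corrcoef(res, centered)[0, 1] > 0.99
        assert np.abs(res - centered).max() < 0.5


class TestLevene:
    def test_identical_groups_give_zero(self):
        r = levene_variance_test([1, 2, 6, 1, 2, 6], ["F"] * 3 + ["M"] * 3)
        assert r.F == pytest.approx(0.0)

    def test_two_by_two_hand_case(self):
        # |dev| groups: (1,1) and (2,2) -> SSB=1, SSW=0 -> F is infinite
        r = levene_variance_test([1, 3, 2, 6], ["F", "F", "M", "M"])
        assert np.isinf(r.F)
        assert levene_reference([[1, 3], [2, 6]]) == np.inf

    def test_matches_definitional_oracle(self, rng):
        x = rng.normal(size=30)
        sex = np.array(["F"] * 15 + ["M"] * 15)
        r = levene_variance_test(x, sex)
        assert r.F == pytest.approx(
            levene_reference([list(x[:15]), list(x[15:])]), abs=1e-10)

    def test_reports_group_variances(self, rng):
        x = np.concatenate([rng.normal(size=20), rng.normal(scale=3, size=20)])
        sex = np.array(["F"] * 20 + ["M"] * 20)
        r = levene_variance_test(x, sex)
        assert r.group_variances["M"] > r.group_variances["F"]

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            levene_variance_test([1, 2, 3], ["F", "F", "F"])


class TestHarmonize:
    REGIONS = [f"vol_{c}" for c in "abcdefghij"]

    def _table(self, rng, n=400, n_batches=2, offset=0.0, scale=1.0):
        t = pd.DataFrame({
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            "age": rng.uniform(20, 30, size=n),
            "batch": [f"b{i % n_batches}" for i in range(n)],
        })
        for r in self.REGIONS:
            base = rng.normal(size=n)
            shift = np.where(t["batch"] == "b1", offset, 0.0)
            sc = np.where(t["batch"] == "b1", scale, 1.0)
            t[r] = base * sc + shift
        return t

    def test_single_batch_identity(self, rng):
        t = self._table(rng, n_batches=1)
        out = harmonize_batches(t, "batch", self.REGIONS, preserve=("sex", "age"))
        pd.testing.assert_frame_equal(out, t)

    def test_additive_offset_removed(self, rng):
        t = self._table(rng, offset=5.0)
        out = harmonize_batches(t, "batch", self.REGIONS, preserve=("sex", "age"))
        for r in self.REGIONS:
            means = out.groupby("batch")[r].mean()
            assert abs(means["b0"] - means["b1"]) < 0.25  # vs 5.0 before

    def test_scale_effect_removed(self, rng):
        t = self._table(rng, scale=3.0)
        out = harmonize_batches(t, "batch", self.REGIONS, preserve=("sex", "age"))
        for r in self.REGIONS:
            sds = out.groupby("batch")[r].std()
            assert 0.8 < sds["b1"] / sds["b0"] < 1.25  # vs 3.0 before

    def test_rejects_singleton_batch(self, rng):
        t = self._table(rng, n=7, n_batches=7)
        with pytest.raises(ValidationError):
            harmonize_batches(t, "batch", self.REGIONS)

    def test_matches_reference_r_implementation(self, tmp_path):
        """Cross-check against the independent empirical-Bayes implementation
        in Bioconductor's sva package (run through Rscript)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        from neurocongruence.synthetic_data import mouse_style_spec, simulate_cohort

        spec = mouse_style_spec(
            n_female=30, n_male=30,
            region_effects={"A": 0.4, "B": -0.2, "C": 0.0, "D": 0.1, "E": 0.3},
            n_batches=3, batch_offset_sd=0.5, batch_scale_range=(0.7, 1.4),
            noise_cv=0.05, seed=11)
        t = simulate_cohort(spec)
        regions = [c for c in t.columns if c.startswith("vol_")]
        mine = harmonize_batches(t, "batch", regions, preserve=("sex", "age"))
        t.to_csv(tmp_path / "dat.csv", index=False)
        rscript = f'''
suppressMessages(library(sva))
t <- read.csv("{tmp_path}/dat.csv", check.names=FALSE)
regions <- grep("^vol_", names(t), value=TRUE)
Y <- t(as.matrix(t[, regions]))
mod <- model.matrix(~ factor(sex, levels=c("F","M")) + I(age - mean(age)), data=t)
out <- ComBat(dat=Y, batch=t$batch, mod=mod, par.prior=TRUE)
write.csv(t(out), "{tmp_path}/combat.csv", row.names=FALSE)
'''
        proc = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"sva unavailable: {proc.stderr[-200:]}")
        ref = pd.read_csv(tmp_path / "combat.csv").to_numpy()
        assert np.allclose(mine[regions].to_numpy(), ref, atol=1e-8)


class TestSummarize:
    def _frame(self, betas, sig):
        return pd.DataFrame({"beta_sex": betas, "significant": sig})

    def test_all_male_biased(self):
        s = summarize_sex_bias(self._frame([0.2, 0.4], [True, True]))
        assert s.pct_male_biased_of_sig == 100.0
        assert s.pct_significant == 100.0

    def test_female_median(self):
        s = summarize_sex_bias(self._frame([-0.1, -0.3, 0.2], [True] * 3))
        assert s.female_median == pytest.approx(-0.2)
        assert s.pct_female_biased_of_sig == pytest.approx(200 / 3)

    def test_empty_significant_set_warns(self, caplog):
        s = summarize_sex_bias(self._frame([0.1, -0.2], [False, False]))
        assert s.pct_significant == 0.0
        assert s.pct_male_biased_of_sig == 0.0


class TestOnePerFamily:
    def test_two_families_of_two(self):
        t = pd.DataFrame({"family_id": ["a", "a", "b", "b"], "x": range(4)})
        out = subset_one_per_family(t, seed=1)
        assert len(out) == 2
        assert out["family_id"].nunique() == 2

    def test_singletons_identity(self):
        t = pd.DataFrame({"family_id": list("abcd"), "x": range(4)})
        pd.testing.assert_frame_equal(subset_one_per_family(t, seed=9), t)

    def test_deterministic(self):
        t = pd.DataFrame({"family_id": ["a"] * 3 + ["b"] * 4, "x": range(7)})
        a = subset_one_per_family(t, seed=42)
        b = subset_one_per_family(t, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_column(self):
        with pytest.raises(ValidationError):
            subset_one_per_family(pd.DataFrame({"x": [1]}), seed=0)
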