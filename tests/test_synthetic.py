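"""Synthetic cohort generator: construction constraints, determinism,
spectrum consistency, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import sigimmune as si
from sigimmune import synthetic as syn
from sigimmune.signatures import CONTEXT_CLASSES

STOPS = {"TAA", "TAG", "TGA"}


def _codons(seq):
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


class TestConfig:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError, match="cds_length_range"):
            syn.SyntheticCohortConfig(cds_length_range=(20, 50))
        with pytest.raises(ValueError, match="gc_content"):
            syn.SyntheticCohortConfig(gc_content=1.5)
        with pytest.raises(ValueError, match="unknown signature"):
            syn.SyntheticCohortConfig(signature_ids=("age_like", "nope"),
                                      charge_signature="age_like")

    def test_defaults_valid(self):
        cfg = syn.SyntheticCohortConfig()
        assert cfg.n_samples == 266


class TestReferenceCds:
    def test_construction_constraints(self):
        cfg = syn.SyntheticCohortConfig(n_genes=5, cds_length_range=(30, 33), seed=1)
        cds = syn.generate_reference_cds(cfg)
        assert len(cds) == 5
        for seq in cds.values():
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG")
            codons = _codons(seq)
            assert codons[-1] in STOPS
            assert not any(c in STOPS for c in codons[:-1])

    def test_same_seed_identical_fasta(self, tmp_path):
        cfg = syn.SyntheticCohortConfig(n_genes=4, cds_length_range=(90, 150), seed=9)
        a, b = tmp_path / "a.fa", tmp_path / "b.fa"
        syn.write_fasta(syn.generate_reference_cds(cfg), a)
        syn.write_fasta(syn.generate_reference_cds(cfg), b)
        assert a.read_bytes() == b.read_bytes()

    def test_pooled_gc_near_target(self):
        cfg = syn.SyntheticCohortConfig(
            n_genes=100, cds_length_range=(999, 999), gc_content=0.5, seed=2
        )
        cds = syn.generate_reference_cds(cfg)
        pooled = "".join(cds.values())
        gc = (pooled.count("G") + pooled.count("C")) / len(pooled)
        assert 0.45 <= gc <= 0.55

    def test_unreachable_gc_fails(self):
        # zero retries makes any target unreachable: exercises the error path
        cfg = syn.SyntheticCohortConfig(
            n_genes=1, cds_length_range=(300, 300), gc_content=0.5, seed=3
        )
        with pytest.raises(ValueError, match="GC target"):
            syn.generate_reference_cds(cfg, max_tries=0)


class TestToyCatalog:
    def test_flat_is_uniform(self):
        cat = syn.make_toy_catalog(["flat"])
        assert np.allclose(cat["flat"].values, 1 / 96)

    def test_apobec_ctog_mass_on_tcn(self):
        cat = syn.make_toy_catalog(["apobec_CtoG"])
        tcn = [f"T[C>G]{b}" for b in "ACGT"]
        assert cat.loc[tcn, "apobec_CtoG"].sum() >= 0.9

    def test_apobec_ctot_and_age_like_motifs(self):
        cat = syn.make_toy_catalog(["apobec_CtoT", "age_like"])
        assert cat.loc[[f"T[C>T]{b}" for b in "ACGT"], "apobec_CtoT"].sum() >= 0.9
        assert cat.loc[[f"{b}[C>T]G" for b in "ACGT"], "age_like"].sum() >= 0.9

    def test_columns_sum_to_one(self):
        cat = syn.make_toy_catalog(list(syn.TOY_SIGNATURE_IDS))
        assert np.allclose(cat.sum(axis=0), 1.0, atol=1e-9)
        assert (cat.values >= 0).all()

    def test_unknown_id_lists_supported(self):
        with pytest.raises(ValueError, match="supported"):
            syn.make_toy_catalog(["cosmic_99"])


@pytest.fixture(scope="module")
def cds():
    cfg = syn.SyntheticCohortConfig(n_genes=15, cds_length_range=(600, 900), seed=4)
    return syn.generate_reference_cds(cfg)


class TestSimulateMutations:

    def test_record_counts(self, cds, toy_catalog):
        rng = np.random.default_rng(0)
        expo = pd.DataFrame(
            np.full((20, 4), 0.25), columns=toy_catalog.columns,
            index=[f"s{i}" for i in range(20)],
        )
        muts = syn.simulate_mutations(cds, toy_catalog, expo, 500, rng)
        assert len(muts) == 10_000
        assert (muts.groupby("sample_id").size() == 500).all()

    def test_degenerate_single_class_profile(self, cds):
        cat = pd.DataFrame(0.0, index=CONTEXT_CLASSES, columns=["only"])
        cat.loc["T[C>A]A", "only"] = 1.0
        expo = pd.DataFrame([[1.0]], index=["s1"], columns=["only"])
        muts = syn.simulate_mutations(cds, cat, expo, 200, np.random.default_rng(1))
        assert (muts["context"] == "T[C>A]A").all()
        # records are consistent with the reference and class
        reclassified = si.classify_mutations(muts, cds)
        assert (reclassified["context"] == "T[C>A]A").all()

    def test_flat_profile_spectrum_uniform_over_available(self, cds):
        """Pooled spectrum from the flat profile passes a chi-square GOF test
        against uniform over the 96 classes."""
        cat = syn.make_toy_catalog(["flat"])
        expo = pd.DataFrame([[1.0]], index=["s1"], columns=["flat"])
        muts = syn.simulate_mutations(cds, cat, expo, 50_000, np.random.default_rng(2))
        observed = si.build_spectrum(muts).values
        stat, p = sps.chisquare(observed)
        assert p > 0.01

    def test_ground_truth_labels_present(self, cds, toy_catalog):
        expo = pd.DataFrame(
            [[0.25, 0.25, 0.25, 0.25]], index=["s1"], columns=toy_catalog.columns
        )
        muts = syn.simulate_mutations(cds, toy_catalog, expo, 300,
                                      np.random.default_rng(3))
        assert set(muts["true_signature"]) <= set(toy_catalog.columns)
        assert (muts["strand"] == "+").all()

    def test_determinism(self, cds, toy_catalog):
        expo = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4]], index=["s1"], columns=toy_catalog.columns
        )
        a = syn.simulate_mutations(cds, toy_catalog, expo, 200, np.random.default_rng(5))
        b = syn.simulate_mutations(cds, toy_catalog, expo, 200, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)


class TestSimulateExpression:
    samples = [f"s{i}" for i in range(50)]

    def _covariates(self, rng):
        return pd.DataFrame(
            {"burden": rng.poisson(100, len(self.samples))}, index=self.samples
        )

    def test_zero_effect_no_correlation(self):
        rng = np.random.default_rng(0)
        cov = self._covariates(rng)
        spec = {"M": {"genes": [f"m{i}" for i in range(10)],
                      "covariate": "burden", "effect": 0.0}}
        mat = syn.simulate_expression(self.samples, spec, cov, 0.5, rng)
        mean = mat.loc[spec["M"]["genes"]].mean(axis=0)
        r = np.corrcoef(mean.values, cov["burden"].values)[0, 1]
        assert abs(r) < 0.2

    def test_noiseless_limit_is_affine(self):
        rng = np.random.default_rng(1)
        cov = self._covariates(rng)
        spec = {"M": {"genes": ["m1", "m2"], "covariate": "burden", "effect": 1.0}}
        mat = syn.simulate_expression(self.samples, spec, cov, 0.0, rng,
                                      n_background=0)
        mean = mat.mean(axis=0).values
        z = (cov["burden"] - cov["burden"].mean()) / cov["burden"].std(ddof=0)
        np.testing.assert_allclose(mean - mean.mean(), z.values, atol=1e-10)

    def test_planted_effect_detected_across_seeds(self):
        """Effect 0.8 on a 200-sample cohort: module-mean vs covariate
        correlation exceeds 0.5 in nearly all seeds."""
        samples = [f"s{i}" for i in range(200)]
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cov = pd.DataFrame({"burden": rng.poisson(100, 200)}, index=samples)
            spec = {"M": {"genes": [f"m{i}" for i in range(20)],
                          "covariate": "burden", "effect": 0.8}}
            mat = syn.simulate_expression(samples, spec, cov, 0.5, rng,
                                          n_background=0)
            mean = mat.mean(axis=0)
            if np.corrcoef(mean.values, cov["burden"].values)[0, 1] > 0.5:
                hits += 1
        assert hits >= int(0.95 * n_seeds)

    def test_overlapping_modules_fail(self):
        rng = np.random.default_rng(2)
        cov = self._covariates(rng)
        spec = {
            "A": {"genes": ["g1", "g2"], "covariate": "burden", "effect": 1.0},
            "B": {"genes": ["g2", "g3"], "covariate": "burden", "effect": 1.0},
        }
        with pytest.raises(ValueError, match="overlap"):
            syn.simulate_expression(self.samples, spec, cov, 0.5, rng)

    def test_missing_rate_applied(self):
        rng = np.random.default_rng(3)
        cov = self._covariates(rng)
        mat = syn.simulate_expression(self.samples, {}, cov, 0.5, rng,
                                      n_background=100, missing_rate=0.1)
        frac = mat.isna().values.mean()
        assert 0.05 < frac < 0.15


class TestSimulateClinical:
    def _scores(self, rng, n=100):
        return pd.DataFrame({
            "mcc": rng.standard_normal(n), "til": rng.standard_normal(n),
        }, index=[f"s{i}" for i in range(n)])

    def test_zero_censor_rate_all_events(self):
        rng = np.random.default_rng(0)
        clin = syn.simulate_clinical(self._scores(rng), {"mcc": 0.5}, {}, 0.0, rng)
        assert (clin["event"] == 1).all()

    def test_censor_rate_approximately_achieved(self):
        rng = np.random.default_rng(1)
        clin = syn.simulate_clinical(self._scores(rng, 2000), {"mcc": 0.5}, {},
                                     0.3, rng)
        assert 0.25 < (clin["event"] == 0).mean() < 0.35

    def test_infiltrate_three_ordered_levels(self):
        rng = np.random.default_rng(2)
        clin = syn.simulate_clinical(self._scores(rng, 300), {}, {"til": 1.0},
                                     0.2, rng)
        assert set(clin["infiltrate"]) == {0, 1, 2}
        counts = clin["infiltrate"].value_counts()
        assert counts.min() > 60  # tertile cuts keep groups balanced

    def test_non_finite_scores_fail(self):
        rng = np.random.default_rng(3)
        scores = self._scores(rng)
        scores.iloc[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            syn.simulate_clinical(scores, {"mcc": 0.5}, {}, 0.1, rng)

    def test_null_betas_give_uniform_logrank_p(self):
        """With all hazard betas zero, a logrank test between score-defined
        halves rejects at roughly the nominal rate."""
        from sigimmune.stats import km_logrank

        rejections = 0
        n_reps = 200
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            scores = self._scores(rng, 60)
            clin = syn.simulate_clinical(scores, {"mcc": 0.0}, {}, 0.2, rng)
            group = (scores["mcc"] > scores["mcc"].median()).astype(int)
            surv = pd.DataFrame({
                "time": clin["time_months"].values,
                "event": clin["event"].values,
                "group": group.values,
            })
            if km_logrank(surv)[0].p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_reps <= 0.11


class TestWholeCohort:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = syn.SyntheticCohortConfig(
            n_samples=10, n_genes=6, cds_length_range=(300, 450),
            mutations_per_sample_mean=30.0, seed=21,
        )
        pa = syn.write_cohort(syn.simulate_cohort(cfg), tmp_path / "a")
        pb = syn.write_cohort(syn.simulate_cohort(cfg), tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_spectrum_consistency_with_exposures(self, small_cohort, toy_catalog):
        """Pooled spectrum over many samples with heterogeneous exposures is
        within TV 0.05 of the exposure-weighted catalog mixture at 50,000
        pooled mutations."""
        rng = np.random.default_rng(17)
        n_samples, n_each = 25, 2000
        expo = pd.DataFrame(
            rng.dirichlet(np.ones(4), n_samples),
            index=[f"s{i}" for i in range(n_samples)],
            columns=toy_catalog.columns,
        )
        muts = syn.simulate_mutations(small_cohort.cds, toy_catalog, expo,
                                      n_each, rng)
        mixture = toy_catalog.values @ expo.values.mean(axis=0)
        observed = si.build_spectrum(muts).values
        observed = observed / observed.sum()
        tv = 0.5 * np.abs(observed - mixture).sum()
        assert tv < 0.05

    def test_planted_infiltrate_dependence(self, small_cohort):
        infl = small_cohort.clinical["infiltrate"]
        counts = small_cohort.covariates["charge_increase_apobec_CtoG"]
        res = si.cuzick_trend(counts.values, infl.values)
        assert res.z > 0
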