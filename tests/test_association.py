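"""Association scans, BH FDR, LD pruning, metabolite-phenotype linkage."""

import numpy as np
import pandas as pd
import pytest

from magsnv.association import (
    bh_fdr,
    genotype_r2,
    ld_prune,
    metabolite_phenotype_link,
    snv_group_scan,
    snv_trait_scan,
)
from magsnv.io import FeatureTable, SampleMeta, SiteKey
from magsnv.matrix import BinarySnvGenotypes
from magsnv.simulate import simulate_group_panel, simulate_trait_panel


def bh_oracle(p):
    """Literal step-up definition: q_i = min_{p_(j) >= p_i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    order = np.argsort(pv, kind="stable")
    q = np.full(p.shape, np.nan)
    qv = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [
            pv[order[j]] * m / (j + 1) for j in range(pos, m)
        ]
        qv[idx] = min(1.0, min(candidates))
    q[ok] = qv
    return q


class TestBhFdr:
    def test_worked_case(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m counts only the two non-missing values
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(100)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            p = rng.random(n)
            p[rng.random(n) < 0.1] = np.nan
            q = bh_fdr(p)
            np.testing.assert_allclose(q, bh_oracle(p), atol=0, rtol=0)
            ok = ~np.isnan(p)
            if ok.sum():
                _, q_sm, _, _ = multipletests(p[ok], method="fdr_bh")
                np.testing.assert_allclose(q[ok], q_sm, atol=1e-12)


def make_geno(genotype, mags=None):
    genotype = np.asarray(genotype, dtype=np.float32)
    n_sites, n_samples = genotype.shape
    keys = [SiteKey(f"s{i}", i, "A") for i in range(n_sites)]
    mags = mags or ["magA"] * n_sites
    return BinarySnvGenotypes(
        site_keys=keys,
        sample_ids=[f"S{j}" for j in range(n_samples)],
        genotype=genotype,
        allele_map=[("A", "C")] * n_sites,
        presence_fraction=np.ones(n_sites),
        minor_allele_fraction=np.full(n_sites, 0.3),
        site_to_mag=dict(zip(keys, mags)),
    )


def make_meta(n, groups=("CON", "RMT", "RFT"), days=(15, 35, 56)):
    per = n // len(groups)
    return [
        SampleMeta(f"S{j}", f"S{j}", groups[min(j // per, 2)], days[j % 3])
        for j in range(n)
    ]


def make_traits(values, kinds=None):
    df = pd.DataFrame(
        np.asarray(values, dtype=float).T,
        index=[f"S{j}" for j in range(np.asarray(values).shape[1])],
        columns=[f"t{i}" for i in range(np.asarray(values).shape[0])],
    )
    return FeatureTable(df, kinds)


class TestTraitScan:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        g = (rng.random(30) < 0.5).astype(float)
        geno = make_geno(g[None, :])
        traits = make_traits([2.0 * g])
        out = snv_trait_scan(geno, traits, make_meta(30), covariate_day=False)
        row = out.iloc[0]
        assert row.estimate == pytest.approx(2.0, abs=1e-10)
        assert row.p == 0.0 and row.model == "linear"

    def test_monomorphic_skipped(self):
        geno = make_geno(np.ones((1, 30)))
        traits = make_traits([np.random.default_rng(1).normal(size=30)])
        out = snv_trait_scan(geno, traits, make_meta(30))
        assert out.iloc[0].skip_reason == "monomorphic"
        assert np.isnan(out.iloc[0].p)

    def test_min_samples_and_class_count(self):
        rng = np.random.default_rng(2)
        g = np.array([1.0, 1.0] + [0.0] * 28)  # only 2 carriers
        geno = make_geno(g[None, :])
        traits = make_traits([rng.normal(size=30)])
        out = snv_trait_scan(geno, traits, make_meta(30))
        assert out.iloc[0].skip_reason == "min_class_count"
        out = snv_trait_scan(geno, traits, make_meta(30), min_n=40)
        assert out.iloc[0].skip_reason == "too_few_samples"

    def test_agrees_with_statsmodels_and_normal_equations(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        meta = make_meta(40)
        days = np.array([m.day for m in meta], dtype=float)
        for _ in range(50):
            g = (rng.random(40) < rng.uniform(0.2, 0.6)).astype(float)
            if g.sum() < 3 or g.sum() > 37:
                continue
            y = rng.normal(size=40) + rng.normal() * g + 0.01 * days
            geno = make_geno(g[None, :])
            out = snv_trait_scan(geno, make_traits([y]), meta)
            row = out.iloc[0]
            X = sm.add_constant(np.column_stack([g, days]))
            ref = sm.OLS(y, X).fit()
            assert row.estimate == pytest.approx(ref.params[1], abs=1e-8)
            assert row.std_error == pytest.approx(ref.bse[1], abs=1e-8)
            assert row.p == pytest.approx(ref.pvalues[1], abs=1e-8)
            # independent closed form via the normal equations
            beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
            assert row.estimate == pytest.approx(beta_ne[1], abs=1e-8)

    def test_binary_trait_logistic_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = 90
        g = (rng.random(n) < 0.5).astype(float)
        meta = make_meta(n)
        days = np.array([m.day for m in meta], dtype=float)
        prob = 1 / (1 + np.exp(-(-0.3 + 1.2 * g)))
        y = (rng.random(n) < prob).astype(float)
        geno = make_geno(g[None, :])
        out = snv_trait_scan(geno, make_traits([y], kinds={"t0": "binary"}), meta)
        row = out.iloc[0]
        assert row.model == "logistic"
        X = sm.add_constant(np.column_stack([g, days]))
        ref = sm.Logit(y, X).fit(disp=0)
        assert row.estimate == pytest.approx(ref.params[1], abs=1e-6)
        assert row.p == pytest.approx(ref.pvalues[1], rel=1e-5)

    def test_separation_flagged_not_fitted(self):
        n = 30
        g = np.array([1.0] * 15 + [0.0] * 15)
        geno = make_geno(g[None, :])
        out = snv_trait_scan(
            geno, make_traits([g], kinds={"t0": "binary"}), make_meta(n),
            covariate_day=False,
        )
        assert out.iloc[0].skip_reason == "separation_or_nonconvergence"
        assert np.isnan(out.iloc[0].p)

    def test_invariant_to_site_and_trait_order(self):
        rng = np.random.default_rng(7)
        G = (rng.random((4, 36)) < 0.4).astype(float)
        T = rng.normal(size=(3, 36))
        meta = make_meta(36)
        a = snv_trait_scan(make_geno(G), make_traits(T), meta)
        perm_sites, perm_traits = [2, 0, 3, 1], [1, 2, 0]
        g2 = make_geno(G[perm_sites])
        t2 = FeatureTable(
            make_traits(T).data.iloc[:, perm_traits]
        )
        b = snv_trait_scan(g2, t2, meta)
        key = ["site", "trait_id"]
        a_sorted = a.sort_values(key).reset_index(drop=True)
        b_sorted = b.sort_values(key).reset_index(drop=True)
        # sites were renamed by make_geno; compare via estimates per pair
        merged = a_sorted.merge(b_sorted, on="trait_id", suffixes=("_a", "_b"))
        merged = merged[
            np.isclose(merged.estimate_a, merged.estimate_b, equal_nan=True)
        ]
        assert len(merged) >= len(a)

    def test_per_trait_fdr_flag(self):
        rng = np.random.default_rng(9)
        G = (rng.random((5, 36)) < 0.4).astype(float)
        T = rng.normal(size=(2, 36))
        meta = make_meta(36)
        out = snv_trait_scan(make_geno(G), make_traits(T), meta, fdr_per_trait=True)
        for _, sub in out.groupby("trait_id"):
            np.testing.assert_allclose(
                sub["q"].to_numpy(), bh_oracle(sub["p"].to_numpy()), atol=1e-12
            )


class TestGroupScan:
    def test_no_group_difference_p_one(self):
        g = np.array([0.0, 1.0] * 18)  # identical pattern in every group
        out = snv_group_scan(make_geno(g[None, :]), make_meta(36))
        assert out.iloc[0].p > 0.5

    def test_perfect_separation_flagged(self):
        meta = make_meta(36)
        g = np.array([1.0 if m.group == "RMT" else 0.0 for m in meta])
        out = snv_group_scan(make_geno(g[None, :]), meta)
        assert out.iloc[0].skip_reason == "separation_or_nonconvergence"

    def test_planted_shift_recovered(self):
        geno, meta, causal = simulate_group_panel(seed=4, n_sites=60, n_causal=20)
        out = snv_group_scan(geno, meta)
        hits = set(out.loc[out["q"] < 0.05, "site"])
        sens = len(hits & set(causal)) / len(causal)
        assert sens >= 0.8
        null_sites = set(out["site"]) - set(causal)
        assert len(hits & null_sites) <= 2

    def test_estimate_sign_matches_shift_direction(self):
        geno, meta, causal = simulate_group_panel(seed=12, n_sites=30, n_causal=10)
        out = snv_group_scan(geno, meta)
        causal_rows = out[out["site"].isin(causal) & (out.skip_reason == "")]
        assert (causal_rows["estimate"] > 0).mean() > 0.8


class TestLdPrune:
    def test_duplicate_sites_keep_best_p(self):
        g = np.tile((np.arange(20) < 8).astype(float), (2, 1))
        geno = make_geno(g)
        records = pd.DataFrame(
            dict(
                site=[str(k) for k in geno.site_keys],
                mag_id=["magA", "magA"],
                trait_id=["t0", "t0"],
                p=[1e-9, 1e-10],
            )
        )
        out = ld_prune(records, geno)
        assert list(out.kept["p"]) == [1e-10]
        ((kept_key, removals),) = out.pruned.items()
        assert removals[0][1] == pytest.approx(1.0)

    def test_different_mags_both_kept(self):
        g = np.tile((np.arange(20) < 8).astype(float), (2, 1))
        geno = make_geno(g, mags=["magA", "magB"])
        records = pd.DataFrame(
            dict(
                site=[str(k) for k in geno.site_keys],
                mag_id=["magA", "magB"],
                trait_id=["t0", "t0"],
                p=[1e-9, 1e-10],
            )
        )
        out = ld_prune(records, geno)
        assert len(out.kept) == 2 and not out.pruned

    def test_missing_site_errors(self):
        geno = make_geno(np.zeros((1, 10)))
        records = pd.DataFrame(
            dict(site=["nope:0:A"], mag_id=["magA"], trait_id=["t0"], p=[0.01])
        )
        with pytest.raises(KeyError):
            ld_prune(records, geno)

    @staticmethod
    def prune_oracle(records, geno, thr):
        """Re-derivation of the greedy contract by explicit simulation."""
        site_row = {str(k): i for i, k in enumerate(geno.site_keys)}
        kept = []
        for (mag, trait), sub in records.groupby(["mag_id", "trait_id"], sort=True):
            pool = list(
                sub.sort_values(["p", "site"], kind="stable").itertuples()
            )
            while pool:
                best = pool.pop(0)
                kept.append(best.Index)
                gb = geno.genotype[site_row[best.site]].astype(float)
                pool = [
                    r
                    for r in pool
                    if not (
                        (r2 := genotype_r2(gb, geno.genotype[site_row[r.site]].astype(float)))
                        == r2
                        and r2 > thr
                    )
                ]
        return sorted(kept)

    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(55)
        for _ in range(40):
            n_rec = int(rng.integers(2, 11))
            n_samples = 30
            # correlated blocks: sites drawn as noisy copies of a few factors
            factors = (rng.random((3, n_samples)) < 0.5).astype(float)
            G = np.empty((n_rec, n_samples), dtype=np.float32)
            for i in range(n_rec):
                base = factors[rng.integers(3)].copy()
                flip = rng.random(n_samples) < 0.1
                base[flip] = 1 - base[flip]
                G[i] = base
            mags = [f"mag{rng.integers(2)}" for _ in range(n_rec)]
            geno = make_geno(G, mags=mags)
            records = pd.DataFrame(
                dict(
                    site=[str(k) for k in geno.site_keys],
                    mag_id=mags,
                    trait_id=[f"t{rng.integers(2)}" for _ in range(n_rec)],
                    p=rng.random(n_rec),
                )
            )
            got = sorted(ld_prune(records, geno, 0.6).kept.index)
            want = self.prune_oracle(records, geno, 0.6)
            assert got == want


class TestCalibrationSmoke:
    def test_null_panel_uniformish_p(self):
        geno, traits, meta, _ = simulate_trait_panel(
            seed=2, n_sites=100, n_traits=10, n_causal=0
        )
        out = snv_trait_scan(geno, traits, meta)
        fitted = out[out.skip_reason == ""]
        assert (fitted["q"] < 0.05).sum() == 0
        assert 0.2 < (fitted["p"] < 0.5).mean() < 0.8

    def test_planted_effects_recovered_and_unbiased(self):
        geno, traits, meta, causal = simulate_trait_panel(seed=3)
        out = snv_trait_scan(geno, traits, meta)
        causal_pairs = {(s, t) for s, t, _ in causal}
        hits = out[
            out.apply(lambda r: (r.site, r.trait_id) in causal_pairs, axis=1)
        ]
        assert (hits["q"] < 0.05).mean() >= 0.7
        assert hits["estimate"].mean() == pytest.approx(1.0, rel=0.15)


class TestMetabolitePhenotypeLink:
    def test_identical_feature_rho_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=36)
        meta = make_meta(36)
        mets = make_traits([x])
        phens = FeatureTable(
            pd.DataFrame({"p0": x}, index=[f"S{j}" for j in range(36)])
        )
        df, overlap = metabolite_phenotype_link(mets, phens, meta)
        assert df.iloc[0].rho == pytest.approx(1.0)
        assert df.iloc[0].q < 1e-6

    def test_independent_features_alpha_control(self):
        rng = np.random.default_rng(13)
        mets = make_traits(rng.normal(size=(20, 60)))
        phens = FeatureTable(
            pd.DataFrame(
                rng.normal(size=(60, 5)),
                index=[f"S{j}" for j in range(60)],
                columns=[f"p{i}" for i in range(5)],
            )
        )
        df, _ = metabolite_phenotype_link(mets, phens, make_meta(60))
        assert (df["q"] < 0.05).sum() == 0

    def test_planted_chain_reaches_overlap_report(self, default_study, study_geno):
        """SNV -> metabolite -> phenotype chain surfaces in the overlap."""
        out = snv_trait_scan(
            study_geno, default_study.metabolites, default_study.meta
        )
        snv_mets = sorted(set(out.loc[out["q"] < 0.05, "trait_id"]))
        df, overlap = metabolite_phenotype_link(
            default_study.metabolites,
            default_study.phenotypes,
            default_study.meta,
            snv_metabolites=snv_mets,
        )
        planted_chain = default_study.truth.phenotype_spec[0]["metabolite"]
        assert planted_chain in overlap
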