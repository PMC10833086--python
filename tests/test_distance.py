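"""K2P distances, normalization, strain clustering, time enrichment."""

import math

import numpy as np
import pytest
from scipy.special import comb

from magsnv.distance import (
    cluster_strains,
    k2p_distance,
    linkage_to_newick,
    mag_distance_matrix,
    MagDistanceMatrix,
    normalize_distances,
    read_distance_matrix,
    strain_time_enrichment,
    write_distance_matrix,
)
from magsnv.io import SampleMeta
from magsnv.matrix import MISSING


def seq(text):
    """Encode an ACGT/N string (N = missing)."""
    return np.array(
        ["ACGT".index(c) if c in "ACGT" else -1 for c in text], dtype=np.int8
    )


def k2p_oracle(a, b, min_overlap=10):
    """Independent count-and-formula implementation (explicit loop)."""
    n = ts = tv = 0
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        n += 1
        if x != y:
            if (x, y) in transitions:
                ts += 1
            else:
                tv += 1
    if n < min_overlap:
        return float("nan")
    p, q = ts / n, tv / n
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        return float("nan")
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def random_pair(rng, length=120, miss=0.2):
    alphabet = np.array(list("ACGTN"))
    probs = [(1 - miss) / 4] * 4 + [miss]
    return (
        "".join(rng.choice(alphabet, p=probs) for _ in range(length)),
        "".join(rng.choice(alphabet, p=probs) for _ in range(length)),
    )


class TestK2P:
    def test_identity_is_zero(self):
        s = seq("ACGT" * 25)
        assert k2p_distance(s, s) == 0.0

    def test_worked_example(self):
        # 100 overlapping sites, 10 transitions, 5 transversions
        a = seq("A" * 100)
        b = seq("G" * 10 + "C" * 5 + "A" * 85)
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.90)
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.170181, abs=1e-6)

    def test_saturation_returns_missing(self):
        a = seq("A" * 100)
        b = seq("G" * 50 + "A" * 50)  # P = 0.5, Q = 0
        assert math.isnan(k2p_distance(a, b))

    def test_below_min_overlap_missing(self):
        a = seq("ACGTACGTA" + "N" * 91)
        b = seq("ACGTACGTA" + "N" * 91)
        assert math.isnan(k2p_distance(a, b, min_overlap=10))
        assert k2p_distance(a, b, min_overlap=9) == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            k2p_distance(seq("ACGT"), seq("ACG"))

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a, b = random_pair(rng)
            got = k2p_distance(seq(a), seq(b))
            want = k2p_oracle(a, b)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b = random_pair(rng)
            fwd = k2p_distance(seq(a), seq(b))
            rev = k2p_distance(seq(b), seq(a))
            assert (math.isnan(fwd) and math.isnan(rev)) or fwd == rev

    def test_monotone_in_transition_count(self):
        base = "A" * 200
        prev = -1.0
        for n_ts in range(0, 60, 5):
            other = "G" * n_ts + "A" * (200 - n_ts)
            d = k2p_distance(seq(base), seq(other))
            assert d > prev
            prev = d


class TestMagDistanceMatrix:
    def test_identical_samples_zero_offdiagonal(self, default_study):
        m = default_study.to_matrix()
        truth = default_study.truth
        mag = truth.mags[0]
        dm = mag_distance_matrix(m, mag)
        assert np.allclose(np.diag(dm.distance), 0.0)
        assert np.allclose(dm.distance, dm.distance.T, equal_nan=True)

    def test_vectorized_equals_per_pair_calls(self, default_study):
        m = default_study.to_matrix()
        mag = default_study.truth.mags[2]
        sub = m.sample_ids[:12]
        dm = mag_distance_matrix(m, mag, samples=sub)
        rows = m.sites_of_mag(mag)
        cons = m.consensus[rows]
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                want = k2p_distance(cons[:, i], cons[:, j])
                got = dm.distance[i, j]
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_disjoint_sites_give_missing_and_zero_overlap(self):
        from magsnv.io import SiteKey
        from magsnv.matrix import SnvMatrix

        keys = [SiteKey("s1", i, "A") for i in range(20)]
        cons = np.full((20, 2), MISSING, dtype=np.int8)
        cons[:10, 0] = 0
        cons[10:, 1] = 1
        m = SnvMatrix(keys, ["x", "y"], cons, {k: "magA" for k in keys})
        dm = mag_distance_matrix(m, "magA")
        assert math.isnan(dm.distance[0, 1])
        assert dm.overlap[0, 1] == 0

    def test_noise_free_two_strain_expectation(self):
        """Between-strain distance equals the closed form of the truth split."""
        from magsnv.simulate import SimulationConfig, simulate_study

        cfg = SimulationConfig(
            seed=5, n_mags=1, n_rmt_mags=0, n_temporal_mags=0,
            consensus_error=0.0,
            missingness_by_day=((15, 0.0), (35, 0.0), (56, 0.0)),
            n_planted_snv_effects=0, n_effect_metabolites=0,
        )
        study = simulate_study(cfg)
        truth = study.truth
        mag = truth.mags[0]
        h1, h2 = truth.haplotypes[mag]
        n = len(h1)
        expected = k2p_oracle(h1, h2, min_overlap=1)
        m = study.to_matrix()
        dm = mag_distance_matrix(m, mag)
        strain = truth.strain_assignment[mag]
        ids = dm.sample_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if strain[ids[i]] == strain[ids[j]]:
                    assert dm.distance[i, j] == 0.0
                else:
                    assert dm.distance[i, j] == pytest.approx(expected, abs=1e-12)

    def test_missing_mag_errors(self, study_matrix):
        with pytest.raises(KeyError):
            mag_distance_matrix(study_matrix, "NOPE")


class TestNormalize:
    def _dm(self, dist):
        dist = np.asarray(dist, dtype=float)
        n = dist.shape[0]
        return MagDistanceMatrix(
            "m", [f"S{i}" for i in range(n)], dist, np.full((n, n), 100)
        )

    def test_scaling_example(self):
        dm = self._dm([[0, 0.1, 0.2], [0.1, 0, 0.1], [0.2, 0.1, 0]])
        out = normalize_distances(dm)
        assert out.normalized
        np.testing.assert_allclose(
            out.distance, [[0, 0.5, 1.0], [0.5, 0, 0.5], [1.0, 0.5, 0]]
        )

    def test_all_zero_unchanged(self):
        dm = self._dm(np.zeros((3, 3)))
        out = normalize_distances(dm)
        assert out.normalized
        assert np.all(out.distance == 0)

    def test_max_defined_entry_is_one(self, default_study):
        m = default_study.to_matrix()
        dm = mag_distance_matrix(m, default_study.truth.mags[0])
        out = normalize_distances(dm)
        assert np.nanmax(out.distance) == pytest.approx(1.0)

    def test_preserves_pair_ordering(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0, 0.4, size=(6, 6))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 0)
        dm = self._dm(raw)
        out = normalize_distances(dm)
        iu = np.triu_indices(6, 1)
        assert (np.argsort(raw[iu]) == np.argsort(out.distance[iu])).all()


class TestClustering:
    def _two_block(self):
        dist = np.ones((6, 6))
        dist[:3, :3] = 0.0
        dist[3:, 3:] = 0.0
        np.fill_diagonal(dist, 0)
        return MagDistanceMatrix(
            "m", [f"S{i}" for i in range(6)], dist, np.full((6, 6), 50), True
        )

    def test_separable_blocks_cut_at_half(self):
        cl = cluster_strains(self._two_block(), height=0.5)
        labs = [cl.labels[f"S{i}"] for i in range(6)]
        assert labs[:3] == [labs[0]] * 3 and labs[3:] == [labs[3]] * 3
        assert labs[0] != labs[3]
        # ties in size -> cluster containing the smallest id is number 1
        assert labs[0] == 1

    def test_k_equals_one(self):
        cl = cluster_strains(self._two_block(), k=1)
        assert set(cl.labels.values()) == {1}

    def test_requires_exactly_one_cut(self):
        with pytest.raises(ValueError):
            cluster_strains(self._two_block(), height=0.5, k=2)
        with pytest.raises(ValueError):
            cluster_strains(self._two_block())

    def test_noise_free_recovery_any_cut(self):
        from sklearn.metrics import adjusted_rand_score

        from magsnv.simulate import SimulationConfig, simulate_study
        from magsnv.distance import mag_distance_matrix

        cfg = SimulationConfig(
            seed=9, n_mags=1, n_rmt_mags=0, n_temporal_mags=0,
            consensus_error=0.0,
            missingness_by_day=((15, 0.0), (35, 0.0), (56, 0.0)),
            n_planted_snv_effects=0, n_effect_metabolites=0,
        )
        study = simulate_study(cfg)
        mag = study.truth.mags[0]
        dm = normalize_distances(mag_distance_matrix(study.to_matrix(), mag))
        truth = study.truth.strain_assignment[mag]
        for cut in (0.1, 0.5, 0.9):
            cl = cluster_strains(dm, height=cut)
            labs = [cl.labels[s] for s in cl.clustered_samples]
            tl = [truth[s] for s in cl.clustered_samples]
            assert adjusted_rand_score(labs, tl) == 1.0

    def test_labels_invariant_to_sample_order(self):
        dm = self._two_block()
        perm = [4, 1, 5, 0, 3, 2]
        dm2 = dm.submatrix([dm.sample_ids[i] for i in perm])
        a = cluster_strains(dm, height=0.5).labels
        b = cluster_strains(dm2, height=0.5).labels
        assert a == b

    def test_too_few_samples_errors(self):
        dist = np.full((3, 3), np.nan)
        np.fill_diagonal(dist, 0)
        dm = MagDistanceMatrix("m", ["a", "b", "c"], dist, np.zeros((3, 3), int), True)
        with pytest.raises(ValueError, match="eligible"):
            cluster_strains(dm, height=0.5)

    def test_newick_export_has_all_leaves(self):
        cl = cluster_strains(self._two_block(), k=2)
        nwk = linkage_to_newick(cl)
        assert nwk.endswith(";")
        for s in cl.clustered_samples:
            assert s in nwk


class TestStrainTimeEnrichment:
    def _meta(self, days):
        return [
            SampleMeta(f"S{i}", f"S{i}", "CON", d) for i, d in enumerate(days)
        ]

    def _clustering(self, labels):
        from magsnv.distance import StrainClustering

        return StrainClustering(
            mag_id="m",
            labels={f"S{i}": lab for i, lab in enumerate(labels)},
            linkage=np.empty((0, 4)),
            clustered_samples=[f"S{i}" for i in range(len(labels))],
            dropped_samples=[],
        )

    def test_perfect_alignment_hypergeometric_p(self):
        # cluster 1 exactly on day 15 in a 6 vs 6 design: p = 2 / C(12,6)
        cl = self._clustering([1] * 6 + [2] * 6)
        meta = self._meta([15] * 6 + [56] * 6)
        out = strain_time_enrichment(cl, meta)
        row = out[(out.cluster == 1) & (out.day == 15)].iloc[0]
        assert row.p == pytest.approx(2 / comb(12, 6, exact=True), rel=1e-9)
        assert (out.q <= 1).all()

    def test_independence_gives_p_one(self):
        cl = self._clustering([1, 1, 1, 2, 2, 2] * 2)
        meta = self._meta([15, 15, 56, 15, 56, 56, 56, 15, 56, 15, 56, 15])
        out = strain_time_enrichment(cl, meta)
        balanced = out[(out.cluster == 1) & (out.day == 15)].iloc[0]
        assert balanced.a == 3 and balanced.p == pytest.approx(1.0)

    def test_single_cluster_empty_result(self):
        cl = self._clustering([1] * 8)
        meta = self._meta([15] * 4 + [56] * 4)
        assert strain_time_enrichment(cl, meta).empty


class TestDistanceIO:
    def test_export_import_round_trip(self, default_study, tmp_path):
        m = default_study.to_matrix()
        dm = normalize_distances(
            mag_distance_matrix(m, default_study.truth.mags[0])
        )
        path = tmp_path / "d.tsv"
        write_distance_matrix(dm, path)
        back = read_distance_matrix(path)
        assert back.mag_id == dm.mag_id
        assert back.normalized
        assert back.sample_ids == dm.sample_ids
        np.testing.assert_allclose(back.distance, dm.distance, atol=1e-9)
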