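"""Template identification: TAAHC, k-means, GEV, CV criterion, matching."""

import numpy as np
import pytest

from microstates import (cv_criterion, derive_maps, find_gfp_peaks,
                         first_level_maps, gev, kmeans_microstates,
                         make_template_maps, match_labels, taahc)
from microstates.clustering import MapSet, _normalize_rows


def noisy_duplicates(templates, n_copies=10, noise=0.02, seed=0):
    """Each template duplicated with tiny noise, random polarity and scale."""
    rng = np.random.default_rng(seed)
    maps, labels = [], []
    for k, t in enumerate(templates):
        for _ in range(n_copies):
            m = t + noise * rng.standard_normal(t.shape)
            m *= rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0)
            maps.append(m)
            labels.append(k)
    order = rng.permutation(len(maps))
    return np.array(maps)[order], np.array(labels)[order]


def recovery(mapset, templates):
    """Best |corr| of each template against the recovered maps."""
    n = templates.shape[1]
    corr = np.abs(_normalize_rows(mapset.maps) @
                  _normalize_rows(templates).T) / n
    return corr.max(axis=0)


@pytest.fixture(scope="module")
def separated(templates30):
    return noisy_duplicates(templates30, n_copies=10, noise=0.02, seed=1)


class TestTaahc:
    def test_recovers_separated_clusters(self, separated, templates30):
        maps, _ = separated
        mapset, assignment = taahc(maps, 4)
        assert (recovery(mapset, templates30) >= 0.99).all()
        assert gev(maps, mapset, assignment) > 0.95

    def test_k_equals_m_gives_perfect_gev(self, rng):
        maps = rng.standard_normal((5, 8))
        mapset, assignment = taahc(maps, 5)
        assert gev(maps, mapset, assignment) == pytest.approx(1.0, abs=1e-12)

    def test_polarity_invariance_single_cluster(self, rng):
        u = rng.standard_normal(10)
        mapset, assignment = taahc(np.vstack([u, -u]), 1)
        corr = np.abs(_normalize_rows(np.vstack([u, -u])) @
                      mapset.maps[0]) / 10
        np.testing.assert_allclose(corr, 1.0, atol=1e-9)

    def test_deterministic_for_identical_input(self, separated):
        maps, _ = separated
        a, _ = taahc(maps, 4)
        b, _ = taahc(maps, 4)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_k_larger_than_m_rejected(self, rng):
        with pytest.raises(ValueError):
            taahc(rng.standard_normal((3, 8)), 4)

    def test_output_maps_are_zero_mean_unit_gfp(self, separated):
        mapset, _ = taahc(separated[0], 4)
        np.testing.assert_allclose(mapset.maps.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(
            np.sqrt((mapset.maps**2).mean(axis=1)), 1.0, atol=1e-9)


class TestKmeans:
    def test_recovers_separated_clusters(self, separated, templates30):
        maps, _ = separated
        mapset, _ = kmeans_microstates(maps, 4, restarts=20, seed=3)
        assert (recovery(mapset, templates30) >= 0.99).all()

    def test_more_restarts_never_hurt(self, rng):
        maps = rng.standard_normal((40, 10))  # unstructured = hard
        one, _ = kmeans_microstates(maps, 4, restarts=1, seed=5)
        many, _ = kmeans_microstates(maps, 4, restarts=300, seed=5)
        assert many.gev_on_source >= one.gev_on_source - 1e-12

    def test_reproducible_under_fixed_seed(self, separated):
        maps, _ = separated
        a, _ = kmeans_microstates(maps, 4, restarts=10, seed=7)
        b, _ = kmeans_microstates(maps, 4, restarts=10, seed=7)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_fewer_distinct_maps_than_k_rejected(self):
        u = np.array([1.0, -1.0, 0.5, -0.5])
        maps = np.vstack([u, u, 2 * u, -u])
        with pytest.raises(ValueError):
            kmeans_microstates(maps, 3, restarts=1, seed=0)


class TestGev:
    def test_perfect_assignment_explains_everything(self, rng):
        T = _normalize_rows(rng.standard_normal((2, 8)))
        maps = np.vstack([3.0 * T[0], 0.5 * T[1], -2.0 * T[0]])
        assert gev(maps, T, np.array([0, 1, 0])) == pytest.approx(1.0,
                                                                  abs=1e-12)

    def test_orthogonal_map_contributes_nothing(self):
        t = np.array([1.0, -1.0, 0.0, 0.0])
        u = np.array([0.0, 0.0, 1.0, -1.0])
        assert gev(np.vstack([u]), np.vstack([t]), np.array([0])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_map_toy_case_matches_brute_force(self):
        # hand-checkable: two maps, two templates, both assignments
        t1 = np.array([1.0, -1.0, 1.0, -1.0])
        t2 = np.array([1.0, 1.0, -1.0, -1.0])
        m1 = 2.0 * t1
        m2 = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to both
        maps = np.vstack([m1, m2])
        T = np.vstack([t1, t2])
        # GFPs: 2 and 1; correlations: (1, 0) for m1, (0, 0) for m2
        expected_best = (2.0 * 1.0) ** 2 / (2.0**2 + 1.0**2)
        assert gev(maps, T, np.array([0, 0])) == pytest.approx(expected_best)
        assert gev(maps, T, np.array([0, 1])) == pytest.approx(expected_best)
        assert gev(maps, T, np.array([1, 0])) == pytest.approx(
            0.0 / 5.0, abs=1e-12)


class TestCvCriterion:
    def test_perfect_fit_has_zero_cv(self, rng):
        T = _normalize_rows(rng.standard_normal((2, 10)))
        maps = np.vstack([2 * T[0], -3 * T[1]])
        assert cv_criterion(maps, T, np.array([0, 1])) == pytest.approx(
            0.0, abs=1e-12)

    def test_k_near_electrode_count_rejected(self, rng):
        maps = rng.standard_normal((10, 5))
        T = _normalize_rows(rng.standard_normal((4, 5)))
        with pytest.raises(ValueError):
            cv_criterion(maps, T, np.zeros(10, dtype=int))

    def test_toy_case_matches_hand_residuals(self):
        t = np.array([1.0, -1.0, 1.0, -1.0])  # unit GFP
        u = np.array([1.0, -1.0, -1.0, 1.0]) + t  # residual is orthogonal part
        maps = np.vstack([u])
        # centered u = u; projection onto t: (u·t)/4 = 1 → explained 4·1²
        resid = np.sum(u**2) - (u @ t) ** 2 / 4
        sigma2 = resid / (1 * (4 - 1))
        expected = sigma2 * ((4 - 1) / (4 - 1 - 1)) ** 2
        assert cv_criterion(maps, np.vstack([t]), np.array([0])) == \
            pytest.approx(expected)


class TestMatchLabels:
    @pytest.fixture()
    def reference(self, templates30, montage30):
        return MapSet(maps=templates30, labels=("A", "B", "C", "D"),
                      channel_labels=montage30.labels)

    def test_reference_matches_itself_identically(self, reference):
        out = match_labels(reference, reference)
        assert out.labels == reference.labels
        np.testing.assert_allclose(out.maps, reference.maps, atol=1e-9)

    def test_polarity_flips_do_not_change_matching(self, reference):
        flipped = MapSet(maps=reference.maps * np.array([[-1], [1], [-1], [1]]),
                         labels=("1", "2", "3", "4"))
        out = match_labels(flipped, reference)
        assert out.labels == ("A", "B", "C", "D")
        np.testing.assert_allclose(out.maps, reference.maps, atol=1e-9)

    def test_shuffled_copy_recovers_the_permutation(self, reference):
        perm = [2, 0, 3, 1]
        shuffled = MapSet(maps=reference.maps[perm],
                          labels=("1", "2", "3", "4"))
        out = match_labels(shuffled, reference)
        np.testing.assert_allclose(out.maps, reference.maps, atol=1e-9)


@pytest.fixture(scope="module")
def peaksets(small_study):
    from microstates import standard_chain

    return [find_gfp_peaks(standard_chain(rec))
            for rec in small_study.recordings]


class TestDeriveMaps:
    def test_first_level_yields_k_maps_per_recording(self, peaksets):
        level1 = first_level_maps(peaksets, "taahc", k=4, seed=1)
        assert len(level1) == len(peaksets)
        assert all(ms.k == 4 for ms in level1)
        assert sum(ms.k for ms in level1) == 4 * len(peaksets)

    def test_by_recording_returns_one_mapset_per_recording(self, peaksets):
        out = derive_maps(peaksets, "by_recording", "taahc", seed=1)
        assert len(out) == len(peaksets)
        assert all(ms.labels == ("A", "B", "C", "D") for ms in out.values())

    def test_by_session_returns_one_mapset_per_session(self, peaksets):
        out = derive_maps(peaksets, "by_session", "taahc", seed=1)
        assert set(out) == {ps.session_id for ps in peaksets}

    def test_global_strategy_recovers_generator_templates(self, peaksets,
                                                          small_study):
        out = derive_maps(peaksets, "global", "taahc", seed=1)["global"]
        assert (recovery(out, small_study.templates) >= 0.95).all()

    def test_taahc_and_kmeans_agree_on_global_maps(self, peaksets):
        g_t = derive_maps(peaksets, "global", "taahc", seed=1)["global"]
        g_k = derive_maps(peaksets, "global", "kmeans", restarts=20,
                          seed=1, reference=g_t)["global"]
        n = g_t.maps.shape[1]
        corr = np.abs(np.einsum("ij,ij->i", g_t.maps, g_k.maps)) / n
        assert (corr >= 0.95).all()

    def test_empty_peakset_error_names_the_recording(self, peaksets):
        import dataclasses

        broken = dataclasses.replace(
            peaksets[0], maps=peaksets[0].maps[:0],
            sample_indices=peaksets[0].sample_indices[:0],
            gfp_values=peaksets[0].gfp_values[:0],
            epoch_index=peaksets[0].epoch_index[:0])
        with pytest.raises(ValueError, match=broken.subject_id):
            derive_maps([broken], "global", "taahc")


class TestMapSetIO:
    def test_save_load_round_trip(self, templates30, montage30, tmp_path):
        ms = MapSet(maps=templates30, labels=("A", "B", "C", "D"),
                    algorithm="taahc", strategy="global",
                    channel_labels=montage30.labels, gev_on_source=0.7,
                    seed=3)
        path = tmp_path / "maps.tsv"
        ms.save(path)
        back = MapSet.load(path)
        np.testing.assert_allclose(back.maps, ms.maps, atol=1e-12)
        assert back.labels == ms.labels
        assert back.algorithm == "taahc"
        assert back.gev_on_source == pytest.approx(0.7)
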