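"""Puncta filtering, skeleton resampling, assignment and distance statistics."""

import numpy as np
import pandas as pd
import pytest

from stellate.mapping import (
    Branch,
    FilterCriteria,
    PunctaRecord,
    Skeleton,
    assign_puncta,
    compare_distributions,
    cumulative_distribution,
    distance_histogram,
    filter_puncta,
    pearson_median_skewness,
    puncta_from_table,
    puncta_table,
    resample_skeleton,
    select_somatic_puncta,
    skeleton_from_morphology,
)
from stellate.synthetic import GeneratorConfig, generate_morphology, generate_puncta

CRIT = FilterCriteria(psf_xyz=(0.3, 0.3, 1.1), background_mean=100.0,
                      background_sd=10.0)


def _spot(diam=(0.4, 0.4, 1.3), inten=200.0, soma=0.0, pos=(0, 0, 0)):
    return PunctaRecord(pos, diam, inten, soma_channel_intensity=soma)


class TestFiltering:
    def test_diameter_equal_to_psf_rejected(self):
        assert filter_puncta([_spot(diam=(0.3, 0.3, 1.1))], CRIT) == []

    def test_single_small_axis_rejected(self):
        assert filter_puncta([_spot(diam=(0.4, 0.3, 1.3))], CRIT) == []

    def test_intensity_exactly_threshold_rejected(self):
        assert filter_puncta([_spot(inten=130.0)], CRIT) == []

    def test_passing_spot_kept(self):
        assert len(filter_puncta([_spot()], CRIT)) == 1

    def test_matches_brute_force_predicate(self, rng):
        spots = [
            _spot(
                diam=tuple(rng.uniform(0.1, 0.6, 2)) + (rng.uniform(0.8, 1.6),),
                inten=rng.uniform(80, 250),
            )
            for _ in range(100)
        ]
        expected = [
            s for s in spots
            if s.diameter_xyz[0] > 0.3 and s.diameter_xyz[1] > 0.3
            and s.diameter_xyz[2] > 1.1 and s.peak_intensity > 130.0
        ]
        assert filter_puncta(spots, CRIT) == expected

    def test_idempotent(self, rng):
        spots = [_spot(inten=rng.uniform(80, 250)) for _ in range(50)]
        once = filter_puncta(spots, CRIT)
        assert filter_puncta(once, CRIT) == once


class TestSomaticSelection:
    def test_above_half_max_selected(self):
        sel = select_somatic_puncta([_spot(soma=0.6)], 1.0, CRIT)
        assert len(sel) == 1

    def test_below_half_max_not_selected(self):
        assert select_somatic_puncta([_spot(soma=0.4)], 1.0, CRIT) == []

    def test_missing_soma_channel_rejected(self):
        p = PunctaRecord((0, 0, 0), (0.4, 0.4, 1.3), 200.0)
        with pytest.raises(ValueError, match="soma"):
            select_somatic_puncta([p], 1.0, CRIT)

    def test_matches_brute_force(self, rng):
        spots = [_spot(soma=rng.uniform(0, 1), inten=rng.uniform(80, 250))
                 for _ in range(100)]
        expected = [s for s in spots
                    if s.soma_channel_intensity > 0.5
                    and s.peak_intensity > 130.0]
        assert select_somatic_puncta(spots, 1.0, CRIT) == expected


def _two_branch_skeleton():
    """20 µm trunk along +x from the soma surface; 10 µm child along +y
    attached at arclength 12."""
    trunk = Branch(
        points=np.column_stack([np.linspace(4, 24, 21),
                                np.zeros(21), np.zeros(21)]),
        radii=np.full(21, 0.5),
    )
    child = Branch(
        points=np.column_stack([np.full(11, 16.0),
                                np.linspace(0, 10, 11), np.zeros(11)]),
        radii=np.full(11, 0.4),
        parent=0,
        attach_arclength=12.0,
    )
    return Skeleton(branches=[trunk, child], soma_center=np.zeros(3),
                    soma_radius=4.0)


class TestResampleSkeleton:
    def test_one_micron_branch_has_eleven_samples(self):
        b = Branch(points=np.column_stack([np.linspace(0, 1, 5),
                                           np.zeros(5), np.zeros(5)]),
                   radii=np.full(5, 0.3))
        s = Skeleton(branches=[b])
        out = resample_skeleton(s, step=0.1)
        assert out.positions.shape[0] == 11
        np.testing.assert_allclose(out.path_distance,
                                   np.arange(11) * 0.1, atol=1e-9)

    def test_length_reconstruction(self):
        skel = _two_branch_skeleton()
        out = resample_skeleton(skel, step=0.1)
        for bi, b in enumerate(skel.branches):
            d = out.path_distance[out.branch_id == bi]
            assert d.max() - d.min() == pytest.approx(
                b.arclength()[-1], abs=0.1
            )

    def test_child_starts_at_parent_attachment_distance(self):
        out = resample_skeleton(_two_branch_skeleton(), step=0.1)
        child = out.path_distance[out.branch_id == 1]
        assert child.min() == pytest.approx(12.0, abs=1e-9)

    def test_misattached_child_rejected(self):
        trunk = Branch(points=np.array([[4, 0, 0], [24, 0, 0]]),
                       radii=np.array([0.5, 0.5]))
        bad = Branch(points=np.array([[99, 0, 0], [99, 5, 0]]),
                     radii=np.array([0.4, 0.4]), parent=0,
                     attach_arclength=12.0)
        with pytest.raises(ValueError, match="attachment"):
            Skeleton(branches=[trunk, bad])


def _brute_force_assign(puncta, samples, alpha):
    rows = []
    for p in puncta:
        d = np.linalg.norm(samples.positions - np.asarray(p.position), axis=1)
        ok = d <= samples.radii + alpha
        if not ok.any():
            rows.append((-1, np.nan))
        else:
            idx = np.where(ok)[0]
            j = idx[np.argmin(d[idx])]
            rows.append((int(j), samples.path_distance[j]))
    return rows


@pytest.fixture(scope="module")
def samples():
    return resample_skeleton(_two_branch_skeleton(), step=0.1)


class TestAssignment:
    def test_on_centerline_assigned(self, samples):
        out = assign_puncta([_spot(pos=(10.0, 0.0, 0.0))], samples)
        assert bool(out.loc[0, "assigned"])
        assert out.loc[0, "path_distance"] == pytest.approx(6.0, abs=0.05)

    def test_beyond_search_radius_unassigned(self, samples):
        # trunk radius 0.5 + alpha 0.2, offset by 0.5 + 0.25 + alpha
        out = assign_puncta([_spot(pos=(10.0, 0.95, 0.0))], samples)
        assert not bool(out.loc[0, "assigned"])

    def test_matches_all_pairs_oracle(self, samples, rng):
        puncta = [
            _spot(pos=tuple(rng.uniform([2, -3, -2], [26, 12, 2])))
            for _ in range(1000)
        ]
        out = assign_puncta(puncta, samples, alpha=0.2)
        oracle = _brute_force_assign(puncta, samples, 0.2)
        for i, (j, pd_) in enumerate(oracle):
            if j < 0:
                assert not out.loc[i, "assigned"]
            else:
                assert out.loc[i, "assigned"]
                assert out.loc[i, "sample_index"] == j


class TestDistanceHistogram:
    def test_two_puncta_binning(self):
        samples = resample_skeleton(_two_branch_skeleton(), step=0.1)
        out = assign_puncta(
            [_spot(pos=(9.0, 0, 0)), _spot(pos=(4 + 15.0, 0, 0))], samples
        )
        hist = distance_histogram(out, samples)
        assert hist.puncta_counts[0] == 1 and hist.puncta_counts[1] == 1

    def test_count_conservation(self, rng):
        samples = resample_skeleton(_two_branch_skeleton(), step=0.1)
        puncta = [_spot(pos=tuple(rng.uniform([2, -3, -2], [26, 12, 2])))
                  for _ in range(300)]
        out = assign_puncta(puncta, samples)
        hist = distance_histogram(out, samples)
        assert hist.puncta_counts.sum() == int(out["assigned"].sum())

    def test_uniform_density_recovered(self):
        """A uniform generator density of 0.5/µm is recovered flat: across
        draws, per-bin counts show near-nominal 95 % Poisson coverage and
        the pooled count/expectation ratio is unbiased."""
        from scipy.stats import poisson

        inside = 0
        total = 0
        ratios = []
        for seed in (42, 43, 44):
            cfg = GeneratorConfig(seed=seed, max_path_length=80.0)
            skel = skeleton_from_morphology(generate_morphology(cfg))
            puncta, _ = generate_puncta(skel, density=0.5, seed=seed,
                                        decoy_fraction=0.0)
            smp = resample_skeleton(skel, step=0.1)
            out = assign_puncta(puncta, smp)
            hist = distance_histogram(out, smp, step=0.1)
            for c, s in zip(hist.puncta_counts, hist.segment_counts):
                if s < 100:
                    continue
                mu = 0.5 * s * 0.1
                total += 1
                if poisson.ppf(0.025, mu) <= c <= poisson.ppf(0.975, mu):
                    inside += 1
                ratios.append(c / mu)
        assert total >= 20
        assert inside / total >= 0.8
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.06)


class TestCumulativeAndCompare:
    def test_single_punctum_step(self):
        df = pd.DataFrame({"assigned": [True], "path_distance": [12.0]})
        cdf = cumulative_distribution(df)
        below = cdf[cdf["distance_um"] < 12.0]["cumulative_fraction"]
        at = cdf[cdf["distance_um"] >= 12.0]["cumulative_fraction"]
        assert (below == 0).all() and (at == 1).all()

    def test_identical_sets_ks_zero(self, rng):
        x = rng.uniform(0, 50, 200)
        res = compare_distributions(x, x)
        assert res["statistic"] == 0.0

    def test_uniform_sup_difference(self, rng):
        """U[0,35] vs U[0,100]: the analytic KS sup-difference is 0.65 at
        x = 35."""
        a = rng.uniform(0, 35, 20000)
        b = rng.uniform(0, 100, 20000)
        res = compare_distributions(a, b)
        assert res["statistic"] == pytest.approx(0.65, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])


class TestPearsonMedianSkewness:
    def test_symmetric_sample_zero(self):
        assert pearson_median_skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert pearson_median_skewness([1, 2, 3, 4, 10]) == pytest.approx(
            0.8485, abs=2e-4
        )

    def test_affine_invariance_up_to_scale_sign(self, rng):
        x = rng.normal(0, 1, 100) ** 3
        s = pearson_median_skewness(x)
        assert pearson_median_skewness(3.5 * x + 11) == pytest.approx(s)
        assert pearson_median_skewness(-2.0 * x) == pytest.approx(-s)

    def test_zero_dispersion_rejected(self):
        with pytest.raises(ValueError):
            pearson_median_skewness([2.0, 2.0, 2.0])


class TestSpotTables:
    def test_round_trip(self, rng):
        spots = [_spot(pos=tuple(rng.uniform(0, 10, 3)),
                       inten=rng.uniform(100, 300)) for _ in range(20)]
        again = puncta_from_table(puncta_table(spots))
        assert again == spots
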