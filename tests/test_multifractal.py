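import numpy as np
import pytest

import petfract as pf
from petfract.errors import AnalysisError


def vol(arr):
    return pf.TracerVolume(np.asarray(arr, dtype=float))


class TestBoxMasses:
    def test_uniform_cube_splits_into_octants(self):
        masses = pf.box_masses(vol(np.full((8, 8, 8), 4.0)), 4, w=1)
        assert len(masses) == 8
        assert np.allclose(masses, 0.125)

    def test_single_voxel_concentrates_all_mass(self):
        arr = np.zeros((8, 8, 8))
        arr[1, 1, 1] = 17
        for s in (1, 2, 4, 8):
            masses = pf.box_masses(vol(arr), s, w=1)
            assert masses.tolist() == [1.0]

    def test_two_voxel_mass_split(self):
        arr = np.zeros((4, 4, 4))
        arr[0, 0, 0] = 3
        arr[3, 3, 3] = 1
        masses = pf.box_masses(vol(arr), 2, w=1)
        assert sorted(masses.tolist()) == [0.25, 0.75]

    def test_masses_always_normalized(self, make_random_volume):
        v = make_random_volume(0)
        for s in (1, 2, 4):
            assert pf.box_masses(v, s, w=1).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_mass_raises(self):
        with pytest.raises(AnalysisError, match="no tracer mass"):
            pf.box_masses(vol(np.zeros((4, 4, 4))), 2, w=1)


class TestPartitionSum:
    def test_even_split_second_moment(self):
        assert pf.partition_sum([0.5, 0.5], 2) == pytest.approx(0.5)

    def test_normalization_at_q1(self, make_random_volume):
        masses = pf.box_masses(make_random_volume(1), 2, w=1)
        assert pf.partition_sum(masses, 1) == pytest.approx(1.0)

    def test_negative_order_amplifies_small_masses(self):
        assert pf.partition_sum([0.75, 0.25], -1) == pytest.approx(1 / 0.75 + 1 / 0.25)

    def test_zero_order_counts_boxes(self):
        assert pf.partition_sum([0.2, 0.3, 0.5], 0) == pytest.approx(3.0)

    def test_nonpositive_masses_rejected(self):
        with pytest.raises(ValueError):
            pf.partition_sum([0.5, 0.0, 0.5], 2)


class TestDqSpectrum:
    def test_uniform_phantom_is_flat_at_3(self, uniform32):
        spec = pf.dq_spectrum(uniform32, w=1)
        assert np.allclose(spec.dq, 3.0, atol=1e-6)

    def test_point_phantom_is_flat_at_0(self):
        v = pf.generate(pf.PhantomSpec("point", level=5))
        spec = pf.dq_spectrum(v, w=1)
        assert np.allclose(spec.dq, 0.0, atol=1e-12)

    def test_cascade_matches_closed_form(self, cascade128, cascade_weights):
        spec = pf.dq_spectrum(cascade128, w=1e-9)
        theory = pf.theoretical_spectrum(cascade_weights, spec.q)
        assert np.allclose(spec.dq, theory.dq, atol=0.05)

    def test_insufficient_scales_raise(self, uniform32):
        with pytest.raises(AnalysisError, match="3 scales"):
            pf.dq_spectrum(uniform32, w=1, sizes=[1, 2])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_cascade_parameter_recovery(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.full(8, 2.0))
        v = pf.generate(pf.PhantomSpec("cascade", level=7, weights=tuple(w)))
        spec = pf.dq_spectrum(v, w=1e-12)
        theory = pf.theoretical_spectrum(w, spec.q)
        assert np.allclose(spec.dq, theory.dq, atol=0.05)

    @pytest.mark.parametrize(
        "volume_factory,w,sizes",
        [
            (lambda: pf.generate(pf.PhantomSpec("uniform", level=4)), 1, None),
            (
                lambda: pf.generate(
                    pf.PhantomSpec("cascade", level=6, weights=(0.4, 0.3, 0.2, 0.1, 0, 0, 0, 0))
                ),
                1e-9,
                None,
            ),
            # sampled volumes are fitted over their well-sampled scales only:
            # boxes holding O(1) tracer quanta bias the negative-q moments
            (
                lambda: pf.body_phantom(pf.PhantomSpec("body", level=6, lesion_count=10, seed=3)),
                1,
                [4, 8, 16, 32],
            ),
        ],
        ids=["uniform", "cascade", "body"],
    )
    def test_dq_non_increasing_in_q(self, volume_factory, w, sizes):
        spec = pf.dq_spectrum(volume_factory(), w=w, sizes=sizes)
        assert np.all(np.diff(spec.dq) <= 1e-6)

    def test_d0_equals_boxcount_dimension(self, make_random_volume):
        v = make_random_volume(9)
        sizes = [1, 2, 4, 8]
        spec = pf.dq_spectrum(v, w=1, sizes=sizes, q_list=[0])
        fit = pf.fit_dimension(pf.box_counts(v, 1, sizes))
        assert spec.value(0) == pytest.approx(fit.df, abs=1e-9)


class TestSummaries:
    def test_mean_mfs_of_constant_spectrum(self):
        n = len(pf.SUMMARY_Q)
        spec = pf.MomentSpectrum(pf.SUMMARY_Q, (2.5,) * n, (1.0,) * n, (0.0,) * n)
        assert pf.mean_mfs(spec) == pytest.approx(2.5)

    def test_mean_mfs_of_uniform_phantom(self, uniform32):
        assert pf.mean_mfs(pf.dq_spectrum(uniform32, w=1)) == pytest.approx(3.0, abs=1e-6)

    def test_mean_mfs_of_cascade_matches_closed_form_average(
        self, cascade128, cascade_weights
    ):
        theory = pf.theoretical_spectrum(cascade_weights, pf.SUMMARY_Q)
        got = pf.mean_mfs(pf.dq_spectrum(cascade128, w=1e-9))
        assert got == pytest.approx(np.mean(theory.dq), abs=0.05)

    def test_mean_mfs_requires_all_21_orders(self):
        spec = pf.MomentSpectrum((0, 1, 2), (3.0, 3.0, 3.0), (1.0,) * 3, (0.0,) * 3)
        with pytest.raises(ValueError, match="missing"):
            pf.mean_mfs(spec)

    def test_delta_d_of_identical_stages_is_zero(self, uniform32):
        spec = pf.dq_spectrum(uniform32, w=1)
        dd = pf.delta_d({1: spec, 2: spec})
        assert dd == {1: 0.0, 2: 0.0}

    def test_delta_d_published_worked_examples(self):
        assert pf.delta_d({1: 2.389, 2: 2.178})[2] == pytest.approx(-0.211)
        assert pf.delta_d({1: 2.425, 3: 2.305})[3] == pytest.approx(-0.120)

    def test_delta_d_requires_baseline(self):
        with pytest.raises(AnalysisError, match="baseline"):
            pf.delta_d({2: 2.1, 3: 2.2})

    def test_delta_d_equals_mean_mfs_difference(self, cascade128, cascade_weights, uniform32):
        a = pf.dq_spectrum(uniform32, w=1)
        b = pf.dq_spectrum(cascade128, w=1e-9)
        dd = pf.delta_d({1: a, 2: b})
        assert abs(dd[2] - (pf.mean_mfs(b) - pf.mean_mfs(a))) <= 1e-12
        assert dd[1] == 0.0
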