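"""Von Neumann entropy, quantum JSD and layer-reduction behavior."""

import numpy as np
import pytest

from muxbrain.connectivity import LayerNetwork
from muxbrain.reducibility import (
    group_snr,
    js_distance,
    js_distance_matrix_log,
    layer_distance_matrix,
    reduce_layers,
    rescaled_laplacian,
    von_neumann_entropy,
)

from conftest import complete_layer, random_layer


def cycle_adj(n):
    z = np.zeros((n, n))
    for i in range(n):
        z[i, (i + 1) % n] = z[(i + 1) % n, i] = 1.0
    return z


class TestRescaledLaplacian:
    @pytest.mark.parametrize("w", [0.5, 1.0, 3.7])
    def test_single_edge_spectrum_is_zero_one(self, w):
        adj = np.array([[0.0, w], [w, 0.0]])
        lr = rescaled_laplacian(adj)
        assert np.allclose(np.sort(lr.eigenvalues), [0.0, 1.0])

    def test_complete_graph_spectrum(self):
        # combinatorial Laplacian of K_N has eigenvalue N (multiplicity N-1);
        # rescaling by 1/(N(N-1)) gives 1/(N-1)
        lr = rescaled_laplacian(complete_layer(5).z)
        assert np.allclose(np.sort(lr.eigenvalues), [0, 0.25, 0.25, 0.25, 0.25])

    def test_unit_trace_and_psd(self, rng):
        adj = random_layer(12, 0.4, 3, weight_scale=2.0).z
        lr = rescaled_laplacian(adj)
        assert np.trace(lr.matrix) == pytest.approx(1.0, abs=1e-9)
        assert lr.eigenvalues.min() >= -1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rescaled_laplacian(np.zeros((3, 3)))


class TestEntropy:
    def test_single_edge_entropy_zero(self):
        lr = rescaled_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert von_neumann_entropy(lr) == 0.0

    @pytest.mark.parametrize("n", [3, 5, 9, 17])
    def test_complete_graph_closed_form(self, n):
        h = von_neumann_entropy(rescaled_laplacian(complete_layer(n).z))
        assert h == pytest.approx(np.log2(n - 1), abs=1e-12)

    def test_invariant_under_weight_rescaling(self):
        adj = random_layer(10, 0.4, 5, weight_scale=1.0).z
        h1 = von_neumann_entropy(rescaled_laplacian(adj))
        h2 = von_neumann_entropy(rescaled_laplacian(7.3 * adj))
        assert h1 == pytest.approx(h2, abs=1e-12)


class TestJsDistance:
    def test_identical_layers_give_zero(self):
        lr = rescaled_laplacian(complete_layer(6).z)
        assert js_distance(lr, lr) == 0.0

    def test_symmetry(self):
        la = rescaled_laplacian(complete_layer(5).z)
        lb = rescaled_laplacian(cycle_adj(5))
        assert js_distance(la, lb) == js_distance(lb, la)

    def test_agrees_with_matrix_log_oracle(self):
        la = rescaled_laplacian(complete_layer(5).z)
        lb = rescaled_laplacian(cycle_adj(5))
        assert js_distance(la, lb) == pytest.approx(
            js_distance_matrix_log(la, lb), abs=1e-8
        )

    def test_matrix_log_agreement_on_random_layers(self):
        for seed in range(5):
            la = rescaled_laplacian(random_layer(12, 0.5, seed, 1.0).z)
            lb = rescaled_laplacian(random_layer(12, 0.5, seed + 50, 1.0).z)
            assert js_distance(la, lb) == pytest.approx(
                js_distance_matrix_log(la, lb), abs=1e-8
            )

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            seeds = rng.integers(10000, size=3)
            ls = [rescaled_laplacian(random_layer(20, 0.3, int(s), 1.0).z) for s in seeds]
            dab = js_distance(ls[0], ls[1])
            dbc = js_distance(ls[1], ls[2])
            dac = js_distance(ls[0], ls[2])
            assert dac <= dab + dbc + 1e-9

    def test_bounded_in_unit_interval(self):
        la = rescaled_laplacian(complete_layer(20).z)
        z = np.zeros((20, 20))
        z[0, 1] = z[1, 0] = 1.0
        lb = rescaled_laplacian(z)
        assert 0 <= js_distance(la, lb) <= 1

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            js_distance(rescaled_laplacian(complete_layer(3).z),
                        rescaled_laplacian(complete_layer(4).z))


class TestReduceLayers:
    def test_identical_copies_degenerate_tie_breaks_to_no_merge(self):
        layer = random_layer(15, 0.4, 9)
        layers = [LayerNetwork(layer.z.copy(), layer.band) for _ in range(4)]
        res = reduce_layers(layers)
        assert np.allclose(res.distance_matrix, 0)
        assert np.allclose(res.quality, res.quality[0])
        assert res.optimal_step == 0

    def test_independent_dense_layers_prefer_no_reduction(self):
        layers = [random_layer(30, 0.3, s) for s in range(4)]
        res = reduce_layers(layers)
        assert res.optimal_step == 0
        assert len(res.quality) == 4

    def test_duplicated_layers_merge_first(self):
        # duplicated denser pair should be the closest and merge first,
        # and merging pure redundancy must not lower the quality
        dense = random_layer(30, 0.6, 1)
        layers = [
            dense,
            LayerNetwork(dense.z.copy(), dense.band),
            random_layer(30, 0.25, 2),
            random_layer(30, 0.25, 3),
        ]
        res = reduce_layers(layers)
        first_merge = set(res.merge_sequence[0][:2].astype(int))
        assert first_merge == {0, 1}
        assert res.quality[1] >= res.quality[0] - 1e-12

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            reduce_layers([complete_layer(5)])

    def test_quality_never_uses_interlayer_coupling(self):
        # the trajectory is a function of the layers alone
        layers = [random_layer(12, 0.4, s) for s in range(3)]
        q1 = reduce_layers(layers).quality
        q2 = reduce_layers(layers).quality
        assert np.allclose(q1, q2)


class TestGroupSnr:
    def test_hand_computed_three_subject_stats(self):
        d = [np.array([[0, x], [x, 0.0]]) for x in (0.1, 0.2, 0.3)]
        e = [np.array([[0, x], [x, 0.0]]) for x in (0.4, 0.5)]
        stats = group_snr(d + e, [0, 0, 0, 1, 1])
        mu0, sd0 = np.mean([0.1, 0.2, 0.3]), np.std([0.1, 0.2, 0.3], ddof=1)
        assert stats.mu[0][0, 1] == pytest.approx(mu0)
        assert stats.snr[0][0, 1] == pytest.approx(mu0 / sd0)

    def test_zero_dispersion_flagged_undefined(self):
        d = [np.zeros((2, 2))] * 4
        stats = group_snr(d, [0, 0, 1, 1])
        assert np.isnan(stats.snr[0][0, 1])

    def test_band_specific_group_difference_shows_in_target_layer(self):
        """Groups differing only in band-3 coupling should expose layer 3 in
        the largest |relative difference| of layer-pair distance SNR."""
        import muxbrain as mb

        cfg = mb.SyntheticConfig(
            n_subjects_per_group=10, n_rois=20, n_timepoints=180, seed=5,
            background_strength=0.8,
            group_effects={1: [(3, set(range(15)), 1.0)]},
        )
        cohort = mb.generate_cohort(cfg)
        scheme = cfg.band_scheme()
        rng = np.random.default_rng(17)
        dists, labels = [], []
        for ts, label in zip(cohort.subjects, cohort.labels):
            layers, _ = mb.build_layers(ts, scheme, n_surrogates=25,
                                        seed=int(rng.integers(2**31)))
            if any(l.n_edges == 0 for l in layers):
                continue
            dists.append(layer_distance_matrix(layers))
            labels.append(label)
        stats = group_snr(dists, labels)
        rel = np.abs(np.nan_to_num(stats.relative_difference))
        iu = np.triu_indices(12, k=1)
        order = np.argsort(rel[iu])[::-1]
        top_pairs = [(iu[0][o], iu[1][o]) for o in order[:3]]
        assert any(3 in pair for pair in top_pairs)
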