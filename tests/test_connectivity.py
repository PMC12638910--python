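import numpy as np
import pytest

from eegstages.connectivity import (
    PLIMatrix, efficiency, embed, instantaneous_phase,
    long_range_mask, mi_matrix, pli_matrix, top_links,
)
from helpers import (
    brute_force_global_efficiency, brute_force_local_efficiency,
    random_symmetric_graph, tone,
)


class TestInstantaneousPhase:
    def test_tone_phase_advances_at_its_angular_frequency(self):
        phases = instantaneous_phase(tone(10.0)[None, :], band=(8, 12),
                                     fs=128.0)
        mid = np.unwrap(phases[0])[200:1000]
        slope = np.polyfit(np.arange(mid.size) / 128.0, mid, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_quarter_cycle_offset_pair(self):
        x = np.vstack([tone(10.0), tone(10.0, phase=-np.pi / 2)])
        phases = instantaneous_phase(x, band=(8, 12), fs=128.0)
        dphi = np.angle(np.exp(1j * (phases[0] - phases[1])))[200:1000]
        assert np.allclose(dphi, np.pi / 2, atol=0.02)

    def test_sign_flip_shifts_phase_by_pi(self):
        x = tone(10.0)[None, :]
        p_pos = instantaneous_phase(x, band=(8, 12), fs=128.0)
        p_neg = instantaneous_phase(-x, band=(8, 12), fs=128.0)
        diff = np.angle(np.exp(1j * (p_pos - p_neg)))[0, 200:1000]
        assert np.allclose(np.abs(diff), np.pi, atol=0.02)


class TestPLIMatrix:
    def test_constant_lag_gives_unit_pli(self):
        x = np.vstack([tone(10.0), tone(10.0, phase=-np.pi / 2)])
        pli = pli_matrix(x, band=(8, 12), fs=128.0)
        assert pli.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_identical_channels_give_zero_pli(self):
        x = np.tile(tone(10.0), (2, 1))
        pli = pli_matrix(x, band=(8, 12), fs=128.0)
        assert pli.values[0, 1] == 0.0

    def test_independent_noise_pli_small(self):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(40):
            x = rng.standard_normal((2, 1280))
            vals.append(pli_matrix(x, fs=128.0).values[0, 1])
        assert np.mean(vals) < 0.1

    def test_symmetry_zero_diagonal_and_scale_invariance(self, rng):
        x = rng.standard_normal((4, 1280))
        pli = pli_matrix(x, fs=128.0)
        assert np.allclose(pli.values, pli.values.T)
        assert np.all(np.diag(pli.values) == 0)
        scaled = x * np.array([1.0, 5.0, 0.2, 40.0])[:, None]
        pli2 = pli_matrix(scaled, fs=128.0)
        assert np.allclose(pli.values, pli2.values, atol=1e-12)


class TestTopLinks:
    def _pli(self, values, montage):
        return PLIMatrix(values, (1.0, 45.0), montage.channel_names)

    def test_under_supply_returns_all_qualifying(self, montage):
        values = np.zeros((14, 14))
        mask = long_range_mask(montage)
        pairs = np.argwhere(np.triu(mask, 1))[:3]
        for i, j in pairs:
            values[i, j] = values[j, i] = 0.6
        links = top_links(self._pli(values, montage), montage, k=10)
        assert len(links) == 3

    def test_below_range_yields_empty(self, montage):
        values = np.full((14, 14), 0.3)
        np.fill_diagonal(values, 0.0)
        assert top_links(self._pli(values, montage), montage, k=10) == []

    def test_ranking_and_lexicographic_tie_break(self, montage):
        values = np.zeros((14, 14))
        mask = long_range_mask(montage)
        pairs = [tuple(p) for p in np.argwhere(np.triu(mask, 1))[:4]]
        weights = [0.65, 0.55, 0.65, 0.60]
        for (i, j), w in zip(pairs, weights):
            values[i, j] = values[j, i] = w
        links = top_links(self._pli(values, montage), montage, k=4)
        names = montage.channel_names
        # equal 0.65 weights resolve by channel-index order
        assert links[0][:2] == (names[pairs[0][0]], names[pairs[0][1]])
        assert links[1][:2] == (names[pairs[2][0]], names[pairs[2][1]])
        assert [l[2] for l in links] == [0.65, 0.65, 0.60, 0.55]

    def test_short_range_pairs_excluded(self, montage):
        values = np.zeros((14, 14))
        i, j = montage.index("AF3"), montage.index("AF4")  # neighbours? no:
        # AF3-AF4 is interhemispheric but short; use the template rule
        mask = long_range_mask(montage)
        if not mask[i, j]:
            values[i, j] = values[j, i] = 0.65
            assert top_links(self._pli(values, montage), montage, k=5) == []


class TestEfficiency:
    def test_complete_unit_graph(self):
        w = np.ones((5, 5)) - np.eye(5)
        g = efficiency(w)
        assert g.global_efficiency == pytest.approx(1.0)
        assert g.local_efficiency == pytest.approx(1.0)

    def test_three_node_path(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        g = efficiency(w)
        assert g.global_efficiency == pytest.approx(5 / 6)

    def test_disconnected_pairs_contribute_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        g = efficiency(w)
        assert g.global_efficiency == pytest.approx(1 / 3)

    def test_matches_brute_force_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            w = random_symmetric_graph(rng, int(rng.integers(3, 8)))
            g = efficiency(w)
            assert g.global_efficiency == pytest.approx(
                brute_force_global_efficiency(w), abs=1e-12)
            assert g.local_efficiency == pytest.approx(
                brute_force_local_efficiency(w), abs=1e-12)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            efficiency(np.array([[0, 1.0], [0.5, 0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            efficiency(np.array([[0, -1.0], [-1.0, 0]]))


class TestEmbed:
    def test_direct_construction(self):
        e = embed(np.array([1.0, 2.0, 3.0, 4.0]), m=2, tau=1)
        assert np.array_equal(e.vectors, [[1, 2], [2, 3], [3, 4]])

    def test_m1_is_identity_column(self):
        x = np.arange(5.0)
        e = embed(x, m=1, tau=3)
        assert np.array_equal(e.vectors, x[:, None])

    def test_vector_count_formula(self):
        e = embed(np.arange(10.0), m=3, tau=2)
        assert e.vectors.shape == (6, 3)

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match="too short"):
            embed(np.arange(4.0), m=3, tau=2)


class TestMIMatrix:
    def test_diagonal_is_channel_entropy_and_copy_identity(self, rng):
        x = rng.standard_normal(1280)
        data = np.vstack([x, x.copy()])
        mi = mi_matrix(data, bias_correction=False)
        # identical channels: MI(X, X) = H(X)
        assert mi.values[0, 1] == pytest.approx(mi.values[0, 0], abs=1e-12)

    def test_four_state_deterministic_copy_is_two_bits(self):
        x = np.tile([0.0, 1.0, 2.0, 3.0], 320)
        data = np.vstack([x, x.copy()])
        mi = mi_matrix(data, bias_correction=False)
        assert mi.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_independent_channels_near_zero_after_correction(self):
        rng = np.random.default_rng(3)
        vals = [mi_matrix(rng.standard_normal((2, 1280))).values[0, 1]
                for _ in range(25)]
        assert np.mean(vals) < 0.05

    def test_symmetric_nonnegative_bounded_by_marginals(self, rng):
        data = rng.standard_normal((4, 1280))
        data[1] += 0.8 * data[0]  # induce dependence
        mi = mi_matrix(data)
        v = mi.values
        assert np.allclose(v, v.T)
        assert np.all(v >= 0)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert v[i, j] <= min(v[i, i], v[j, j]) + 1e-9

    def test_constant_channel_has_zero_entropy_and_mi(self, rng):
        data = np.vstack([np.full(1280, 2.5), rng.standard_normal(1280)])
        mi = mi_matrix(data, bias_correction=False)
        assert mi.values[0, 0] == 0.0
        assert mi.values[0, 1] == 0.0
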