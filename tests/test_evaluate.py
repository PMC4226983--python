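import numpy as np
import pytest

from imputeval import (
    GenotypeMatrix,
    accuracy_per_individual,
    accuracy_per_snp,
    bin_by_covariate,
    compute_marker_stats,
    filter_informative,
)
from imputeval.evaluate import accuracy_per_snp_matrix
from imputeval.panels import PanelDefinition

from .conftest import uniform_map


class TestFilterInformative:
    def test_constant_observed_in_one_group_removes_marker(self):
        obs = np.array([[0], [0], [0], [1], [2], [0]])
        dos = np.array([[0.1], [0.5], [0.9], [1.0], [1.9], [0.2]])
        groups = [np.array([0, 1, 2]), np.array([3, 4, 5])]
        keep = filter_informative(obs, dos, groups)
        assert not keep[0]

    def test_variable_everywhere_is_kept(self):
        obs = np.array([[0], [1], [1], [2]])
        dos = np.array([[0.2], [0.9], [1.1], [1.8]])
        groups = [np.array([0, 1]), np.array([2, 3])]
        assert filter_informative(obs, dos, groups)[0]

    def test_one_of_five_groups_suffices_for_removal(self):
        rng = np.random.default_rng(0)
        obs = rng.integers(0, 3, size=(25, 4)).astype(np.int8)
        dos = rng.uniform(0, 2, size=(25, 4))
        groups = [np.arange(i * 5, (i + 1) * 5) for i in range(5)]
        obs[groups[3], 2] = 1  # constant in exactly one group
        keep = filter_informative(obs, dos, groups)
        assert not keep[2]
        assert keep[[0, 1, 3]].all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_informative(np.zeros((2, 1)), np.zeros((2, 1)), [np.array([], dtype=int)])


class TestAccuracyPerSnp:
    def test_perfect_imputation(self):
        assert accuracy_per_snp([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_opposite_genotypes(self):
        assert accuracy_per_snp([0, 2, 0, 2], [2, 0, 2, 0]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert accuracy_per_snp([0, 0, 1, 2], [0, 1, 1, 2]) == pytest.approx(
            0.8528, abs=1e-4
        )

    def test_constant_input_is_a_contract_violation(self):
        with pytest.raises(ValueError, match="filter"):
            accuracy_per_snp([1, 1, 1], [0.5, 1.0, 1.5])

    def test_matrix_version_matches_scalar(self, rng):
        obs = rng.integers(0, 3, size=(30, 8)).astype(float)
        dos = np.clip(obs + rng.normal(0, 0.5, size=obs.shape), 0, 2)
        expected = [accuracy_per_snp(obs[:, j], dos[:, j]) for j in range(8)]
        assert np.allclose(accuracy_per_snp_matrix(obs, dos), expected, atol=1e-12)


class TestAccuracyPerIndividual:
    def test_perfect_imputation_all_modes(self):
        obs = np.array([0.0, 1, 2, 1, 0, 2])
        means = np.full(6, 1.0)
        sds = np.full(6, 0.8)
        for mode in ("raw", "centered", "standardized"):
            r = accuracy_per_individual(
                obs, obs.copy(), mode, marker_means=means, marker_sds=sds
            )
            assert r == pytest.approx(1.0)

    def test_centering_by_constant_equals_raw(self, rng):
        obs = rng.integers(0, 3, size=12).astype(float)
        dos = np.clip(obs + rng.normal(0, 0.3, 12), 0, 2)
        raw = accuracy_per_individual(obs, dos, "raw")
        centered = accuracy_per_individual(
            obs, dos, "centered", marker_means=np.full(12, 0.7)
        )
        assert centered == pytest.approx(raw, abs=1e-12)

    def test_frequency_aligned_errors_inflate_raw_accuracy(self):
        """When imputation errors track the allele-frequency gradient, the
        raw per-individual correlation exceeds the centered one."""
        means = np.array([1.8, 1.6, 0.3, 0.1])
        obs = np.array([2.0, 2.0, 0.0, 0.0])
        dos = np.array([1.7, 1.5, 0.35, 0.30])
        raw = accuracy_per_individual(obs, dos, "raw")
        centered = accuracy_per_individual(obs, dos, "centered", marker_means=means)
        assert raw > centered

    def test_undefined_correlation_reported_missing(self):
        r = accuracy_per_individual(np.array([1.0, 1.0]), np.array([0.5, 0.9]), "raw")
        assert np.isnan(r)


class TestMarkerStats:
    def _setup(self, panel_pos, marker_pos, mafs=None):
        pos = np.sort(np.concatenate([panel_pos, marker_pos]))
        mm = uniform_map(len(pos))
        mm.positions_bp = pos.astype(np.int64)
        genos = GenotypeMatrix(
            genotypes=np.tile(np.array([[0], [1], [2]]), (1, len(pos))),
            marker_map=mm,
        )
        panel_idx = np.flatnonzero(np.isin(pos, panel_pos))
        panel = PanelDefinition("p", panel_idx, mm)
        eval_idx = np.flatnonzero(np.isin(pos, marker_pos))
        return mm, panel, genos, eval_idx

    def test_marker_at_panel_position_has_zero_distance(self):
        mm, panel, genos, _ = self._setup(np.array([100, 500]), np.array([300]))
        stats = compute_marker_stats(mm, panel, genos, marker_indices=panel.marker_indices[:1])
        assert stats.distance_bp[0] == 0

    def test_nearest_panel_snp(self):
        mm, panel, genos, eval_idx = self._setup(
            np.array([100, 1000]), np.array([400])
        )
        stats = compute_marker_stats(mm, panel, genos, marker_indices=eval_idx)
        assert stats.distance_bp[0] == 300
        assert mm.positions_bp[stats.nearest_panel_index[0]] == 100

    def test_equidistant_tie_goes_to_lower_position(self):
        mm, panel, genos, eval_idx = self._setup(
            np.array([100, 700]), np.array([400])
        )
        stats = compute_marker_stats(mm, panel, genos, marker_indices=eval_idx)
        assert mm.positions_bp[stats.nearest_panel_index[0]] == 100

    def test_five_neighbors_ordered_nearest_first(self):
        panel_pos = np.array([100, 200, 300, 900, 1500, 2000, 2600])
        mm, panel, genos, eval_idx = self._setup(panel_pos, np.array([850]))
        stats = compute_marker_stats(mm, panel, genos, marker_indices=eval_idx)
        d = np.abs(mm.positions_bp[stats.neighbor_indices[0]] - 850)
        assert len(d) == 5
        assert (np.diff(d) >= 0).all()


class TestBinByCovariate:
    def test_bin_sizes(self, rng):
        values = rng.uniform(-1, 1, 2500)
        cov = rng.uniform(0, 1, 2500)
        bins = bin_by_covariate(values, cov, bin_size=1000)
        assert list(bins["n_markers"]) == [1000, 1000, 500]

    def test_constant_covariate_keeps_position_order(self, rng):
        values = rng.uniform(-1, 1, 300)
        bins = bin_by_covariate(values, np.full(300, 0.25), bin_size=100)
        assert np.allclose(bins["covariate_mean"], 0.25)
        # stable tie-break by position: bins are consecutive slices
        assert bins["reliability_mean"].iloc[0] == pytest.approx(
            (values[:100] ** 2).mean()
        )

    def test_monotone_reliability_gives_monotone_bins(self):
        n = 3000
        maf = np.linspace(0.01, 0.5, n)
        r = np.sqrt(0.9 * maf / (0.05 + maf))
        bins = bin_by_covariate(r, maf, bin_size=1000)
        rel = bins["reliability_mean"].to_numpy()
        assert (np.diff(rel) >= 0).all()

    def test_empty_input(self):
        bins = bin_by_covariate(np.array([]), np.array([]))
        assert len(bins) == 0
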