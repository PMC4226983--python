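import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imputeval import (
    GenotypeMatrix,
    HaplotypeSet,
    LiStephensImputer,
    hard_call,
    impute_ls_hmm,
    impute_stepwise,
)
from imputeval.lshmm import DosageMatrix
from imputeval.panels import PanelDefinition, mask_to_panel
from imputeval.sim import MISSING

from .conftest import uniform_map
from .oracles import enumerate_posteriors


def _typed_every_other(truth_genotypes):
    obs = np.full_like(truth_genotypes, MISSING)
    obs[:, ::2] = truth_genotypes[:, ::2]
    return obs


class TestCopyingModel:
    def test_target_matching_one_reference_pair_is_recovered(self, rng):
        """With negligible error, a target identical to a reference diploid
        at a dense typed panel is copied through at untyped markers.  The
        reference haplotypes are independent draws, so the typed profile
        identifies the true pair essentially uniquely."""
        mm = uniform_map(60, spacing_bp=1000)
        ref = HaplotypeSet(
            alleles=rng.integers(0, 2, size=(12, 60)), marker_map=mm
        )
        truth = (ref.alleles[0] + ref.alleles[1]).astype(np.int8)[None, :]
        obs = _typed_every_other(truth)
        targets = GenotypeMatrix(genotypes=obs, marker_map=mm)
        dos = impute_ls_hmm(ref, targets, error_rate=1e-6)
        assert np.max(np.abs(dos.dosages[0] - truth[0])) < 0.01

    def test_two_haplotype_reference_forces_the_pair(self):
        mm = uniform_map(6, spacing_bp=50_000)
        alleles = np.array([[0, 1, 0, 1, 0, 1], [1, 1, 0, 0, 1, 0]], dtype=np.int8)
        ref = HaplotypeSet(alleles=alleles, marker_map=mm)
        implied = alleles[0] + alleles[1]
        obs = np.full((1, 6), MISSING, dtype=np.int8)
        obs[0, [0, 3, 4]] = implied[[0, 3, 4]]  # typed at heterozygous sites
        targets = GenotypeMatrix(genotypes=obs, marker_map=mm)
        dos = impute_ls_hmm(ref, targets, error_rate=1e-4, recombination_scale=1.0)
        assert np.allclose(dos.dosages[0], implied, atol=0.01)


class TestForwardBackwardOracle:
    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(
        n_hap=st.integers(min_value=2, max_value=4),
        n_markers=st.integers(min_value=2, max_value=5),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_posteriors_match_path_enumeration(self, n_hap, n_markers, seed):
        rng = np.random.default_rng(seed)
        mm = uniform_map(n_markers, spacing_bp=200_000)
        ref = HaplotypeSet(
            alleles=rng.integers(0, 2, size=(n_hap, n_markers)), marker_map=mm
        )
        obs = rng.integers(0, 3, size=n_markers).astype(np.int8)
        untyped = rng.uniform(size=n_markers) < 0.5
        obs[untyped] = MISSING
        if (obs == MISSING).all():
            obs[0] = 1
        targets = GenotypeMatrix(genotypes=obs[None, :], marker_map=mm)

        rho, err = 50.0, 0.01
        imputer = LiStephensImputer(
            recombination_scale=rho, error_rate=err, report_observed_at_typed=False
        ).fit(ref)
        probs = imputer.predict_proba(targets)[0]
        expected = enumerate_posteriors(
            ref.alleles, mm.positions_morgan, obs, rho, err
        )
        assert np.max(np.abs(probs - expected)) < 1e-8


class TestInvariantsAndContracts:
    def test_posterior_normalisation_and_dosage_bounds(self, small_dataset):
        ds = small_dataset
        L = min(120, ds.n_markers)
        ref = ds.haps.take_haplotypes(np.arange(20)).take_markers(np.arange(L))
        truth = ds.genos.take_markers(np.arange(L))
        obs = _typed_every_other(truth.genotypes[20:26])
        targets = GenotypeMatrix(genotypes=obs, marker_map=ref.marker_map)
        imputer = LiStephensImputer(report_observed_at_typed=False).fit(ref)
        probs = imputer.predict_proba(targets)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-9)
        dos = imputer.predict(targets)
        assert dos.dosages.min() >= 0 and dos.dosages.max() <= 2

    def test_larger_reference_does_not_hurt(self, small_dataset):
        """Enlarging the reference set from a subset to a superset should
        not decrease mean accuracy beyond sampling noise."""
        ds = small_dataset
        L = min(300, ds.n_markers)
        deltas = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            order = rng.permutation(ds.n_individuals)
            targets_idx, small_idx, big_extra = order[:5], order[5:13], order[13:25]
            big_idx = np.concatenate([small_idx, big_extra])
            truth = ds.genos.take_markers(np.arange(L))
            obs = np.full((5, L), MISSING, dtype=np.int8)
            obs[:, ::4] = truth.genotypes[targets_idx][:, ::4]
            tg = GenotypeMatrix(genotypes=obs, marker_map=truth.marker_map)

            def _accuracy(ref_rows):
                hap_rows = np.column_stack((2 * ref_rows, 2 * ref_rows + 1)).ravel()
                ref = ds.haps.take_haplotypes(hap_rows).take_markers(np.arange(L))
                dos = impute_ls_hmm(ref, tg)
                true_g = truth.genotypes[targets_idx].astype(float)
                keep = np.ptp(true_g, axis=0) > 0
                r = [
                    np.corrcoef(true_g[:, j], dos.dosages[:, j])[0, 1]
                    for j in np.flatnonzero(keep)
                    if np.ptp(dos.dosages[:, j]) > 0
                ]
                return float(np.mean(r))

            deltas.append(_accuracy(big_idx) - _accuracy(small_idx))
        assert np.mean(deltas) >= -0.02

    def test_marker_map_mismatch_rejected(self):
        ref = HaplotypeSet(alleles=np.zeros((2, 5), dtype=int), marker_map=uniform_map(5))
        bad = GenotypeMatrix(
            genotypes=np.zeros((1, 6), dtype=np.int8), marker_map=uniform_map(6)
        )
        with pytest.raises(ValueError, match="marker map"):
            LiStephensImputer().fit(ref).predict(bad)

    def test_untyped_individual_flagged_by_id(self):
        mm = uniform_map(4)
        ref = HaplotypeSet(alleles=np.eye(4, dtype=int)[:2], marker_map=mm)
        g = np.full((2, 4), MISSING, dtype=np.int8)
        g[0, 0] = 1
        targets = GenotypeMatrix(
            genotypes=g, marker_map=mm, individual_ids=["ok", "empty"]
        )
        with pytest.raises(ValueError, match="empty"):
            LiStephensImputer().fit(ref).predict(targets)


class TestHardCall:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ((0.2, 0.5, 0.3), 1),
            ((0.5, 0.5, 0.0), 1),   # tie broken toward the heterozygote
            ((1.0, 0.0, 0.0), 0),
            ((0.4, 0.1, 0.5), 2),
            ((0.5, 0.0, 0.5), 0),   # AA beats BB on ties
        ],
    )
    def test_argmax_with_tie_rules(self, probs, expected):
        p = np.array([[list(probs)]])
        dos = DosageMatrix(
            dosages=p[..., 1] + 2 * p[..., 2],
            genotype_probs=p,
            marker_map=uniform_map(1),
        )
        assert hard_call(dos).genotypes[0, 0] == expected


class TestStepwise:
    def test_degenerate_lo_equals_hd_matches_single_step(self, small_dataset):
        ds = small_dataset
        L = min(150, ds.n_markers)
        mm = ds.genos.marker_map.take(np.arange(L))
        haps = ds.haps.take_markers(np.arange(L))
        panel_idx = np.arange(0, L, 5)
        panel = PanelDefinition("p", panel_idx, mm)
        ref1 = haps.take_haplotypes(np.arange(0, 16))
        ref2 = haps.take_haplotypes(np.arange(16, 32))
        truth = GenotypeMatrix(
            genotypes=ds.genos.genotypes[16:20, :L], marker_map=mm
        )
        targets = mask_to_panel(truth, panel)
        final, step1 = impute_stepwise(targets, ref1, ref2, panel, panel)
        direct = impute_ls_hmm(ref2, targets)
        assert np.allclose(final.dosages, direct.dosages, atol=1e-9)

    def test_nesting_violation_rejected(self, small_dataset):
        ds = small_dataset
        L = min(60, ds.n_markers)
        mm = ds.genos.marker_map.take(np.arange(L))
        haps = ds.haps.take_markers(np.arange(L))
        lo = PanelDefinition("lo", np.array([1, 3]), mm)
        hd = PanelDefinition("hd", np.array([0, 2, 4]), mm)
        targets = GenotypeMatrix(
            genotypes=ds.genos.genotypes[:2, :L], marker_map=mm
        )
        with pytest.raises(ValueError, match="nest"):
            impute_stepwise(targets, haps, haps, lo, hd)
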