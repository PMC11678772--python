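"""Mixture drawing, augmentation bounds, paired-sample pairing, and corpus
persistence."""

import numpy as np
import pytest

from fieldlift import dataset_generator as dg
from fieldlift import spectral_core as sc


class TestDrawComposition:
    def test_all_values_in_range_without_dropout(self, tiny_library, default_aug, rng):
        for _ in range(200):
            comp = dg.draw_composition(tiny_library, default_aug, False, rng)
            assert set(comp) == {m.name for m in tiny_library}
            assert all(1.0 <= v <= 50.0 for v in comp.values())

    def test_dropout_inclusion_frequency(self, tiny_library, default_aug, rng):
        """Each metabolite is present in ~50% of dropout draws (10^4 draws)."""
        counts = {m.name: 0 for m in tiny_library}
        n = 10_000
        for _ in range(n):
            for name in dg.draw_composition(tiny_library, default_aug, True, rng):
                counts[name] += 1
        for name, c in counts.items():
            assert abs(c / n - 0.5) <= 0.02, name

    def test_empty_library_gives_empty_map(self, default_aug, rng):
        assert dg.draw_composition([], default_aug, False, rng) == {}


class TestReference:
    def test_reference_added_to_composition(self, small_axis_hf, default_aug):
        rec = sc.SpectrumRecord(small_axis_hf, np.zeros(small_axis_hf.n_points))
        out = dg.add_reference(rec, default_aug)
        assert out.composition == {dg.REFERENCE_NAME: 2.96}

    def test_reference_peak_at_zero_ppm(self, small_axis_hf, default_aug):
        rec = sc.SpectrumRecord(small_axis_hf, np.zeros(small_axis_hf.n_points))
        out = dg.add_reference(rec, default_aug)
        assert int(np.argmax(out.intensities)) == small_axis_hf.index_of(0.0)

    def test_double_reference_rejected(self, small_axis_hf, default_aug):
        rec = sc.SpectrumRecord(small_axis_hf, np.zeros(small_axis_hf.n_points))
        out = dg.add_reference(rec, default_aug)
        with pytest.raises(sc.ValidationError, match="reference already present"):
            dg.add_reference(out, default_aug)


class TestNoise:
    def test_peak_to_peak_bound(self, small_axis_hf, default_aug, rng):
        rec = sc.SpectrumRecord(small_axis_hf, np.zeros(small_axis_hf.n_points))
        out = dg.add_noise(rec, default_aug, rng=rng)
        added = out.intensities
        bound = 0.001 * default_aug.reference_height
        assert added.max() - added.min() <= bound
        assert np.abs(added).max() <= bound / 2

    def test_zero_noise_is_identity(self, small_axis_hf, rng):
        aug = dg.AugmentationConfig(noise_pp_frac=0.0)
        rec = sc.SpectrumRecord(small_axis_hf, np.ones(small_axis_hf.n_points))
        out = dg.add_noise(rec, aug, rng=rng)
        assert np.array_equal(out.intensities, rec.intensities)

    def test_multiplier_scales_empirical_sd(self, rng):
        """4x multiplier scales the noise standard deviation by 4 +- 5%."""
        axis = sc.make_axis(100_000, 0.0, 10.0, 400.0)
        aug = dg.AugmentationConfig()
        base = sc.SpectrumRecord(axis, np.zeros(axis.n_points))
        sd1 = dg.add_noise(base, aug, multiplier=1.0, rng=rng).intensities.std()
        sd4 = dg.add_noise(base, aug, multiplier=4.0, rng=rng).intensities.std()
        assert sd4 / sd1 == pytest.approx(4.0, rel=0.05)

    def test_nonpositive_multiplier_rejected(self, small_axis_hf, default_aug, rng):
        rec = sc.SpectrumRecord(small_axis_hf, np.zeros(small_axis_hf.n_points))
        with pytest.raises(sc.ValidationError, match="multiplier"):
            dg.add_noise(rec, default_aug, multiplier=0.0, rng=rng)


class TestJitter:
    def test_draw_bounded_by_max_ppb(self, default_aug, rng):
        draws = [dg.draw_jitter_ppm(default_aug, rng) for _ in range(5_000)]
        assert max(abs(d) for d in draws) <= 3.4e-3
        assert any(d < 0 for d in draws) and any(d > 0 for d in draws)

    def test_zero_shift_is_identity(self, small_axis_hf, rng):
        aug = dg.AugmentationConfig(shift_max_ppb=0.0)
        rec = sc.SpectrumRecord(small_axis_hf, rng.random(small_axis_hf.n_points))
        out = dg.jitter_metabolite(rec, aug, rng=rng)
        assert np.array_equal(out.intensities, rec.intensities)

    def test_translation_preserves_total_intensity(self, rng):
        axis = sc.make_axis(1_000, 0.0, 10.0, 400.0)
        y = np.zeros(1_000)
        y[400:600] = rng.random(200)  # support far from edges
        rec = sc.SpectrumRecord(axis, y)
        out = dg.jitter_metabolite(rec, dg.AugmentationConfig(shift_max_ppb=3_000.0),
                                   rng=rng)
        assert out.intensities.sum() == pytest.approx(y.sum(), rel=1e-12)

    def test_explicit_delta_is_grid_translation(self, small_axis_hf, default_aug):
        y = np.zeros(small_axis_hf.n_points)
        y[100] = 1.0
        rec = sc.SpectrumRecord(small_axis_hf, y)
        delta = 5 * small_axis_hf.delta_ppm
        out = dg.jitter_metabolite(rec, default_aug, delta_ppm=delta)
        assert out.intensities[105] == 1.0 and out.intensities.sum() == 1.0


class TestBaseline:
    def test_offset_bound(self, small_axis_hf, default_aug, rng):
        rec = sc.SpectrumRecord(small_axis_hf, np.zeros(small_axis_hf.n_points))
        bound = 0.006 * default_aug.reference_height
        for _ in range(200):
            out = dg.shift_baseline(rec, default_aug, rng=rng)
            assert abs(out.provenance["baseline_offset"]) <= bound

    def test_zero_max_is_identity(self, small_axis_hf, rng):
        aug = dg.AugmentationConfig(baseline_max_frac=0.0)
        rec = sc.SpectrumRecord(small_axis_hf, np.ones(small_axis_hf.n_points))
        out = dg.shift_baseline(rec, aug, rng=rng)
        assert np.array_equal(out.intensities, rec.intensities)

    def test_mean_shift_equals_offset_exactly(self, small_axis_hf, default_aug, rng):
        rec = sc.SpectrumRecord(small_axis_hf, rng.random(small_axis_hf.n_points))
        out = dg.shift_baseline(rec, default_aug, offset=0.1234)
        assert np.mean(out.intensities) - np.mean(rec.intensities) == pytest.approx(
            0.1234, abs=1e-12
        )


class TestArtifacts:
    def test_counts_within_caps(self, default_aug, rng):
        seen_s, seen_t = set(), set()
        for _ in range(1_000):
            arts = dg.draw_artifacts(default_aug, -0.32, 10.2, rng)
            kinds = [a[0] for a in arts]
            seen_s.add(kinds.count("singlet"))
            seen_t.add(kinds.count("triplet"))
        assert seen_s == {0, 1, 2, 3}
        assert seen_t == {0, 1, 2, 3}

    def test_no_triplets_when_disabled(self, rng):
        aug = dg.AugmentationConfig(include_triplets=False)
        for _ in range(500):
            arts = dg.draw_artifacts(aug, -0.32, 10.2, rng)
            assert all(kind == "singlet" for kind, _, _ in arts)

    def test_seeded_determinism(self, small_axis_hf, default_aug):
        rec = sc.SpectrumRecord(small_axis_hf, np.zeros(small_axis_hf.n_points))
        a = dg.add_artifacts(rec, default_aug, rng=np.random.default_rng(42))
        b = dg.add_artifacts(rec, default_aug, rng=np.random.default_rng(42))
        assert np.array_equal(a.intensities, b.intensities)

    def test_triplet_is_one_two_one(self, default_aug):
        axis = sc.make_axis(20_001, 0.0, 10.0, 400.0)
        rec = sc.SpectrumRecord(axis, np.zeros(axis.n_points))
        out = dg.add_artifacts(rec, default_aug,
                               artifacts=[("triplet", 5.0, 10.0)])
        y = out.intensities
        center = axis.index_of(5.0)
        side = axis.index_of(5.0 + dg.ARTIFACT_TRIPLET_J_HZ / 400.0)
        assert y[center] == pytest.approx(2.0 * y[side], rel=0.02)


class TestPairedSamples:
    def test_compositions_shared_between_fields(self, tiny_library, default_aug, rng):
        cfg = dg.CorpusConfig(n_all_present=1, n_with_dropout=1, train_count=1,
                              val_count=1, test_count=0, n_points=460)
        for use_dropout in (False, True):
            s = dg.generate_paired_sample(tiny_library, default_aug, cfg,
                                          use_dropout, rng)
            assert s.lf.composition == s.hf.composition
            assert s.conc.shape == (len(tiny_library),)

    def test_doublet_separation_scales_4x(self):
        """A pure doublet's LF peak-pair separation (ppm) is 4x the HF one."""
        from scipy.signal import find_peaks

        lib = [sc.MetaboliteSpinModel("d", [sc.Multiplet(5.0, [10.0], 2.0)])]
        aug = dg.AugmentationConfig(noise_pp_frac=0.0, shift_max_ppb=0.0,
                                    baseline_max_frac=0.0, max_singlets=0,
                                    max_triplets=0)
        cfg = dg.CorpusConfig(n_all_present=1, n_with_dropout=1, train_count=1,
                              val_count=1, test_count=0, n_points=46_000)
        s = dg.generate_paired_sample(lib, aug, cfg, False, np.random.default_rng(3))

        def separation(y, ppm):
            peaks, _ = find_peaks(y, height=0.1 * y.max())
            # ignore the reference singlet at 0 ppm
            peaks = [p for p in peaks if ppm[p] > 1.0]
            assert len(peaks) == 2
            return ppm[peaks[1]] - ppm[peaks[0]]

        ppm = s.lf.axis.ppm
        sep_lf = separation(s.lf.intensities, ppm)
        sep_hf = separation(s.hf.intensities, ppm)
        assert sep_lf == pytest.approx(4.0 * sep_hf, rel=0.02)
        assert sep_lf == pytest.approx(10.0 / 100.0, rel=0.02)  # J/freq in ppm

    def test_lf_noise_multiplier_scales_lf_only(self, tiny_library):
        aug = dg.AugmentationConfig(lf_noise_multiplier=4.0)
        cfg = dg.CorpusConfig(n_all_present=1, n_with_dropout=1, train_count=1,
                              val_count=1, test_count=0, n_points=46_000)
        rng = np.random.default_rng(11)
        quiet = dg.generate_paired_sample(tiny_library, aug, cfg, False, rng)
        base = dg.AugmentationConfig(noise_pp_frac=0.0, lf_noise_multiplier=4.0)
        clean = dg.generate_paired_sample(tiny_library, base, cfg, False,
                                          np.random.default_rng(11))
        lf_noise = quiet.lf.intensities - clean.lf.intensities
        hf_noise = quiet.hf.intensities - clean.hf.intensities
        ref = aug.reference_height
        assert np.abs(lf_noise).max() <= 4.0 * 0.001 * ref / 2
        assert np.abs(hf_noise).max() <= 0.001 * ref / 2
        assert lf_noise.std() == pytest.approx(4.0 * hf_noise.std(), rel=0.05)


class TestCorpus:
    def test_toy_split_ratio(self, tiny_library, default_aug, toy_corpus_cfg, tmp_path):
        dg.build_corpus(tiny_library, default_aug, toy_corpus_cfg, tmp_path / "c.h5")
        corpus = dg.load_corpus(tmp_path / "c.h5")
        assert corpus["train"]["lf"].shape == (16, 460)
        assert corpus["val"]["hf"].shape == (4, 460)
        assert corpus["test"]["conc"].shape == (2, len(tiny_library))
        assert corpus["manifest"]["library_hash"] == sc.library_hash(tiny_library)

    def test_equal_seeds_give_byte_identical_files(self, tiny_library, default_aug,
                                                   toy_corpus_cfg, tmp_path):
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        dg.build_corpus(tiny_library, default_aug, toy_corpus_cfg, p1)
        dg.build_corpus(tiny_library, default_aug, toy_corpus_cfg, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_changes_corpus(self, tiny_library, default_aug,
                                           toy_corpus_cfg, tmp_path):
        from dataclasses import replace

        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        dg.build_corpus(tiny_library, default_aug, toy_corpus_cfg, p1)
        dg.build_corpus(tiny_library, default_aug,
                        replace(toy_corpus_cfg, seed=8), p2)
        assert p1.read_bytes() != p2.read_bytes()

    def test_inconsistent_counts_rejected_before_generation(self):
        with pytest.raises(sc.ValidationError, match="train_count"):
            dg.CorpusConfig(n_all_present=10, n_with_dropout=10,
                            train_count=16, val_count=5)

    def test_dropout_half_marginals(self, tiny_library, default_aug, tmp_path):
        """Metabolites appear in about half of the dropout-half samples."""
        cfg = dg.CorpusConfig(n_all_present=0, n_with_dropout=400,
                              train_count=300, val_count=100, test_count=0,
                              seed=5, n_points=460)
        dg.build_corpus(tiny_library, default_aug, cfg, tmp_path / "c.h5")
        corpus = dg.load_corpus(tmp_path / "c.h5")
        conc = np.concatenate([corpus["train"]["conc"], corpus["val"]["conc"]])
        present_frac = (conc > 0).mean(axis=0)
        # binomial: sd = sqrt(.25/400) = 0.025; allow 4 sd
        assert np.all(np.abs(present_frac - 0.5) < 0.1)


class TestFixedConcentrationTests:
    def test_three_levels_constant_vectors(self, tiny_library, default_aug):
        samples = dg.build_fixed_concentration_tests(
            tiny_library, default_aug, [5.0, 25.0, 50.0],
            dg.CorpusConfig(n_all_present=1, n_with_dropout=1, train_count=1,
                            val_count=1, test_count=0, n_points=460),
        )
        assert len(samples) == 3
        for level, s in zip([5.0, 25.0, 50.0], samples):
            assert np.all(s.conc == level)
            assert s.lf.composition[tiny_library[0].name] == level

    def test_linearity_across_levels_pre_noise(self, tiny_library):
        aug = dg.AugmentationConfig(noise_pp_frac=0.0, ref_conc=2.96)
        cfg = dg.CorpusConfig(n_all_present=1, n_with_dropout=1, train_count=1,
                              val_count=1, test_count=0, n_points=460)
        s5, s25 = dg.build_fixed_concentration_tests(tiny_library, aug, [5.0, 25.0], cfg)
        ref = sc.render_metabolite(
            sc.MetaboliteSpinModel(dg.REFERENCE_NAME,
                                   [sc.Multiplet(0.0, [], dg.REFERENCE_PROTONS)]),
            cfg.hf_axis(), aug.ref_conc,
        ).intensities
        assert np.allclose(s25.hf.intensities - ref,
                           5.0 * (s5.hf.intensities - ref), atol=1e-9)

    def test_empty_levels_rejected(self, tiny_library, default_aug):
        with pytest.raises(sc.ValidationError, match="levels"):
            dg.build_fixed_concentration_tests(tiny_library, default_aug, [])

    def test_out_of_range_level_warns(self, tiny_library, default_aug):
        cfg = dg.CorpusConfig(n_all_present=1, n_with_dropout=1, train_count=1,
                              val_count=1, test_count=0, n_points=460)
        with pytest.warns(UserWarning, match="outside"):
            dg.build_fixed_concentration_tests(tiny_library, default_aug, [60.0], cfg)


def test_uniform_noise_mse_floor_matches_empirical(rng):
    """A noiseless prediction against a uniformly noisy target has expected
    MSE a^2/12."""
    from fieldlift.evaluation import uniform_noise_mse_floor

    a = 0.03
    noise = rng.uniform(-a / 2, a / 2, size=200_000)
    assert noise.var() == pytest.approx(uniform_noise_mse_floor(a), rel=0.02)
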