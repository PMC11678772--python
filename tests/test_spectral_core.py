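"""Axis construction, first-order multiplet physics, Lorentzian rendering,
and spectrum file IO."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fieldlift import spectral_core as sc


class TestSpectralAxis:
    def test_standard_window_spacing(self):
        ax = sc.make_axis(46_000, -0.32, 10.2, 400.0)
        assert ax.delta_ppm == pytest.approx(10.52 / 45_999, rel=1e-12)
        assert ax.ppm[0] == -0.32 and ax.ppm[-1] == 10.2
        assert np.allclose(np.diff(ax.ppm), ax.delta_ppm)

    def test_two_point_grid(self):
        ax = sc.make_axis(2, 0.0, 1.0, 100.0)
        assert ax.ppm.tolist() == [0.0, 1.0]

    def test_hz_offset_is_ppm_times_freq(self):
        ax = sc.make_axis(11, 0.0, 1.0, 100.0)
        assert ax.hz_offset(5) == pytest.approx(ax.ppm[5] * 100.0)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(n_points=100, ppm_min=10.2, ppm_max=-0.32), "inverted bounds"),
            (dict(freq=0.0), "spectrometer_freq"),
            (dict(freq=-400.0), "spectrometer_freq"),
            (dict(n_points=1), "n_points"),
        ],
    )
    def test_validation_names_offending_field(self, kwargs, match):
        defaults = dict(n_points=100, ppm_min=-0.32, ppm_max=10.2, freq=400.0)
        defaults.update(kwargs)
        with pytest.raises(sc.ValidationError, match=match):
            sc.make_axis(**defaults)


def brute_force_sticks(j_list, freq):
    """Oracle: expand all 2^n coupling sign combinations and bin."""
    lines = {}
    for signs in itertools.product((-1, 1), repeat=len(j_list)):
        pos = sum(s * j / (2 * freq) for s, j in zip(signs, j_list))
        key = round(pos, 9)
        lines[key] = lines.get(key, 0.0) + 1.0 / 2 ** len(j_list)
    return sorted(lines.items())


class TestMultipletLines:
    def test_doublet_positions_and_weights(self):
        m = sc.Multiplet(1.33, [7.0], 1.0)
        lines = sc.multiplet_line_positions(m, 400.0)
        assert [p for p, _ in lines] == pytest.approx([1.33 - 0.00875, 1.33 + 0.00875])
        assert [w for _, w in lines] == pytest.approx([0.5, 0.5])

    def test_triplet_binomial_weights(self):
        m = sc.Multiplet(1.33, [7.0, 7.0], 4.0)
        lines = sc.multiplet_line_positions(m, 100.0)
        assert len(lines) == 3
        assert [w for _, w in lines] == pytest.approx([1.0, 2.0, 1.0])

    def test_no_coupling_single_line(self):
        lines = sc.multiplet_line_positions(sc.Multiplet(3.0, [], 2.5), 400.0)
        assert lines == [(3.0, 2.5)]

    @settings(derandomize=True, max_examples=40)
    @given(
        n=st.integers(0, 5),
        j=st.floats(2.0, 12.0),
        freq=st.sampled_from([100.0, 400.0]),
    )
    def test_identical_couplings_match_brute_force(self, n, j, freq):
        m = sc.Multiplet(5.0, [j] * n, 1.0)
        lines = sc.multiplet_line_positions(m, freq)
        oracle = brute_force_sticks([j] * n, freq)
        assert len(lines) == n + 1 == len(oracle)
        binom = [math.comb(n, k) / 2 ** n for k in range(n + 1)]
        assert [w for _, w in lines] == pytest.approx(binom)
        assert [p - 5.0 for p, _ in lines] == pytest.approx([p for p, _ in oracle])

    @staticmethod
    def _cluster(pairs, tol=1e-8):
        """Merge lines closer than ``tol`` so both representations are
        compared on one footing regardless of internal merge tolerances."""
        out = []
        for p, w in sorted(pairs):
            if out and p - out[-1][0] <= tol:
                p0, w0 = out[-1]
                out[-1] = (p0, w0 + w)
            else:
                out.append((p, w))
        return out

    @settings(derandomize=True, max_examples=40)
    @given(js=st.lists(st.floats(2.0, 12.0), max_size=4))
    def test_arbitrary_couplings_match_brute_force(self, js):
        lines = self._cluster(sc.multiplet_line_positions(sc.Multiplet(0.0, js, 1.0), 400.0))
        oracle = self._cluster(brute_force_sticks(js, 400.0))
        assert len(lines) == len(oracle)
        assert [p for p, _ in lines] == pytest.approx([p for p, _ in oracle], abs=1e-8)
        assert [w for _, w in lines] == pytest.approx([w for _, w in oracle])

    @settings(derandomize=True, max_examples=30)
    @given(j=st.floats(2.0, 12.0), center=st.floats(0.5, 9.5))
    def test_field_scaling_law(self, j, center):
        """ppm splitting of a doublet at 100 MHz is exactly 4x that at 400 MHz."""
        m = sc.Multiplet(center, [j], 1.0)
        lf = sc.multiplet_line_positions(m, 100.0)
        hf = sc.multiplet_line_positions(m, 400.0)
        sep_lf = lf[1][0] - lf[0][0]
        sep_hf = hf[1][0] - hf[0][0]
        assert sep_lf == pytest.approx(4.0 * sep_hf, rel=1e-12)


class TestRendering:
    def test_singlet_peak_at_nearest_grid_point(self, small_axis_hf):
        model = sc.MetaboliteSpinModel("ref", [sc.Multiplet(0.0, [], 1.0)])
        rec = sc.render_metabolite(model, small_axis_hf, 2.96)
        assert int(np.argmax(rec.intensities)) == small_axis_hf.index_of(0.0)

    def test_unit_height_amplitude_convention(self):
        # grid point exactly on the line center
        ax = sc.make_axis(1001, 0.0, 10.0, 400.0)
        model = sc.MetaboliteSpinModel("s", [sc.Multiplet(5.0, [], 1.0, 1.0)])
        rec = sc.render_metabolite(model, ax, 1.0)
        assert rec.intensities.max() == pytest.approx(1.0, rel=1e-6)

    def test_linearity_in_concentration(self, small_axis_hf, tiny_library):
        model = tiny_library[0]
        r1 = sc.render_metabolite(model, small_axis_hf, 3.7)
        r2 = sc.render_metabolite(model, small_axis_hf, 7.4)
        assert np.allclose(r2.intensities, 2.0 * r1.intensities, rtol=1e-12)

    def test_linewidth_ppm_scales_with_field(self):
        """FWHM in ppm at 100 MHz is 4x the FWHM at 400 MHz."""
        def fwhm(freq):
            ax = sc.make_axis(40_001, 4.0, 6.0, freq)
            model = sc.MetaboliteSpinModel("s", [sc.Multiplet(5.0, [], 1.0, 1.0)])
            y = sc.render_metabolite(model, ax, 1.0).intensities
            above = ax.ppm[y >= y.max() / 2]
            return above[-1] - above[0]

        assert fwhm(100.0) == pytest.approx(4.0 * fwhm(400.0), rel=1e-3)

    @pytest.mark.parametrize("freq", [100.0, 400.0])
    def test_integral_proportional_to_conc_times_protons(self, freq):
        """Trapezoidal integral vs the analytic Lorentzian area.

        A peak-height-normalized Lorentzian of FWHM g has area
        height * pi * g / 2, so a rendered metabolite integrates to
        conc * total_protons * pi * (linewidth/freq) / 2 far from edges.
        """
        ax = sc.make_axis(46_000, -0.32, 10.2, freq)
        model = sc.MetaboliteSpinModel(
            "m", [sc.Multiplet(4.0, [7.0], 2.0), sc.Multiplet(6.5, [], 1.5)]
        )
        conc = 3.2
        rec = sc.render_metabolite(model, ax, conc)
        integral = np.trapezoid(rec.intensities, ax.ppm)
        analytic = conc * model.total_protons * math.pi * (1.0 / freq) / 2.0
        assert integral == pytest.approx(analytic, rel=0.01)

    def test_superposition_of_mixture(self, small_axis_hf, tiny_library):
        total = np.zeros(small_axis_hf.n_points)
        for i, model in enumerate(tiny_library):
            total += sc.render_metabolite(model, small_axis_hf, 1.0 + i).intensities
        # pointwise sum of renders equals a single accumulated render
        again = np.zeros(small_axis_hf.n_points)
        for i, model in enumerate(tiny_library):
            for mult in model.multiplets:
                sc.render_multiplet(mult, small_axis_hf, 1.0 + i, out=again)
        assert np.array_equal(total, again) or np.allclose(total, again, rtol=1e-13)

    def test_negative_concentration_rejected(self, small_axis_hf, tiny_library):
        with pytest.raises(sc.ValidationError, match="conc"):
            sc.render_metabolite(tiny_library[0], small_axis_hf, -1.0)


class TestFileIO:
    def test_writer_reader_round_trip(self, tmp_path):
        ax = sc.make_axis(8, 0.0, 7.0, 400.0)
        rec = sc.SpectrumRecord(ax, np.array([0.0, 1.5, 0.25, -0.5, 3.0, 0.0, 1e-7, 2.0]),
                                composition={"x": 1.2})
        path = tmp_path / "spec.jdx"
        sc.write_spectrum(rec, path)
        back = sc.read_external_spectrum(path, ax)
        assert np.array_equal(back.intensities, rec.intensities)
        assert back.composition == rec.composition

    def test_descending_ppm_storage_equivalent(self, tmp_path):
        ax = sc.make_axis(16, 0.0, 3.0, 400.0)
        y = np.sin(np.arange(16.0))
        asc = tmp_path / "asc.jdx"
        desc = tmp_path / "desc.jdx"
        for path, order in ((asc, slice(None)), (desc, slice(None, None, -1))):
            lines = ["##TITLE=t", "##XUNITS=PPM", "##.OBSERVE FREQUENCY=400.0",
                     "##XYPOINTS=(XY..XY)"]
            lines += [f"{x!r}, {v!r}" for x, v in zip(ax.ppm[order], y[order])]
            lines.append("##END=")
            path.write_text("\n".join(lines))
        a = sc.read_external_spectrum(asc, ax)
        d = sc.read_external_spectrum(desc, ax)
        assert np.array_equal(a.intensities, d.intensities)

    def test_resampling_zeroes_outside_source_range(self, tmp_path):
        src_ax = sc.make_axis(64, 2.0, 4.0, 400.0)
        rec = sc.SpectrumRecord(src_ax, np.ones(64))
        path = tmp_path / "narrow.jdx"
        sc.write_spectrum(rec, path)
        target = sc.make_axis(101, 0.0, 10.0, 400.0)
        back = sc.read_external_spectrum(path, target)
        outside = (target.ppm < 2.0) | (target.ppm > 4.0)
        assert np.all(back.intensities[outside] == 0.0)
        assert np.all(back.intensities[~outside] > 0.0)

    def test_missing_frequency_is_format_error(self, tmp_path):
        path = tmp_path / "nofreq.jdx"
        path.write_text(
            "##TITLE=t\n##XUNITS=PPM\n##XYPOINTS=(XY..XY)\n0.0, 1.0\n1.0, 2.0\n##END=\n"
        )
        with pytest.raises(sc.FormatError, match="OBSERVE FREQUENCY"):
            sc.read_external_spectrum(path, sc.make_axis(4, 0.0, 1.0, 400.0))

    def test_hz_axis_converted_via_frequency(self, tmp_path):
        path = tmp_path / "hz.jdx"
        # 400 Hz at 400 MHz -> 1 ppm
        path.write_text(
            "##TITLE=t\n##XUNITS=HZ\n##.OBSERVE FREQUENCY=400.0\n"
            "##XYPOINTS=(XY..XY)\n0.0, 1.0\n400.0, 3.0\n##END=\n"
        )
        ax = sc.make_axis(3, 0.0, 1.0, 400.0)
        back = sc.read_external_spectrum(path, ax)
        assert back.intensities == pytest.approx([1.0, 2.0, 3.0])

    def test_xydata_run_format(self, tmp_path):
        path = tmp_path / "xy.jdx"
        path.write_text(
            "##TITLE=t\n##XUNITS=PPM\n##.OBSERVE FREQUENCY=400.0\n"
            "##FIRSTX=0.0\n##LASTX=3.0\n##NPOINTS=4\n##XFACTOR=1\n##YFACTOR=2\n"
            "##XYDATA=(X++(Y..Y))\n0.0 1 2\n2.0 3 4\n##END=\n"
        )
        ax = sc.make_axis(4, 0.0, 3.0, 400.0)
        back = sc.read_external_spectrum(path, ax)
        assert back.intensities == pytest.approx([2.0, 4.0, 6.0, 8.0])

    def test_peak_table_deposits_on_nearest_grid_point(self, tmp_path):
        path = tmp_path / "peaks.jdx"
        path.write_text(
            "##TITLE=t\n##XUNITS=PPM\n##.OBSERVE FREQUENCY=400.0\n"
            "##PEAK TABLE=(XY..XY)\n2.01, 5.0\n##END=\n"
        )
        ax = sc.make_axis(11, 0.0, 10.0, 400.0)
        back = sc.read_external_spectrum(path, ax)
        assert back.intensities[2] == 5.0 and back.intensities.sum() == 5.0

    def test_garbage_file_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.jdx"
        path.write_text("##TITLE=t\n##XYPOINTS=(XY..XY)\n1.0, 2.0, 3.0\n")
        with pytest.raises(sc.ParseError, match="bad.jdx:3"):
            sc.read_external_spectrum(path, sc.make_axis(4, 0.0, 1.0, 400.0))

    def test_peaklist_round_trip(self, tmp_path):
        path = tmp_path / "ala.tsv"
        path.write_text(
            "# name: alanine_like\n"
            "1.48\t7.2,7.2\t3\n"
            "3.78\t7.2\t1\t1.5\n"
        )
        model = sc.read_peaklist(path)
        assert model.name == "alanine_like"
        assert model.multiplets[0].j_hz == (7.2, 7.2)
        assert model.multiplets[1].linewidth_hz == 1.5

    def test_peaklist_bad_row_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1.48 7.2 3\n")  # spaces, not tabs
        with pytest.raises(sc.ParseError, match="bad.tsv:1"):
            sc.read_peaklist(path)


class TestLibraries:
    def test_builtin_library_has_21_unique_named_models(self):
        lib = sc.builtin_library()
        assert len(lib) == 21
        assert len({m.name for m in lib}) == 21
        for m in lib:
            assert m.multiplets
            for mult in m.multiplets:
                assert 0.5 <= mult.center_ppm <= 9.5
                assert all(2.0 <= j <= 12.0 for j in mult.j_hz)

    def test_extended_library_deterministic_and_prefixed(self):
        a = sc.extended_library(87)
        b = sc.extended_library(87)
        assert len(a) == 87
        assert sc.library_hash(a) == sc.library_hash(b)
        assert a[:21] == sc.builtin_library()

    def test_library_hash_changes_with_content(self):
        assert sc.library_hash(sc.builtin_library(5)) != sc.library_hash(sc.builtin_library(6))
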