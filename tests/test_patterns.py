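import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmpscan.patterns import (
    GrayCodeSpec,
    PSPSpec,
    PatternConfigError,
    PatternStack,
    fringe_band_index,
    gray_decode,
    gray_encode,
    gray_encode_int,
    gray_order_lut,
    make_gray_code_patterns,
    make_psp_patterns,
    make_scan_patterns,
)


def small_spec(**kw):
    defaults = dict(width_px=240, height_px=4, n_steps=12, n_periods=4)
    defaults.update(kw)
    return PSPSpec(**defaults)


class TestPSPSpec:
    def test_rejects_clipping(self):
        with pytest.raises(PatternConfigError, match="clip"):
            small_spec(mean_level=0.7, amplitude=0.5)
        with pytest.raises(PatternConfigError, match="clip"):
            small_spec(mean_level=0.3, amplitude=0.5)

    def test_rejects_too_few_steps(self):
        with pytest.raises(PatternConfigError, match="n_steps"):
            small_spec(n_steps=2)

    def test_rejects_misaligned_periods(self):
        with pytest.raises(PatternConfigError, match="divisible"):
            small_spec(width_px=250, n_periods=4)


class TestPSPPatterns:
    def test_twelve_step_has_twelve_frames(self):
        stack = make_psp_patterns(small_spec(n_steps=12))
        assert len(stack) == 12
        assert all(k == "psp" for k in stack.kinds)

    def test_cosine_profile_and_row_invariance(self):
        # column u of frame n must be A + B cos(2 pi u n_per / W + off + 2 pi n / N)
        spec = small_spec(mean_level=0.5, amplitude=0.4)
        stack = make_psp_patterns(spec)
        u = np.arange(spec.width_px)
        for n, frame in enumerate(stack.frames):
            expected = 0.5 + 0.4 * np.cos(
                2 * np.pi * spec.n_periods * u / spec.width_px
                + spec.phase_offset + 2 * np.pi * n / spec.n_steps
            )
            assert np.allclose(frame[0], expected, atol=1e-12)
            assert np.all(frame == frame[0])  # fringes vertical: rows identical

    def test_phase_zero_column_with_zero_offset(self):
        # with no phase offset the u = 0 column of frame 0 is at the peak
        spec = small_spec(mean_level=0.5, amplitude=0.5, phase_offset=0.0)
        stack = make_psp_patterns(spec)
        assert stack.frames[0][0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_frame_sum_is_n_times_mean(self):
        # equally spaced cosines cancel: per-pixel mean equals mean_level
        spec = small_spec()
        total = np.sum(make_psp_patterns(spec).frames, axis=0)
        assert np.allclose(total, spec.n_steps * spec.mean_level, atol=1e-12)


class TestGrayCodes:
    def test_encode_decode_examples(self):
        assert gray_decode(gray_encode(0, 4)) == 0
        np.testing.assert_array_equal(gray_encode(5, 4), [0, 1, 1, 1])
        assert gray_decode(np.array([0, 1, 1, 1])) == 5

    def test_roundtrip_exhaustive_up_to_ten_bits(self):
        for m in range(1, 11):
            k = np.arange(2 ** m)
            assert np.array_equal(
                np.asarray(
                    [gray_decode(gray_encode(int(v), m), n_bits=m) for v in k[:64]]
                ),
                k[:64],
            )
            # vectorized identity over the whole range
            g = gray_encode_int(k)
            assert np.array_equal(gray_order_lut(m)[g], k)

    def test_adjacent_codes_differ_in_one_bit(self):
        for m in (4, 6):
            k = np.arange(2 ** m)
            g = gray_encode_int(k)
            ham = np.array([bin(int(a ^ b)).count("1") for a, b in zip(g[:-1], g[1:])])
            assert np.all(ham == 1)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=1023))
    def test_roundtrip_property(self, k):
        assert gray_decode(gray_encode(k, 10), n_bits=10) == k

    def test_decode_length_mismatch(self):
        with pytest.raises(ValueError, match="bits"):
            gray_decode(np.array([0, 1]), n_bits=4)


class TestGrayCodePatterns:
    def test_sixteen_periods_need_four_k1_frames(self):
        spec = GrayCodeSpec.for_psp(PSPSpec(width_px=1920, height_px=2, n_periods=16))
        stack = make_gray_code_patterns(spec)
        assert sum(k == "gray_k1" for k in stack.kinds) == 4
        assert sum(k == "gray_k2" for k in stack.kinds) == 5

    def test_single_bit_pattern_splits_in_half(self):
        spec = GrayCodeSpec(width_px=100, height_px=2, n_bits=1,
                            pixels_per_period=50, include_complementary=False)
        stack = make_gray_code_patterns(spec)
        frame = stack.frames[0]
        assert np.all(frame[:, :50] == 0) and np.all(frame[:, 50:] == 1)

    def test_band_codewords_unique(self):
        # every period-wide band carries a codeword distinct from all others
        spec = GrayCodeSpec.for_psp(small_spec(n_periods=4))
        stack = make_gray_code_patterns(spec)
        g1 = stack.gray_k1_frames
        words = set()
        for band in range(4):
            cols = slice(band * 60, (band + 1) * 60)
            word = tuple(int(g1[i][0, cols].mean() > 0.5) for i in range(len(g1)))
            for i in range(len(g1)):  # band must be constant
                assert np.all(g1[i][0, cols] == g1[i][0, band * 60])
            words.add(word)
        assert len(words) == 4

    def test_too_few_bits_rejected(self):
        with pytest.raises(PatternConfigError, match="bands"):
            GrayCodeSpec(width_px=240, height_px=2, n_bits=1, pixels_per_period=60)

    def test_complementary_bands_shifted_half_period(self):
        x = np.arange(240)
        b1 = fringe_band_index(x, 60, shifted=False)
        b2 = fringe_band_index(x, 60, shifted=True)
        assert b1.min() == 0 and b1.max() == 3
        assert b2.min() == 0 and b2.max() == 4
        # k2 transitions occur 30 px after k1 transitions
        t1 = np.nonzero(np.diff(b1))[0]   # 59, 119, 179
        t2 = np.nonzero(np.diff(b2))[0]   # 29, 89, 149, 209
        assert np.array_equal(t2[1:] - t1, np.full(len(t1), 30))
        assert t2[0] == t1[0] - 30


class TestStackIO:
    def test_full_scan_stack_counts(self):
        stack = make_scan_patterns(PSPSpec(width_px=1920, height_px=2))
        assert len(stack) == 21  # 12 PSP + 4 k1 + 5 k2

    def test_png_roundtrip(self, tmp_path):
        stack = make_scan_patterns(small_spec(height_px=8))
        stack.save(tmp_path)
        names = sorted(p.name for p in tmp_path.glob("*.png"))
        assert names[0] == "gray1_00.png" and "psp_00.png" in names
        loaded = PatternStack.load(tmp_path)
        assert loaded.kinds == stack.kinds
        for a, b in zip(loaded.frames, stack.frames):
            assert np.abs(a - b).max() <= 0.5 / 255 + 1e-9
        assert loaded.psp_spec == stack.psp_spec
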