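"""Embedded zerotree codec: thresholds, passes, bitstreams, rate accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ezweeg import ezw
from ezweeg.ezw import CoderState, EZWBitstream, bits_per_sample, decode, dominant_pass, encode
from ezweeg.wavelet import WaveletCoeffs, dwt_multilevel, quantize_coeffs
from conftest import make_pyramid, oracle_dominant_pass


def _pyr(approx, *details):
    return WaveletCoeffs(
        approx=np.asarray(approx, dtype=float),
        details=[np.asarray(d, dtype=float) for d in details],
        original_length=sum(len(b) for b in [approx, *details]),
    )


class TestInitialThreshold:
    @pytest.mark.parametrize(
        "maxval,expected", [(57, 32), (1, 1), (64, 64), (2, 2), (255, 128)]
    )
    def test_power_of_two_rule(self, maxval, expected):
        c = _pyr([maxval], [0], [0, 0])
        assert ezw.initial_threshold(c) == expected

    def test_all_zero_marks_empty(self):
        c = _pyr([0], [0], [0, 0])
        assert ezw.initial_threshold(c) == 0
        stream = encode(c)
        assert stream.t0 == 0 and stream.passes == []
        np.testing.assert_array_equal(decode(stream).to_array(), 0.0)


class TestDominantPass:
    def test_hand_traced_first_pass(self):
        c = _pyr([8], [-4], [2, 1])
        state = CoderState(4)
        symbols, newly = dominant_pass(c, 8, state)
        assert symbols == ["POS", "ZTR"]
        assert newly == [0]

    def test_hand_traced_second_pass(self):
        c = _pyr([8], [-4], [2, 1])
        state = CoderState(4)
        dominant_pass(c, 8, state, 0)
        symbols, _ = dominant_pass(c, 4, state, 1)
        assert symbols == ["NEG", "ZTR", "ZTR"]

    def test_all_significant_no_ztr(self):
        c = _pyr([9], [-10], [12, 15])
        symbols, _ = dominant_pass(c, 8, CoderState(4))
        assert "ZTR" not in symbols and "IZ" not in symbols

    def test_isolated_zero_when_descendant_significant(self):
        c = _pyr([0], [0], [9, 0])
        symbols, _ = dominant_pass(c, 8, CoderState(4))
        assert symbols == ["IZ", "IZ", "POS", "ZTR"]

    def test_matches_brute_force_on_random_pyramids(self, rng):
        for _ in range(50):
            c = make_pyramid(16, 3, rng, lo=-5, hi=5)
            bands = [b.astype(np.int64) for b in c.bands()]
            t0 = ezw.initial_threshold(c)
            if t0 == 0:
                continue
            state = CoderState(c.total_count)
            sizes = [b.size for b in bands]
            off = np.cumsum([0] + sizes)
            t, pass_index = t0, 0
            while t >= 1:
                sig = [
                    state.significant[off[j] : off[j + 1]].copy()
                    for j in range(len(bands))
                ]
                expected = oracle_dominant_pass(bands, sig, t)
                got, _ = dominant_pass(c, t, state, pass_index)
                assert [ezw.SYMBOL_NAMES.index(s) for s in got] == expected
                t //= 2
                pass_index += 1


class TestRefinement:
    def test_no_significant_coeffs_empty(self):
        c = _pyr([0], [0], [3, 0])
        bits = ezw.refinement_pass(c, CoderState(4), pass_index=1)
        assert bits == []

    @pytest.mark.parametrize("magnitude,expected_bit", [(12, 1), (9, 0), (15, 1), (8, 0)])
    def test_midpoint_rule_for_coeff_found_at_t8(self, magnitude, expected_bit):
        c = _pyr([magnitude], [0], [0, 0])
        state = CoderState(4)
        dominant_pass(c, 8, state, 0)  # found at T=8, interval [8,16)
        bits = ezw.refinement_pass(c, state, pass_index=1)
        assert bits == [expected_bit]


class TestEncodeDecode:
    def test_lossless_round_trip(self, rng):
        for n in [8, 37, 250, 512]:
            c = make_pyramid(n, 3, rng)
            np.testing.assert_array_equal(decode(encode(c)).to_array(), c.to_array())

    def test_negative_values_round_trip(self):
        c = _pyr([-57], [33], [-1, 0])
        np.testing.assert_array_equal(decode(encode(c)).to_array(), c.to_array())

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_lossless_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 300))
        c = make_pyramid(n, 3, rng, lo=-1000, hi=1000)
        np.testing.assert_array_equal(decode(encode(c)).to_array(), c.to_array())

    def test_budget_never_exceeded(self, rng):
        c = make_pyramid(256, 3, rng)
        for budget in [16, 64, 300, 1000]:
            stream = encode(c, max_bits=budget)
            assert stream.total_bits + ezw.HEADER_BITS <= budget

    def test_doubling_budget_never_hurts(self, rng):
        c = make_pyramid(256, 3, rng)
        flat = c.to_array()
        errs = []
        for budget in [128, 256, 512, 1024, 4096]:
            rec = decode(encode(c, max_bits=budget)).to_array()
            errs.append(np.sqrt(np.mean((rec - flat) ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_budget_below_header_rejected(self, rng):
        c = make_pyramid(16, 2, rng)
        with pytest.raises(ValueError):
            encode(c, max_bits=4)

    def test_noninteger_coeffs_rejected(self):
        c = _pyr([1.5], [0], [0, 0])
        with pytest.raises(ValueError):
            encode(c)

    def test_prefix_decodes_like_truncated_stream(self, rng):
        c = make_pyramid(128, 3, rng)
        full = encode(c)
        flat = c.to_array()
        prev_err = np.inf
        for k in range(len(full.passes) + 1):
            a = decode(full.truncated(k)).to_array()
            # earlier prefixes are coarser but never contradictory
            assert np.all((a == 0) | (np.sign(a) == np.sign(flat)))
            err = np.sqrt(np.mean((a - flat) ** 2))
            assert err <= prev_err + 1e-12
            prev_err = err
        assert prev_err == 0.0

    def test_decoder_state_matches_encoder_per_pass(self, rng):
        c = make_pyramid(64, 3, rng, lo=-40, hi=40)
        full = encode(c)
        # replay the encoder's significance evolution independently
        state_enc = CoderState(c.total_count)
        t, pass_index = full.t0, 0
        for k in range(len(full.passes)):
            dominant_pass(c, t, state_enc, pass_index)
            ezw.refinement_pass(c, state_enc, pass_index)
            _, state_dec = decode(full.truncated(k + 1), return_state=True)
            np.testing.assert_array_equal(state_dec.significant, state_enc.significant)
            assert state_dec.order == state_enc.order
            t //= 2
            pass_index += 1


class TestBitstreamContainer:
    def test_bytes_round_trip(self, rng):
        c = make_pyramid(100, 3, rng)
        stream = encode(c, max_bits=512, cluster_preamble=7)
        back = EZWBitstream.from_bytes(stream.to_bytes())
        assert back.t0 == stream.t0
        assert back.cluster_preamble == 7
        assert back.total_bits == stream.total_bits
        np.testing.assert_array_equal(decode(back).to_array(), decode(stream).to_array())

    def test_bad_magic_rejected(self):
        with pytest.raises(ValueError):
            EZWBitstream.from_bytes(b"NOPE" + bytes(64))

    def test_quant_step_travels(self, rng):
        c = quantize_coeffs(dwt_multilevel(rng.standard_normal(64), 3), 0.125)
        stream = encode(c)
        back = EZWBitstream.from_bytes(stream.to_bytes())
        assert back.quant_step == pytest.approx(0.125)
        assert decode(back).quant_step == pytest.approx(0.125)


class TestRateAccounting:
    def test_rate_formula(self):
        stream = EZWBitstream(t0=0, n_samples=250, levels=3, wavelet_name="db4")
        stream.passes = [
            ezw.Pass(np.zeros(900, dtype=np.int8), np.zeros(192, dtype=np.uint8))
        ]
        assert stream.total_bits == 1992
        assert bits_per_sample(stream) == pytest.approx(8.0)

    def test_header_only_rate(self):
        stream = EZWBitstream(t0=0, n_samples=8, levels=3, wavelet_name="db4")
        assert bits_per_sample(stream) == pytest.approx(1.0)

    def test_rate_decreases_with_n(self):
        streams = [
            EZWBitstream(t0=0, n_samples=n, levels=3, wavelet_name="db4")
            for n in (8, 16, 64)
        ]
        rates = [bits_per_sample(s) for s in streams]
        assert rates == sorted(rates, reverse=True)

    def test_preamble_counted_in_payload(self, rng):
        c = make_pyramid(64, 3, rng)
        plain = encode(c)
        with_preamble = encode(c, cluster_preamble=3)
        assert with_preamble.total_bits == plain.total_bits + ezw.PREAMBLE_BITS
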