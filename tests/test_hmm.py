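"""Profile-HMM construction and scoring against closed forms and the
path-enumeration oracle."""

import math

import numpy as np
import pytest

from conftest import (enumerate_paths, oracle_chain_posteriors,
                      random_tiny_architecture)
from hmmdemux.architecture import parse_architecture, parse_segment
from hmmdemux.hmm import (BackgroundModel, ErrorModel, ScoringError,
                          assemble_global_hmm, background_score, backward,
                          barcode_confidence, build_segment_hmm,
                          extraction_quality, forward, forward_backward,
                          score_read, _chain_entry_posteriors)


class TestSegmentModels:
    def test_zero_error_spacer_is_deterministic(self, zero_error):
        h = build_segment_hmm(parse_segment("S:ACGT", 1), zero_error)
        assert math.exp(forward(h, "ACGT").logPxM) == pytest.approx(1.0)

    def test_impossible_emission_scores_zero(self, zero_error):
        h = build_segment_hmm(parse_segment("S:ACGT", 1), zero_error)
        assert forward(h, "ACGA").logPxM == -math.inf

    def test_read_segment_length_is_geometric(self, zero_error):
        E = 5.0
        h = build_segment_hmm(parse_segment("R:N", 1), zero_error,
                              expected_read_length=E)
        p = 1.0 - 1.0 / E
        for L in range(1, 11):
            got = math.exp(forward(h, "A" * L).logPxM)
            expected = 0.25 ** L * p ** (L - 1) * (1 - p)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_barcode_segment_has_background_chain(self):
        arch = parse_architecture(["B:GTA,AAC", "R:N"])
        h = assemble_global_hmm(arch)
        (group,) = h.barcode_groups
        labels = [lab for lab, _, _ in group.chains]
        assert labels == [0, 1, -1]          # two barcodes + background

    def test_no_background_chain_without_barcode(self):
        h = assemble_global_hmm(parse_architecture(["R:N"]))
        assert h.barcode_groups == ()


class TestForwardBackward:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_enumeration(self, seed, uniform_bg):
        rng = np.random.default_rng(seed)
        arch = random_tiny_architecture(rng)
        err = ErrorModel(base_error=0.05, indel_open=0.0)
        h = assemble_global_hmm(arch, err, uniform_bg, expected_read_length=3.0)
        x = "".join(rng.choice(list("ACGT"), rng.integers(2, 6)))
        total, _ = enumerate_paths(h, x)
        m = forward(h, x)
        if total == 0.0:
            assert m.logPxM == -math.inf
        else:
            assert m.logPxM == pytest.approx(math.log(total), rel=1e-9)
        assert backward(h, x).logPxM == pytest.approx(m.logPxM, rel=1e-9)

    def test_identity_on_random_architectures(self, uniform_bg):
        from conftest import random_architecture
        rng = np.random.default_rng(123)
        for _ in range(20):
            arch = random_architecture(rng)
            h = assemble_global_hmm(arch, ErrorModel(), uniform_bg)
            x = "".join(rng.choice(list("ACGT"), rng.integers(10, 40)))
            fwd = forward(h, x).logPxM
            bwd = backward(h, x).logPxM
            assert abs(fwd - bwd) < 1e-9

    def test_invalid_character_rejected(self, uniform_bg):
        h = assemble_global_hmm(parse_architecture(["R:N"]))
        with pytest.raises(ScoringError):
            forward(h, "ACGU")

    def test_base_error_monotonicity(self, uniform_bg):
        """For an exactly matching read, more assumed sequencing error
        never raises the model likelihood."""
        arch = parse_architecture(["S:ACGTAC", "B:GGTT,CCAA", "R:N"])
        read = "ACGTAC" + "GGTT" + "ACGTACGTAC"
        prev = math.inf
        for e in (0.0, 0.01, 0.05, 0.1, 0.2):
            h = assemble_global_hmm(arch, ErrorModel(base_error=e), uniform_bg)
            cur = forward(h, read).logPxM
            assert cur <= prev + 1e-12
            prev = cur


class TestBackgroundScore:
    def test_uniform_closed_form(self, uniform_bg):
        assert background_score("ACGTACGTAC", uniform_bg) == \
            pytest.approx(10 * math.log(0.25))

    def test_certain_base(self):
        bg = BackgroundModel(np.array([1.0, 0.0, 0.0, 0.0]))
        assert background_score("AAA", bg) == 0.0

    def test_zero_frequency_base(self):
        bg = BackgroundModel(np.array([0.5, 0.5, 0.0, 0.0]))
        assert background_score("G", bg) == -math.inf

    def test_n_scores_as_likeliest_base(self):
        bg = BackgroundModel(np.array([0.4, 0.3, 0.2, 0.1]))
        assert background_score("N", bg) == pytest.approx(math.log(0.4))


class TestBarcodeConfidence:
    def test_no_barcode_gives_full_confidence(self, uniform_bg):
        h = assemble_global_hmm(parse_architecture(["R:N"]))
        m = forward_backward(h, "ACGTACGT")
        V, winners = barcode_confidence(m, h)
        assert V == 1.0 and winners is None

    def test_symmetric_barcodes_split_evenly(self):
        # chains AAC / ACA are exactly symmetric on an A-homopolymer read;
        # a skewed background makes the competing background chain negligible
        bg = BackgroundModel(np.array([0.001, 0.5, 0.498, 0.001]))
        arch = parse_architecture(["B:AAC,ACA", "R:N"])
        h = assemble_global_hmm(arch, ErrorModel(base_error=0.05,
                                                 indel_open=0.0), bg)
        m = forward_backward(h, "AAA" + "CGCGCG")
        V, winners = barcode_confidence(m, h)
        assert V == pytest.approx(0.5, abs=1e-6)
        assert winners[0] in (0, 1)

    def test_chain_posteriors_sum_to_one(self, uniform_bg):
        arch = parse_architecture(["B:GTAT,AACC,CGGA", "R:N"])
        h = assemble_global_hmm(arch, ErrorModel(), uniform_bg)
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = "".join(rng.choice(list("ACGT"), 15))
            m = forward_backward(h, x)
            post = _chain_entry_posteriors(m, h, h.barcode_groups[0])
            assert sum(post) == pytest.approx(1.0, abs=1e-6)

    def test_matches_enumeration(self, uniform_bg):
        arch = parse_architecture(["B:G,A", "R:N"])
        h = assemble_global_hmm(arch, ErrorModel(base_error=0.1, indel_open=0.0),
                                uniform_bg, expected_read_length=3.0)
        for x in ("GAC", "ACG", "TTT", "GA"):
            m = forward_backward(h, x)
            got = _chain_entry_posteriors(m, h, h.barcode_groups[0])
            (want,) = oracle_chain_posteriors(h, x)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


class TestExtractionQuality:
    def test_equal_evidence(self):
        p, q = extraction_quality(-5.0, -5.0, 1.0)
        assert p == pytest.approx(0.5, abs=1e-12)
        assert q == pytest.approx(-10 * math.log10(0.5), abs=1e-9)

    def test_vanishing_background(self):
        p, q = extraction_quality(-5.0, -math.inf, 1.0)
        assert p == 0.0 and q == 60.0

    def test_half_confidence_without_background(self):
        p, q = extraction_quality(-5.0, -math.inf, 0.5)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_both_impossible_rejected(self):
        with pytest.raises(ScoringError):
            extraction_quality(-math.inf, -math.inf, 1.0)

    def test_ranges(self, uniform_bg):
        arch = parse_architecture(["B:GTAT,AACC", "R:N"])
        h = assemble_global_hmm(arch)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = "".join(rng.choice(list("ACGT"), 20))
            res, _ = score_read(h, x, uniform_bg)
            assert 0.0 <= res.p_error <= 1.0
            assert 0.0 <= res.V <= 1.0
            assert res.q >= 0.0
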