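"""Posterior labeling, optimal-accuracy decoding and extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_best_labeling, oracle_state_posteriors
from hmmdemux.architecture import parse_architecture
from hmmdemux.decoder import (SKIP_PENALTY, FastqRecord, decode_umi,
                              encode_umi, extract_read,
                              optimal_accuracy_decode, posterior_labels)
from hmmdemux.hmm import (ErrorModel, assemble_global_hmm,
                          forward_backward, score_read)


class TestPosteriorLabels:
    def test_deterministic_model_is_one_hot(self, zero_error, uniform_bg):
        arch = parse_architecture(["S:AC", "R:N"])
        h = assemble_global_hmm(arch, zero_error, uniform_bg,
                                expected_read_length=4.0)
        m = forward_backward(h, "ACGTT")
        post = posterior_labels(m, h)
        want = np.zeros((5, 3))
        want[:2, 0] = 1.0
        want[2:, 1] = 1.0
        assert post == pytest.approx(want, abs=1e-12)

    def test_rows_sum_to_one(self, uniform_bg):
        arch = parse_architecture(["B:GTA,AAC", "F:NN", "R:N"])
        h = assemble_global_hmm(arch, ErrorModel(), uniform_bg)
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = "".join(rng.choice(list("ACGT"), rng.integers(6, 25)))
            post = posterior_labels(m := forward_backward(h, x), h)
            assert post.sum(axis=1) == pytest.approx(np.ones(len(x)), abs=1e-6)

    def test_matches_enumeration(self, uniform_bg):
        arch = parse_architecture(["B:G,A", "R:N"])
        h = assemble_global_hmm(arch, ErrorModel(base_error=0.1,
                                                 indel_open=0.0),
                                uniform_bg, expected_read_length=3.0)
        for x in ("GACG", "TACG", "GG"):
            m = forward_backward(h, x)
            got = posterior_labels(m, h, fold_background=True)
            _, mass = oracle_state_posteriors(h, x)
            want = np.zeros_like(got)
            for s in range(h.n_states):
                if not h.is_silent[s]:
                    want[:, h.seg_of[s] - 1] += mass[:, s]
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


class TestOptimalAccuracyDecode:
    def test_one_hot_identity(self):
        arch = parse_architecture(["S:AA", "R:N"])
        post = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], float)
        assert list(optimal_accuracy_decode(post, arch)) == [1, 1, 2, 2]

    def test_uniform_ties_switch_earliest(self):
        arch = parse_architecture(["S:AAAA", "R:N"])
        post = np.full((4, 2), 0.5)
        labels = optimal_accuracy_decode(post, arch)
        assert list(labels) == [1, 2, 2, 2]
        assert post[np.arange(4), labels - 1].sum() == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 4))
        L = int(rng.integers(2, 7))
        specs = ["S:A"] * (K - 1) + ["R:N"]
        arch = parse_architecture(specs)
        post = rng.random((L, K))
        labels = optimal_accuracy_decode(post, arch)
        got = post[np.arange(L), labels - 1].sum()
        got += sum(SKIP_PENALTY for k in range(1, K + 1)
                   if k not in set(labels.tolist()))
        skip = np.full(K, SKIP_PENALTY)
        want = oracle_best_labeling(post, skip)
        assert got == pytest.approx(want, rel=1e-12)
        assert (np.diff(labels) >= 0).all()

    def test_monotone_even_on_adversarial_posteriors(self):
        arch = parse_architecture(["S:A", "B:GG,CC", "R:N"])
        rng = np.random.default_rng(0)
        for _ in range(20):
            post = rng.random((8, 3))
            labels = optimal_accuracy_decode(post, arch)
            assert (np.diff(labels) >= 0).all()


class TestExtractRead:
    def _decode(self, arch, h, bg, seq, threshold=0.0):
        res, m = score_read(h, seq, bg)
        labels = optimal_accuracy_decode(posterior_labels(m, h), arch)
        rec = FastqRecord("r", seq, "I" * len(seq))
        return extract_read(rec, labels, arch, res, threshold)

    def test_barcode_recognized_and_trimmed(self, uniform_bg):
        arch = parse_architecture(["B:GTA,AAC", "R:N"])
        h = assemble_global_hmm(arch, ErrorModel(), uniform_bg)
        lr = self._decode(arch, h, uniform_bg, "GTA" + "ACGTTACGATCG")
        assert lr.accepted
        assert lr.barcode == "GTA"
        assert lr.read_seq == "ACGTTACGATCG"
        assert len(lr.read_qual) == len(lr.read_seq)

    def test_identity_architecture_keeps_everything(self, uniform_bg):
        arch = parse_architecture(["R:N"])
        h = assemble_global_hmm(arch, ErrorModel(), uniform_bg)
        lr = self._decode(arch, h, uniform_bg, "ACGTACGTAA")
        assert lr.accepted and lr.read_seq == "ACGTACGTAA"

    def test_short_fingerprint_rejected(self, uniform_bg):
        arch = parse_architecture(
            ["F:NNN", "S:T", "F:NNNN", "S:T", "F:NNN", "B:GACTT", "S:GGGG",
             "R:N"])
        h = assemble_global_hmm(arch, ErrorModel(), uniform_bg)
        intact = "ACG" "T" "CGAT" "T" "GCA" "GACTT" "GGGG" "ACGTTACGATCGATCG"
        ok = self._decode(arch, h, uniform_bg, intact)
        assert ok.accepted and ok.umi_seq == "ACGCGATGCA"
        deleted = intact[:6] + intact[7:]       # drop one UMI base
        bad = self._decode(arch, h, uniform_bg, deleted)
        assert not bad.accepted and bad.reason == "fingerprint length"

    def test_below_threshold_rejected(self, uniform_bg):
        arch = parse_architecture(["B:GTA,AAC", "R:N"])
        h = assemble_global_hmm(arch, ErrorModel(), uniform_bg)
        lr = self._decode(arch, h, uniform_bg, "GTAACGTTACGATCG",
                          threshold=61.0)
        assert not lr.accepted and lr.reason == "threshold"

    def test_labels_monotone_in_segment_index(self, uniform_bg):
        arch = parse_architecture(["F:NN", "B:GTAC,AACC", "R:N"])
        h = assemble_global_hmm(arch, ErrorModel(), uniform_bg)
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = "".join(rng.choice(list("ACGT"), 20))
            lr = self._decode(arch, h, uniform_bg, x)
            assert (np.diff(lr.labels) >= 0).all()


class TestUmiEncoding:
    @pytest.mark.parametrize("umi,code", [
        ("AAAA", 0), ("ACGT", 27), ("T", 3), ("GG", 10),
    ])
    def test_declared_examples(self, umi, code):
        assert encode_umi(umi) == code

    def test_ambiguous_umi_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            encode_umi("ACNG")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=12))
    def test_roundtrip_injective(self, umi):
        assert decode_umi(encode_umi(umi), len(umi)) == umi
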