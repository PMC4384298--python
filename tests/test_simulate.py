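"""Benchmark simulation and recall/precision accounting."""

import numpy as np
import pytest

from hmmdemux.architecture import parse_architecture
from hmmdemux.decoder import LabeledRead
from hmmdemux.simulate import (evaluate, generate_barcode_set, hamming,
                               simulate_dataset)


class TestBarcodeDesign:
    def test_pairwise_distance_constraint(self):
        pair = generate_barcode_set(2, 4, 2, seed=1)
        assert hamming(*pair) >= 2

    def test_six_nt_design_distance_three(self):
        bcs = generate_barcode_set(8, 6, 3, seed=5)
        assert len(set(bcs)) == 8
        for i in range(8):
            for j in range(i + 1, 8):
                assert hamming(bcs[i], bcs[j]) >= 3

    def test_infeasible_request_errors(self):
        # sphere packing: 4^4 = 256 codewords cannot host 300 at distance 3
        with pytest.raises(ValueError):
            generate_barcode_set(300, 4, 3, seed=0, max_tries=20_000)

    def test_deterministic_given_seed(self):
        assert generate_barcode_set(4, 5, 2, seed=9) == \
            generate_barcode_set(4, 5, 2, seed=9)


class TestSimulateDataset:
    def _arch(self):
        bcs = generate_barcode_set(4, 6, 3, seed=2)
        return parse_architecture([f"B:{','.join(bcs)}", "F:NNNN", "R:N"]), bcs

    def test_error_free_records_render_exactly(self):
        arch, bcs = self._arch()
        ds = simulate_dataset(arch, error_rate=0.0, n_true=50, n_random=10,
                              read_length=20, seed=3)
        assert ds.n_true == 50 and ds.n_random == 10
        for rid, seq, qual in ds.records:
            t = ds.truth[rid]
            assert len(seq) == len(qual)
            if t.origin == "true":
                assert seq.startswith(bcs[t.barcode_index])
                assert seq[6:10] == t.umi
                assert t.read_end - t.read_start == 20
            else:
                assert t.barcode_index == -1

    def test_substitution_rate_within_binomial_bound(self):
        arch, bcs = self._arch()
        err = 0.05
        ds = simulate_dataset(arch, error_rate=err, n_true=400, n_random=0,
                              read_length=30, seed=4)
        clean = simulate_dataset(arch, error_rate=0.0, n_true=400, n_random=0,
                                 read_length=30, seed=4)
        diffs = total = 0
        for (rid, seq, _), (_, ref, _) in zip(ds.records, clean.records):
            diffs += sum(a != b for a, b in zip(seq, ref))
            total += len(seq)
        sigma = np.sqrt(err * (1 - err) / total)
        assert abs(diffs / total - err) < 3 * sigma

    def test_deterministic_given_seed(self):
        arch, _ = self._arch()
        a = simulate_dataset(arch, error_rate=0.02, n_true=30, n_random=5,
                             seed=8)
        b = simulate_dataset(arch, error_rate=0.02, n_true=30, n_random=5,
                             seed=8)
        assert a.records == b.records


def _labeled(rid, accepted, barcode=None, reason=None):
    return LabeledRead(source=rid, labels=np.array([1]), read_seq="A",
                       read_qual="I", barcode=barcode, umi_seq="",
                       umi_code=None, q=40.0, accepted=accepted,
                       reason=reason)


class TestEvaluate:
    def _truth(self):
        arch = parse_architecture(["B:AAA,CCC", "R:N"])
        ds = simulate_dataset(arch, error_rate=0.0, n_true=6, n_random=4,
                              read_length=5, seed=0)
        return ds

    def test_perfect_extraction(self):
        ds = self._truth()
        labeled = []
        for rid, _, _ in ds.records:
            t = ds.truth[rid]
            if t.origin == "true":
                labeled.append(_labeled(rid, True,
                                        ds.barcodes[t.barcode_index]))
            else:
                labeled.append(_labeled(rid, False, reason="threshold"))
        ev = evaluate(labeled, ds.truth, barcodes=ds.barcodes)
        assert ev.recall == 1.0 and ev.precision == 1.0
        assert ev.misassigned == 0 and ev.false_positives == 0

    def test_nothing_accepted_vacuous_precision(self):
        ds = self._truth()
        labeled = [_labeled(rid, False, reason="threshold")
                   for rid, _, _ in ds.records]
        ev = evaluate(labeled, ds.truth, barcodes=ds.barcodes)
        assert ev.recall == 0.0 and ev.precision == 1.0

    def test_hand_computed_counts(self):
        """10 reads: 6 true (4 right barcode, 1 wrong, 1 rejected),
        4 random (1 falsely accepted)."""
        arch = parse_architecture(["B:AAA,CCC", "R:N"])
        ds = simulate_dataset(arch, error_rate=0.0, n_true=6, n_random=4,
                              read_length=5, seed=1)
        trues = [rid for rid, _, _ in ds.records
                 if ds.truth[rid].origin == "true"]
        randoms = [rid for rid, _, _ in ds.records
                   if ds.truth[rid].origin == "random"]
        labeled = []
        for rid in trues[:4]:
            labeled.append(_labeled(rid, True,
                                    ds.barcodes[ds.truth[rid].barcode_index]))
        wrong = ds.barcodes[1 - ds.truth[trues[4]].barcode_index]
        labeled.append(_labeled(trues[4], True, wrong))
        labeled.append(_labeled(trues[5], False, reason="threshold"))
        labeled.append(_labeled(randoms[0], True, ds.barcodes[0]))
        for rid in randoms[1:]:
            labeled.append(_labeled(rid, False, reason="threshold"))
        ev = evaluate(labeled, ds.truth, barcodes=ds.barcodes)
        assert ev.recall == pytest.approx(4 / 6)
        assert ev.precision == pytest.approx(4 / 6)
        assert ev.misassigned == 1
        assert ev.false_positives == 1
        assert ev.n_assigned == 6
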