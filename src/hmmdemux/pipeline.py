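"""End-to-end extraction pipeline.

Streams FASTQ (optionally gzip-compressed, single- or paired-end) through:
architecture auto-detection (when a library of candidates is given) ->
background estimation -> automatic threshold calibration -> per-read
forward/backward scoring, optimal-accuracy decoding and trimming ->
low-complexity and contaminant filtering -> demultiplexed per-barcode
FASTQ outputs, an "unextracted" file carrying rejection reasons, and a
machine-readable run report whose counts partition the input exactly.

Runs are deterministic given the configuration and seed; the ``threads``
field is accepted for interface compatibility and never changes results
(processing is sequential).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .architecture import (ArchitectureLibrary, ReadArchitecture,
                           load_architecture_file)
from .calibration import (ThresholdResult, calibrate_threshold, emit_from_model,
                          emit_random, select_threshold)
from .decoder import (FastqRecord, optimal_accuracy_decode,
                      posterior_labels, extract_read)
from .filters import (DEFAULT_DUST_THRESHOLD, DEFAULT_MAX_EDITS, _best_hit,
                      dust_score)
from .hmm import (BackgroundModel, ErrorModel, ProfileHMM, ScoreResult,
                  assemble_global_hmm, background_score,
                  extraction_quality, forward, score_read)

__all__ = [
    "RunConfig",
    "RunReport",
    "read_fastq",
    "write_fastq",
    "open_maybe_gzip",
    "detect_architecture",
    "run",
]


def open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    """Open plain or gzip text transparently; gzip output uses mtime=0 so
    identical runs produce byte-identical files."""
    path = Path(path)
    if path.suffix == ".gz":
        if "r" in mode:
            return gzip.open(path, mode)
        raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
        return io.TextIOWrapper(gz, newline="\n")
    return open(path, mode, newline="" if "r" in mode else "\n")


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream FASTQ records; malformed records raise with their position."""
    with open_maybe_gzip(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        idx = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ record {idx + 1} "
                    f"(around line {idx * 4 + 1}): {exc}"
                ) from exc
            idx += 1
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: record {idx} ({title.split()[0]!r}, around line "
                    f"{(idx - 1) * 4 + 1}): sequence and quality lengths differ"
                )
            yield FastqRecord(id=title, seq=seq.upper(), qual=qual)


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with open_maybe_gzip(path, "wt") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


class _LazyWriter:
    def __init__(self, path: Path):
        self.path = path
        self._fh: IO | None = None

    def write(self, rec: FastqRecord) -> None:
        if self._fh is None:
            self._fh = open_maybe_gzip(self.path, "wt")
        self._fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()


@dataclass
class RunConfig:
    """Configuration of one extraction run."""

    input1: str
    output_prefix: str
    input2: str | None = None
    architecture: ReadArchitecture | None = None
    architecture_file: str | None = None
    architecture2: ReadArchitecture | None = None     # paired-end mate model
    threshold: float | None = None                    # None = auto-calibrate
    error_model: ErrorModel = dc_field(default_factory=ErrorModel)
    expected_read_length: float = 1000.0
    reference_fasta: str | None = None
    max_edits: int = DEFAULT_MAX_EDITS
    dust_threshold: float = DEFAULT_DUST_THRESHOLD    # 0 disables
    seed: int = 42
    calibration_n: int = 10_000
    detect_sample: int = 1_000
    background_reads: int = 100_000                   # 0 = uniform background
    gzip_output: bool = False
    threads: int = 1                                  # results independent of it

    def __post_init__(self) -> None:
        if (self.architecture is None) == (self.architecture_file is None):
            raise ValueError(
                "exactly one of architecture / architecture_file must be set"
            )


@dataclass
class RunReport:
    """Machine-readable account of one run; counts partition the input."""

    input_reads: int
    chosen_architecture: str
    detection_scores: dict[str, float]
    threshold: float
    calibration: ThresholdResult | None
    accepted_per_barcode: dict[str, int]
    rejected_per_reason: dict[str, int]
    contaminant_counts: dict[str, int]

    @property
    def accepted(self) -> int:
        return sum(self.accepted_per_barcode.values())

    @property
    def rejected(self) -> int:
        return sum(self.rejected_per_reason.values())

    def validate(self) -> None:
        if self.accepted + self.rejected != self.input_reads:
            raise AssertionError(
                f"report does not partition input: {self.accepted} + "
                f"{self.rejected} != {self.input_reads}"
            )

    def to_tsv(self) -> str:
        rows = [("input_reads", self.input_reads),
                ("chosen_architecture", self.chosen_architecture),
                ("threshold", f"{self.threshold:.4f}")]
        if self.calibration is not None:
            rows += [("calibration_sensitivity", f"{self.calibration.sensitivity:.6f}"),
                     ("calibration_specificity", f"{self.calibration.specificity:.6f}")]
        for name, s in sorted(self.detection_scores.items()):
            rows.append((f"detection_score\t{name}", f"{s:.6f}"))
        for bc, c in sorted(self.accepted_per_barcode.items()):
            rows.append((f"accepted\t{bc}", c))
        for reason, c in sorted(self.rejected_per_reason.items()):
            rows.append((f"rejected\t{reason}", c))
        for ref, c in sorted(self.contaminant_counts.items()):
            rows.append((f"contaminant\t{ref}", c))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"

    def to_text(self) -> str:
        lines = [
            f"input reads          : {self.input_reads}",
            f"architecture         : {self.chosen_architecture}",
            f"extraction threshold : q >= {self.threshold:.3f}",
            f"accepted             : {self.accepted}",
        ]
        for bc, c in sorted(self.accepted_per_barcode.items()):
            lines.append(f"    {bc:<20s} {c}")
        lines.append(f"rejected             : {self.rejected}")
        for reason, c in sorted(self.rejected_per_reason.items()):
            lines.append(f"    {reason:<20s} {c}")
        return "\n".join(lines) + "\n"


def detect_architecture(sample_reads: list[str], lib: ArchitectureLibrary,
                        err: ErrorModel | None = None,
                        bg: BackgroundModel | None = None,
                        expected_read_length: float = 1000.0
                        ) -> tuple[ReadArchitecture, dict[str, float]]:
    """Pick the candidate architecture with the highest mean log-odds
    log P(x|M) - log P(x|R) over the sampled reads; ties go to the first
    architecture in file order."""
    if not sample_reads:
        raise ValueError("architecture detection needs at least one read")
    bg = bg or BackgroundModel.uniform()
    scores: dict[str, float] = {}
    best_name = None
    for arch in lib:
        hmm = assemble_global_hmm(arch, err, bg, expected_read_length)
        total = 0.0
        for x in sample_reads:
            total += forward(hmm, x).logPxM - background_score(x, bg)
        scores[arch.name] = total / len(sample_reads)
        if best_name is None or scores[arch.name] > scores[best_name]:
            best_name = arch.name
    return lib[best_name], scores


def _score_pair(hmm1: ProfileHMM, hmm2: ProfileHMM | None,
                bg: BackgroundModel, x1: str, x2: str | None):
    """Joint evidence for a mate pair: likelihoods multiply, V multiplies."""
    res1, m1 = score_read(hmm1, x1, bg)
    if hmm2 is None or x2 is None:
        return res1, m1, None, None
    res2, m2 = score_read(hmm2, x2, bg)
    logM = res1.logPxM + res2.logPxM
    logR = res1.logPxR + res2.logPxR
    V = res1.V * res2.V
    p_err, q = extraction_quality(logM, logR, V)
    joint = ScoreResult(logPxM=logM, logPxR=logR, V=V, p_error=p_err, q=q,
                        best_barcode=res1.best_barcode
                        if res1.best_barcode is not None else res2.best_barcode)
    return joint, m1, res2, m2


def _calibrate(cfg: RunConfig, hmm1: ProfileHMM, hmm2: ProfileHMM | None,
               bg: BackgroundModel, read_length: int) -> ThresholdResult:
    if hmm2 is None:
        return calibrate_threshold(hmm1, bg, n=cfg.calibration_n,
                                   seed=cfg.seed, read_length=read_length)
    n = cfg.calibration_n
    r1 = emit_from_model(hmm1, n, cfg.seed, read_length=read_length)
    r2 = emit_from_model(hmm2, n, cfg.seed + 7, read_length=read_length)
    d1 = emit_random(bg, n, cfg.seed + 1, [len(x) for x in r1])
    d2 = emit_random(bg, n, cfg.seed + 8, [len(x) for x in r2])
    q_model = [_score_pair(hmm1, hmm2, bg, a, b)[0].q for a, b in zip(r1, r2)]
    q_random = [_score_pair(hmm1, hmm2, bg, a, b)[0].q for a, b in zip(d1, d2)]
    return select_threshold(q_model, q_random, n_model=n, n_random=n,
                            seed=cfg.seed)


def _fixed_prefix_length(arch: ReadArchitecture) -> int:
    return sum(s.length or 0 for s in arch.segments)


def _pair_key(title: str) -> str:
    name = title.split()[0]
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        name = name[:-2]
    return name


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline; returns (and writes) the run report."""
    cfg = config
    prefix = Path(cfg.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if cfg.gzip_output else ".fastq"

    # pass 1: sample reads for background estimation and detection
    sample: list[str] = []
    n_bg = max(cfg.background_reads, cfg.detect_sample)
    for i, rec in enumerate(read_fastq(cfg.input1)):
        if i >= n_bg:
            break
        sample.append(rec.seq)
    if not sample:
        raise ValueError(f"{cfg.input1}: no reads")
    bg = (BackgroundModel.from_reads(sample, cfg.background_reads)
          if cfg.background_reads > 0 else BackgroundModel.uniform())

    detection_scores: dict[str, float] = {}
    if cfg.architecture is not None:
        arch = cfg.architecture
    else:
        lib = load_architecture_file(cfg.architecture_file)
        arch, detection_scores = detect_architecture(
            sample[:cfg.detect_sample], lib, cfg.error_model, bg,
            cfg.expected_read_length)

    hmm1 = assemble_global_hmm(arch, cfg.error_model, bg,
                               cfg.expected_read_length)
    hmm2 = (assemble_global_hmm(cfg.architecture2, cfg.error_model, bg,
                                cfg.expected_read_length)
            if cfg.architecture2 is not None else None)

    median_len = int(np.median([len(s) for s in sample]))
    body_len = max(5, median_len - _fixed_prefix_length(arch))
    calibration = None
    if cfg.threshold is None:
        calibration = _calibrate(cfg, hmm1, hmm2, bg, body_len)
        threshold = calibration.threshold
    else:
        threshold = cfg.threshold

    references = None
    if cfg.reference_fasta:
        from Bio import SeqIO
        references = [(r.id, str(r.seq))
                      for r in SeqIO.parse(cfg.reference_fasta, "fasta")]

    writers: dict[str, _LazyWriter] = {}
    writers2: dict[str, _LazyWriter] = {}

    def writer(bucket: str, mate: int) -> _LazyWriter:
        pool = writers if mate == 1 else writers2
        if bucket not in pool:
            pool[bucket] = _LazyWriter(prefix.parent /
                                       f"{prefix.name}_{bucket}_R{mate}{ext}")
        return pool[bucket]

    accepted_per_barcode: dict[str, int] = {}
    rejected: dict[str, int] = {}
    contam_counts: dict[str, int] = {}
    n_input = 0

    stream1 = read_fastq(cfg.input1)
    stream2 = read_fastq(cfg.input2) if cfg.input2 else None

    for rec1 in stream1:
        rec2 = None
        if stream2 is not None:
            try:
                rec2 = next(stream2)
            except StopIteration:
                raise ValueError("paired files have different record counts")
            if _pair_key(rec1.id) != _pair_key(rec2.id):
                raise ValueError(
                    f"paired files desynchronized at {rec1.id!r} / {rec2.id!r}"
                )
        n_input += 1
        score, m1, _, m2 = _score_pair(hmm1, hmm2, bg, rec1.seq,
                                       rec2.seq if rec2 else None)
        labels1 = optimal_accuracy_decode(posterior_labels(m1, hmm1), arch)
        lr1 = extract_read(rec1, labels1, arch, score, threshold)
        lr2 = None
        if hmm2 is not None and rec2 is not None:
            labels2 = optimal_accuracy_decode(
                posterior_labels(m2, hmm2), cfg.architecture2)
            lr2 = extract_read(rec2, labels2, cfg.architecture2, score,
                               threshold)

        reason = lr1.reason or (lr2.reason if lr2 is not None else None)
        out_seq, out_qual = lr1.read_seq, lr1.read_qual
        if reason is None and cfg.dust_threshold > 0:
            if dust_score(out_seq, cfg.dust_threshold).flagged:
                reason = "low complexity"
        if reason is None and references:
            hit = _best_hit(rec1.id, out_seq, references, cfg.max_edits)
            if hit is not None:
                reason = f"contaminant:{hit.reference}"
                contam_counts[hit.reference] = \
                    contam_counts.get(hit.reference, 0) + 1

        if reason is None:
            bucket = f"BC_{lr1.barcode}" if lr1.barcode else "extracted"
            annot = ""
            if lr1.barcode:
                annot += f";BC:{lr1.barcode}"
            if lr1.umi_seq:
                annot += f";UMI:{lr1.umi_code}"
            annot += f";Q:{score.q:.2f}"
            writer(bucket, 1).write(FastqRecord(rec1.id + annot, out_seq,
                                                out_qual))
            if rec2 is not None:
                if lr2 is not None:
                    writer(bucket, 2).write(
                        FastqRecord(rec2.id + annot, lr2.read_seq,
                                    lr2.read_qual))
                else:
                    writer(bucket, 2).write(rec2)
            key = lr1.barcode or "-"
            accepted_per_barcode[key] = accepted_per_barcode.get(key, 0) + 1
        else:
            key = "contaminant" if reason.startswith("contaminant") else reason
            rejected[key] = rejected.get(key, 0) + 1
            writer("un", 1).write(
                FastqRecord(f"{rec1.id};FAIL:{reason}", rec1.seq, rec1.qual))
            if rec2 is not None:
                writer("un", 2).write(
                    FastqRecord(f"{rec2.id};FAIL:{reason}", rec2.seq,
                                rec2.qual))

    if stream2 is not None:
        try:
            next(stream2)
            raise ValueError("paired files have different record counts")
        except StopIteration:
            pass

    for pool in (writers, writers2):
        for w in pool.values():
            w.close()

    report = RunReport(
        input_reads=n_input,
        chosen_architecture=arch.name,
        detection_scores=detection_scores,
        threshold=threshold,
        calibration=calibration,
        accepted_per_barcode=accepted_per_barcode,
        rejected_per_reason=rejected,
        contaminant_counts=contam_counts,
    )
    report.validate()
    with open(f"{cfg.output_prefix}_report.txt", "w") as fh:
        fh.write(report.to_text())
    with open(f"{cfg.output_prefix}_report.tsv", "w") as fh:
        fh.write(report.to_tsv())
    return report
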