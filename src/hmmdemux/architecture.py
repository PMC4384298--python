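"""Read-architecture grammar.

A read architecture declares the expected layout of a raw sequencing read as
an ordered list of segments: sample barcodes (``B``), random fingerprints /
UMIs (``F``), constant spacers (``S``), possibly-truncated 5'/3' adapters
(``P``) and exactly one variable-length mappable read (``R``).  The textual
form mirrors the command line of classic demultiplexers::

    B:GTA,AAC      two mutually exclusive 3-nt barcodes
    F:NNNN         a 4-nt fingerprint (UMI)
    S:GGGG         a constant spacer
    P:AGGGAGG      an adapter that may be truncated at a read end
    R:N            the mappable read itself

Architecture files hold one named architecture per line
(``<name> <spec> <spec> ...``); ``#`` starts a comment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

__all__ = [
    "SegmentKind",
    "SegmentSpec",
    "ReadArchitecture",
    "ArchitectureLibrary",
    "ArchitectureError",
    "parse_segment",
    "parse_architecture",
    "load_architecture_file",
]


class ArchitectureError(ValueError):
    """Raised for malformed segment specs or inconsistent architectures."""


class SegmentKind(str, Enum):
    BARCODE = "BARCODE"
    FINGERPRINT = "FINGERPRINT"
    SPACER = "SPACER"
    READ = "READ"
    PARTIAL = "PARTIAL"


_KIND_BY_LETTER = {
    "B": SegmentKind.BARCODE,
    "F": SegmentKind.FINGERPRINT,
    "S": SegmentKind.SPACER,
    "R": SegmentKind.READ,
    "P": SegmentKind.PARTIAL,
}
_LETTER_BY_KIND = {v: k for k, v in _KIND_BY_LETTER.items()}

_SEQ_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class SegmentSpec:
    """One block of a read architecture.

    Parameters
    ----------
    index
        1-based position of the segment within the architecture.
    kind
        The block type.
    sequences
        Mutually exclusive sequence alternatives.  For FINGERPRINT a single
        run of ``N``; for READ the single string ``"N"``.
    """

    index: int
    kind: SegmentKind
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ArchitectureError(f"segment index must be >= 1, got {self.index}")
        if not self.sequences:
            raise ArchitectureError(f"segment {self.index}: empty sequence list")
        for s in self.sequences:
            if not _SEQ_RE.match(s):
                raise ArchitectureError(
                    f"segment {self.index}: sequence {s!r} contains characters "
                    "outside A,C,G,T,N"
                )
        kind = self.kind
        if kind is SegmentKind.BARCODE:
            lens = {len(s) for s in self.sequences}
            if len(lens) != 1:
                raise ArchitectureError(
                    f"segment {self.index}: barcode alternatives have unequal "
                    f"lengths {sorted(len(s) for s in self.sequences)}"
                )
            if any("N" in s for s in self.sequences):
                raise ArchitectureError(
                    f"segment {self.index}: barcode sequences may not contain N"
                )
        elif kind is SegmentKind.FINGERPRINT:
            if len(self.sequences) != 1 or set(self.sequences[0]) != {"N"}:
                raise ArchitectureError(
                    f"segment {self.index}: fingerprint must be a single run of N"
                )
        elif kind is SegmentKind.READ:
            if self.sequences != ("N",):
                raise ArchitectureError(
                    f"segment {self.index}: read segment must be exactly 'N'"
                )
        elif kind is SegmentKind.SPACER:
            if len(self.sequences) != 1:
                raise ArchitectureError(
                    f"segment {self.index}: spacer takes exactly one sequence"
                )
            if "N" in self.sequences[0]:
                raise ArchitectureError(
                    f"segment {self.index}: N is not allowed in a spacer"
                )
        elif kind is SegmentKind.PARTIAL:
            if len(self.sequences) != 1:
                raise ArchitectureError(
                    f"segment {self.index}: partial adapter takes exactly one sequence"
                )
            if "N" in self.sequences[0]:
                raise ArchitectureError(
                    f"segment {self.index}: N is not allowed in a partial adapter"
                )

    @property
    def length(self) -> int | None:
        """Segment length in nucleotides; ``None`` for the variable READ."""
        if self.kind is SegmentKind.READ:
            return None
        return len(self.sequences[0])

    def to_spec(self) -> str:
        """Format back to ``<K>:<body>`` text form."""
        return f"{_LETTER_BY_KIND[self.kind]}:{','.join(self.sequences)}"


def parse_segment(spec: str, index: int) -> SegmentSpec:
    """Parse one ``<K>:<body>`` segment declaration.

    Lower-case input is accepted and upper-cased.  ``K`` is one of
    B/F/S/R/P; the body is a comma-separated list of sequences.
    """
    text = spec.strip()
    if ":" not in text:
        raise ArchitectureError(f"segment {index}: {spec!r} is not of the form K:BODY")
    letter, _, body = text.partition(":")
    letter = letter.strip().upper()
    if letter not in _KIND_BY_LETTER:
        raise ArchitectureError(
            f"segment {index}: unknown block type {letter!r} in {spec!r} "
            f"(expected one of {sorted(_KIND_BY_LETTER)})"
        )
    parts = [p.strip().upper() for p in body.split(",")]
    if any(not p for p in parts):
        raise ArchitectureError(f"segment {index}: empty sequence in {spec!r}")
    return SegmentSpec(index=index, kind=_KIND_BY_LETTER[letter], sequences=tuple(parts))


@dataclass(frozen=True)
class ReadArchitecture:
    """An ordered, validated sequence of segments with exactly one READ."""

    segments: tuple[SegmentSpec, ...]
    name: str = "arch"

    def __post_init__(self) -> None:
        n_read = sum(1 for s in self.segments if s.kind is SegmentKind.READ)
        if n_read != 1:
            raise ArchitectureError(
                f"architecture {self.name!r}: needs exactly one READ segment, "
                f"found {n_read}"
            )
        for i, seg in enumerate(self.segments, start=1):
            if seg.index != i:
                raise ArchitectureError(
                    f"architecture {self.name!r}: segment indices must be "
                    f"contiguous from 1 (segment {i} has index {seg.index})"
                )

    @property
    def total_fingerprint_length(self) -> int:
        return sum(
            len(s.sequences[0])
            for s in self.segments
            if s.kind is SegmentKind.FINGERPRINT
        )

    @property
    def barcode_segments(self) -> tuple[SegmentSpec, ...]:
        return tuple(s for s in self.segments if s.kind is SegmentKind.BARCODE)

    @property
    def read_segment(self) -> SegmentSpec:
        return next(s for s in self.segments if s.kind is SegmentKind.READ)

    def to_specs(self) -> list[str]:
        """Format back to the list of ``<K>:<body>`` strings."""
        return [s.to_spec() for s in self.segments]


def parse_architecture(specs: Sequence[str], name: str = "arch") -> ReadArchitecture:
    """Parse an ordered list of segment declarations into an architecture."""
    if not specs:
        raise ArchitectureError("architecture needs at least one segment")
    segments = tuple(parse_segment(s, i) for i, s in enumerate(specs, start=1))
    return ReadArchitecture(segments=segments, name=name)


@dataclass(frozen=True)
class ArchitectureLibrary:
    """A non-empty collection of uniquely named candidate architectures."""

    architectures: tuple[ReadArchitecture, ...]

    def __post_init__(self) -> None:
        if not self.architectures:
            raise ArchitectureError("architecture library is empty")
        names = [a.name for a in self.architectures]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ArchitectureError(f"duplicate architecture names: {dupes}")

    def __iter__(self):
        return iter(self.architectures)

    def __len__(self) -> int:
        return len(self.architectures)

    def __getitem__(self, name: str) -> ReadArchitecture:
        for a in self.architectures:
            if a.name == name:
                return a
        raise KeyError(name)


def load_architecture_file(path: str | Path) -> ArchitectureLibrary:
    """Load candidate architectures, one ``<name> <spec>...`` per line."""
    path = Path(path)
    archs: list[ReadArchitecture] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ArchitectureError(
                    f"{path}:{lineno}: expected '<name> <spec>...'"
                )
            try:
                archs.append(parse_architecture(fields[1:], name=fields[0]))
            except ArchitectureError as exc:
                raise ArchitectureError(f"{path}:{lineno}: {exc}") from exc
    return ArchitectureLibrary(architectures=tuple(archs))
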