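"""Reading and writing pairwise IBD segment files.

The native dialect is the hap-IBD output format: a headerless, tab-separated
file with eight columns per row —

    sample1  hap1  sample2  hap2  chrom  start_bp  end_bp  length_cM

Coordinates are 1-based and inclusive, haplotype indices are 1 or 2, and the
genetic length is in centimorgans.  Files whose name ends in ``.gz`` are
transparently (de)compressed.  A ``generic-tsv`` dialect accepts
individual-level input (sample1, sample2, chrom, start, end, plus a
centimorgan column selected by ``cm_col``); both haplotype indices are then
set to 1, which collapses the graph to one node per individual.

Malformed rows always raise :class:`IBDParseError` naming the offending line;
rows are never silently dropped.
"""

from __future__ import annotations

import csv
import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "IBDSegment",
    "TargetLocus",
    "IBDParseError",
    "read_ibd",
    "write_ibd",
    "parse_locus",
]


class IBDParseError(ValueError):
    """Raised when an IBD file row violates the format contract.

    Attributes
    ----------
    line_number : int or None
        1-based line number of the offending row, when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True, slots=True)
class IBDSegment:
    """One pairwise shared haplotype interval with its genetic length.

    Coordinates are 1-based and inclusive; ``length_cm`` is the genetic map
    length of the interval in centimorgans as reported by the upstream IBD
    detector (it is not recomputed from the physical coordinates).
    """

    sample1: str
    hap1: int
    sample2: str
    hap2: int
    chrom: str
    start_bp: int
    end_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.sample1 or not self.sample2:
            raise ValueError("sample ids must be non-empty")
        if self.sample1 == self.sample2:
            raise ValueError(
                f"within-individual segment not allowed: {self.sample1!r} on both sides"
            )
        if self.hap1 not in (1, 2) or self.hap2 not in (1, 2):
            raise ValueError(f"haplotype index must be 1 or 2, got {self.hap1}/{self.hap2}")
        if self.start_bp <= 0:
            raise ValueError(f"start_bp must be positive, got {self.start_bp}")
        if self.start_bp >= self.end_bp:
            raise ValueError(
                f"start_bp must be < end_bp, got {self.start_bp} >= {self.end_bp}"
            )
        if not self.length_cm > 0:
            raise ValueError(f"length_cm must be positive, got {self.length_cm}")


@dataclass(frozen=True, slots=True)
class TargetLocus:
    """A target genomic interval (or point) on one chromosome, 1-based inclusive."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start_bp <= 0:
            raise ValueError(f"start_bp must be positive, got {self.start_bp}")
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"end_bp must be >= start_bp, got {self.end_bp} < {self.start_bp}"
            )

    @property
    def is_point(self) -> bool:
        return self.start_bp == self.end_bp


_LOCUS_RE = re.compile(r"^([^\s:]+):(\d+)(?:-(\d+))?$")


def parse_locus(spec: str) -> TargetLocus:
    """Parse ``chrom:start-end`` or ``chrom:pos`` into a :class:`TargetLocus`."""
    m = _LOCUS_RE.match(spec.strip())
    if m is None:
        raise ValueError(f"malformed locus spec {spec!r}; expected chrom:start-end or chrom:pos")
    chrom, start_s, end_s = m.groups()
    start = int(start_s)
    end = int(end_s) if end_s is not None else start
    try:
        return TargetLocus(chrom, start, end)
    except ValueError as exc:
        raise ValueError(f"invalid locus spec {spec!r}: {exc}") from exc


def _open_text(path: Path, mode: str):
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", newline="")
    return open(path, mode, newline="")


def _parse_int(value: str, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValueError(f"non-integer {what}: {value!r}") from None


def _parse_float(value: str, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"non-numeric {what}: {value!r}") from None


def read_ibd(
    path: str | Path,
    dialect: str = "hapibd",
    cm_col: int | None = None,
) -> list[IBDSegment]:
    """Read an IBD segment file into a list of validated :class:`IBDSegment`.

    Parameters
    ----------
    path
        TSV file, optionally gzipped (detected by the ``.gz`` suffix).
    dialect
        ``"hapibd"`` (8 columns, haplotype-level) or ``"generic-tsv"``
        (individual-level: sample1, sample2, chrom, start, end, ...).
    cm_col
        1-based index of the centimorgan column; required for
        ``generic-tsv`` and ignored for ``hapibd``.

    Row order is preserved.  Any malformed row raises :class:`IBDParseError`
    with its line number.
    """
    path = Path(path)
    if dialect not in ("hapibd", "generic-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "generic-tsv":
        if cm_col is None:
            raise ValueError("generic-tsv dialect requires cm_col (1-based cM column index)")
        if cm_col <= 5:
            raise ValueError(f"cm_col must point past the 5 fixed columns, got {cm_col}")
        logger.info(
            "reading individual-level generic-tsv input; haplotype indices set to 1"
        )

    segments: list[IBDSegment] = []
    with _open_text(path, "r") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            try:
                if dialect == "hapibd":
                    if len(row) < 8:
                        raise ValueError(f"expected 8 columns, found {len(row)}")
                    seg = IBDSegment(
                        sample1=row[0],
                        hap1=_parse_int(row[1], "haplotype index"),
                        sample2=row[2],
                        hap2=_parse_int(row[3], "haplotype index"),
                        chrom=row[4],
                        start_bp=_parse_int(row[5], "start coordinate"),
                        end_bp=_parse_int(row[6], "end coordinate"),
                        length_cm=_parse_float(row[7], "segment length"),
                    )
                else:
                    if len(row) < cm_col:  # type: ignore[operator]
                        raise ValueError(
                            f"expected at least {cm_col} columns, found {len(row)}"
                        )
                    seg = IBDSegment(
                        sample1=row[0],
                        hap1=1,
                        sample2=row[1],
                        hap2=1,
                        chrom=row[2],
                        start_bp=_parse_int(row[3], "start coordinate"),
                        end_bp=_parse_int(row[4], "end coordinate"),
                        length_cm=_parse_float(row[cm_col - 1], "segment length"),
                    )
            except ValueError as exc:
                raise IBDParseError(str(exc), line_number=lineno) from None
            segments.append(seg)
    return segments


def write_ibd(segments: Iterable[IBDSegment], path: str | Path) -> Path:
    """Write segments as a headerless hap-IBD style TSV (gzipped if ``.gz``).

    Centimorgan lengths are written with six decimals, so a write/read
    round trip reproduces integer fields exactly and ``length_cm`` to well
    within 0.01 cM.
    """
    path = Path(path)
    with _open_text(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.sample1}\t{seg.hap1}\t{seg.sample2}\t{seg.hap2}\t"
                f"{seg.chrom}\t{seg.start_bp}\t{seg.end_bp}\t{seg.length_cm:.6f}\n"
            )
    return path


def read_lengths(path: str | Path) -> list[float]:
    """Read a one-column file of centimorgan lengths (for the age clock CLI)."""
    path = Path(path)
    lengths: list[float] = []
    with _open_text(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            try:
                value = float(text.split()[0])
            except ValueError:
                raise IBDParseError(f"non-numeric length {text!r}", line_number=lineno) from None
            lengths.append(value)
    return lengths


def write_segments_sorted(segments: Sequence[IBDSegment], path: str | Path) -> Path:
    """Deterministically ordered variant of :func:`write_ibd` (sort by all fields)."""
    ordered = sorted(
        segments,
        key=lambda s: (s.chrom, s.start_bp, s.end_bp, s.sample1, s.hap1, s.sample2, s.hap2),
    )
    return write_ibd(ordered, path)
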