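"""Genomic region coordinates (1-based, inclusive)."""

from __future__ import annotations

from typing import NamedTuple


class Region(NamedTuple):
    """A 1-based, fully-closed genomic interval on one contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:  # pragma: no cover - NamedTuple has no init hook
        pass

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return start <= self.end and end >= self.start

    def validate(self) -> "Region":
        if self.start >= self.end:
            raise ValueError(f"region start must precede end, got {self}")
        if self.start < 1:
            raise ValueError("regions are 1-based; start must be >= 1")
        return self


#: The hemizygous target interval analysed by default: the ~3 Mb deletion
#: plus flanks on chromosome 22q11.2 (hg19 coordinates).
DEFAULT_REGION = Region("chr22", 18_400_394, 22_600_038)
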