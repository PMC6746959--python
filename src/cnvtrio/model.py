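"""Genomic-interval data types and the overlap algebra used by every pipeline stage.

Coordinates are 1-based and fully inclusive throughout the package, matching
the ``chrN:start-end`` convention in which CNV loci are reported.  BED-style
0-based half-open inputs are converted at the parser boundary
(:mod:`cnvtrio.io_formats`), never here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

#: Valid sample roles within a family.
ROLES = frozenset({"proband", "mother", "father", "sibling", "unrelated_control"})

#: The four study datasets: one discovery cohort and three replication cohorts.
COHORTS = ("discovery", "rep_wes", "rep_array", "rep_wgs")

#: Genotyping platform per cohort.
PLATFORMS = frozenset({"wes", "array", "wgs"})

CNV_TYPES = frozenset({"DEL", "DUP"})

_INTERVAL_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label to canonical ``chr``-prefixed form.

    Array and exome callers disagree on labels: ``2`` and ``chr2`` denote the
    same chromosome, and numeric sex-chromosome codes ``23``/``24`` mean
    X/Y.  All comparisons in the package are exact string comparisons after
    this normalization.
    """
    s = label.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s == "23":
        s = "X"
    elif s == "24":
        s = "Y"
    elif s.upper() in ("X", "Y", "MT", "M"):
        s = s.upper()
    if not s:
        raise ValueError(f"empty chromosome label: {label!r}")
    return "chr" + s


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key giving the natural chr1..chr22, chrX, chrY, chrM order."""
    body = chrom[3:] if chrom.startswith("chr") else chrom
    if body.isdigit():
        return (int(body), "")
    order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    return (order.get(body.upper(), 26), body)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully inclusive genomic span on a single chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start}) on {self.chrom}"
            )

    @classmethod
    def from_string(cls, s: str, normalize: bool = True) -> "GenomicInterval":
        """Parse a ``chr2:109363161-109371723``-style region string."""
        m = _INTERVAL_RE.match(s.strip())
        if m is None:
            raise ValueError(f"cannot parse interval string: {s!r}")
        chrom = normalize_chrom(m.group(1)) if normalize else m.group(1)
        return cls(chrom, int(m.group(2)), int(m.group(3)))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start + 1


def interval_length(iv: GenomicInterval) -> int:
    """Number of bases spanned: ``end - start + 1`` (always positive)."""
    return iv.end - iv.start + 1


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases shared by two intervals; 0 on different chromosomes or if disjoint."""
    if a.chrom != b.chrom:
        return 0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    return ov if ov > 0 else 0


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap fraction: min of the two one-way coverage fractions.

    The standard CNV-matching statistic — two calls "match" when each covers
    at least a fraction rho of the other.  Symmetric in its arguments and in
    [0, 1], with 1.0 only for identical intervals.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / interval_length(a), ov / interval_length(b))


def fraction_of_a_covered(a: GenomicInterval, b: GenomicInterval) -> float:
    """One-way coverage: fraction of ``a`` covered by ``b``. Not symmetric."""
    return overlap_bp(a, b) / interval_length(a)


def union_span(intervals: list[GenomicInterval]) -> GenomicInterval:
    """Smallest interval containing every input; all inputs must share a chromosome."""
    if not intervals:
        raise ValueError("union_span of empty list")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"union_span across chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


@dataclass(frozen=True)
class CnvCall:
    """One CNV call from one platform for one sample.

    ``support`` is free-form provenance, e.g. the read-support fraction
    reported by a WGS structural-variant caller.
    """

    call_id: str
    sample_id: str
    family_id: str
    role: str
    cohort: str
    platform: str
    interval: GenomicInterval
    cnv_type: str
    quality: Optional[float] = None
    support: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for call {self.call_id}")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r} for call {self.call_id}")
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"unknown platform {self.platform!r} for call {self.call_id}"
            )
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(
                f"cnv_type must be DEL or DUP, got {self.cnv_type!r} "
                f"for call {self.call_id}"
            )
        if self.quality is not None and self.quality < 0:
            raise ValueError(f"negative quality for call {self.call_id}")

    @property
    def is_case(self) -> bool:
        """Probands are cases; parents, siblings and unrelated samples are controls."""
        return self.role == "proband"


def check_unique_call_ids(calls: list[CnvCall]) -> None:
    """Raise if two calls in a loaded set share a call_id."""
    seen: set[str] = set()
    for c in calls:
        if c.call_id in seen:
            raise ValueError(f"duplicate call_id {c.call_id!r} in call set")
        seen.add(c.call_id)
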