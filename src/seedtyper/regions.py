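"""Genomic intervals, hotspot sets and section partitions.

All coordinates are 0-based half-open internally; conversion to and from
1-based VCF positions happens only at the file boundary (:mod:`seedtyper.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError


@dataclass(frozen=True)
class IntervalSpec:
    """A named genomic interval (0-based half-open)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError(
                f"interval {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    def contains(self, pos: float) -> bool:
        """Membership under the half-open convention: start <= pos < end."""
        return self.start <= pos < self.end


def _check_sorted_disjoint(regions: list[IntervalSpec], label: str) -> list[IntervalSpec]:
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise InputError(
                f"{label} {a.name!r} and {b.name!r} overlap ({a.start}-{a.end} vs {b.start}-{b.end})"
            )
    return ordered


@dataclass(frozen=True)
class RegionSet:
    """Named, non-overlapping sub-intervals of an analysis interval.

    Used both for hotspot sets (sparse: gaps allowed) and section partitions
    (dense: must tile the interval; see :meth:`require_tiling`).
    """

    regions: tuple[IntervalSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "regions", tuple(_check_sorted_disjoint(list(self.regions), "regions"))
        )

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def require_within(self, interval: IntervalSpec) -> None:
        for r in self.regions:
            if r.start < interval.start or r.end > interval.end:
                raise InputError(
                    f"region {r.name!r} ({r.start}-{r.end}) extends outside "
                    f"interval {interval.name!r} ({interval.start}-{interval.end})"
                )

    def require_tiling(self, interval: IntervalSpec) -> None:
        """Sections must cover the interval contiguously with no gaps."""
        self.require_within(interval)
        if not self.regions:
            raise InputError("empty section set")
        if self.regions[0].start != interval.start or self.regions[-1].end != interval.end:
            raise InputError(
                f"sections do not span interval {interval.name!r}: "
                f"cover {self.regions[0].start}-{self.regions[-1].end}, "
                f"need {interval.start}-{interval.end}"
            )
        for a, b in zip(self.regions, self.regions[1:]):
            if a.end != b.start:
                raise InputError(f"gap between sections {a.name!r} and {b.name!r} ({a.end} != {b.start})")
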