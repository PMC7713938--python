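"""Circular adjacency analysis: signed spacers at every feature boundary.

For consecutive features the signed spacer is
``downstream.start - upstream.end - 1`` on the circle: positive values are
intergenic gaps, negative values overlapping nucleotides, zero means the
features abut.  The wrap-around boundary (last feature back to the first)
is always included, so n features yield n boundary entries.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .genome import CircularGenome

__all__ = [
    "Boundary",
    "BoundaryReport",
    "SpacerSummary",
    "boundary_spacers",
    "summarize_spacers",
    "compare_spacer_column",
]


@dataclasses.dataclass
class Boundary:
    upstream: str
    downstream: str
    spacer: int


@dataclasses.dataclass
class SpacerSummary:
    n_gaps: int
    total_gap_nt: int
    gap_range: tuple[int, int] | None
    n_overlaps: int
    total_overlap_nt: int
    overlap_range: tuple[int, int] | None
    n_abutting: int


@dataclasses.dataclass
class BoundaryReport:
    entries: list[Boundary]

    @property
    def spacers(self) -> list[int]:
        return [b.spacer for b in self.entries]

    @property
    def summary(self) -> SpacerSummary:
        return summarize_spacers(self)

    @property
    def longest_gap(self) -> Boundary | None:
        gaps = [b for b in self.entries if b.spacer > 0]
        return max(gaps, key=lambda b: b.spacer) if gaps else None

    @property
    def largest_overlap(self) -> Boundary | None:
        ovl = [b for b in self.entries if b.spacer < 0]
        return min(ovl, key=lambda b: b.spacer) if ovl else None


def boundary_spacers(g: CircularGenome) -> BoundaryReport:
    """Signed spacer for every consecutive feature pair, including the
    wrap-around pair across the coordinate origin."""
    feats = g.features
    if len(feats) < 2:
        raise ValueError("need at least two features for boundary analysis")
    entries: list[Boundary] = []
    for up, down in zip(feats, feats[1:]):
        up_end = up.end + g.length if up.wraps_origin else up.end
        entries.append(Boundary(up.name, down.name, down.start - up_end - 1))
    last, first = feats[-1], feats[0]
    last_end = last.end + g.length if last.wraps_origin else last.end
    entries.append(Boundary(last.name, first.name,
                            first.start + g.length - last_end - 1))
    return BoundaryReport(entries=entries)


def summarize_spacers(r: "BoundaryReport | Sequence[int]") -> SpacerSummary:
    """Gap/overlap totals from a boundary report or a raw spacer vector.

    Accepting a plain integer vector ("column mode") lets a printed
    intergenic-nucleotide column be summarized directly, independently of
    coordinates.
    """
    spacers = r.spacers if isinstance(r, BoundaryReport) else list(r)
    gaps = [s for s in spacers if s > 0]
    overlaps = [-s for s in spacers if s < 0]
    return SpacerSummary(
        n_gaps=len(gaps),
        total_gap_nt=sum(gaps),
        gap_range=(min(gaps), max(gaps)) if gaps else None,
        n_overlaps=len(overlaps),
        total_overlap_nt=sum(overlaps),
        overlap_range=(min(overlaps), max(overlaps)) if overlaps else None,
        n_abutting=sum(1 for s in spacers if s == 0),
    )


def compare_spacer_column(r: BoundaryReport,
                          printed: Sequence[int]) -> list[dict]:
    """Flag boundaries where a printed intergenic column disagrees with the
    coordinate-derived spacers.

    ``printed[i]`` is read as the spacer between feature i and its successor
    (the last cell holds the wrap-around boundary).  Returns one record per
    disagreement; coordinate-derived values are authoritative.
    """
    if len(printed) != len(r.entries):
        raise ValueError(
            f"printed column has {len(printed)} cells for {len(r.entries)} boundaries")
    flags = []
    for b, p in zip(r.entries, printed):
        if p != b.spacer:
            flags.append({"upstream": b.upstream, "downstream": b.downstream,
                          "computed": b.spacer, "printed": p})
    return flags
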