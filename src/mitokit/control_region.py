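"""Control-region profiling: tandem-repeat arrays and conserved motifs.

The control region (D-loop) of vertebrate mitogenomes carries tandem-repeat
arrays and short conserved signals (TAS, OH, CSB-1/2/3).  The detector here
implements an exact tandem-repeat model: an array is a maximal stretch where
``seq[i] == seq[i - period]``, reported in the field's ``F x P+r`` notation
(F full copies of a P-mer unit plus an r-base partial copy), with copy
number span/period rounded to one decimal.  Motifs are found by sliding
Hamming-distance scan with a proportional mismatch budget.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

from .composition import round_half_away
from .genome import normalize_sequence

__all__ = [
    "RepeatArray",
    "MotifHit",
    "find_tandem_repeats",
    "format_array",
    "scan_motifs",
    "cr_feature_map",
]


@dataclasses.dataclass
class RepeatArray:
    """One tandem-repeat array (1-based inclusive coordinates).

    Invariant: ``end - start + 1 == full_copies * period + partial_len`` and
    ``unit`` equals the first ``period`` bases of the array (leftmost phase).
    """

    start: int
    end: int
    period: int
    unit: str
    full_copies: int
    partial_len: int
    copy_number: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class MotifHit:
    motif_name: str
    start: int
    end: int
    mismatches: int
    motif_source: str = ""
    is_best: bool = False


def find_tandem_repeats(seq: str, min_period: int = 5, max_period: int = 400,
                        min_total_copies: float = 1.8) -> list[RepeatArray]:
    """Find maximal exact tandem arrays with period in [min_period, max_period].

    For every candidate period p the scan extends runs where
    ``seq[i] == seq[i-p]``; a run starting at i spanning to j-1 yields an
    array over ``[i-p, j-1]``.  Arrays below ``min_total_copies``
    (span/period) are discarded.  When several periods explain the same
    span, the smallest is reported: an array contained in an equal-or-longer
    one whose period divides its own is pruned.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = normalize_sequence(seq)
    n = len(s)
    if not (1 <= min_period <= max_period):
        raise ValueError("need 1 <= min_period <= max_period")
    if min_total_copies < 1.0:
        raise ValueError("min_total_copies must be >= 1")
    candidates: list[RepeatArray] = []
    for p in range(min_period, min(max_period, n - 1) + 1):
        i = p
        while i < n:
            if s[i] == s[i - p]:
                j = i
                while j < n and s[j] == s[j - p]:
                    j += 1
                start = i - p
                span = j - start
                if span / p >= min_total_copies:
                    candidates.append(RepeatArray(
                        start=start + 1, end=j, period=p,
                        unit=s[start:start + p],
                        full_copies=span // p, partial_len=span % p,
                        copy_number=round_half_away(span / p, 1)))
                i = j + 1
            else:
                i += 1
    return _prune(candidates)


def _prune(arrays: list[RepeatArray]) -> list[RepeatArray]:
    kept: list[RepeatArray] = []
    for c in sorted(arrays, key=lambda a: (a.period, a.start)):
        redundant = any(
            a.start <= c.start and a.end >= c.end and a.span >= c.span
            and a.period < c.period and c.period % a.period == 0
            for a in kept)
        if not redundant:
            kept.append(c)
    kept.sort(key=lambda a: (a.start, a.period))
    return kept


def format_array(a: RepeatArray) -> str:
    """Render an array in the published ``F x P+r`` notation (r omitted if 0)."""
    base = f"{a.full_copies} × {a.period}"
    if a.partial_len:
        base += f"+{a.partial_len}"
    return base


def scan_motifs(seq: str, library: Iterable[Sequence[str]],
                max_mismatch_frac: float = 0.2) -> list[MotifHit]:
    """Hamming-distance sliding-window scan for a motif library on the H strand.

    ``library`` entries are ``(name, motif)`` or ``(name, motif, source)``.
    The mismatch budget per motif is ``floor(max_mismatch_frac * len)``.
    All hits within budget are returned with overlapping same-motif hits
    reduced to local minima; the best hit per motif is flagged.
    """
    if not (0.0 <= max_mismatch_frac <= 0.5):
        raise ValueError("max_mismatch_frac must lie in [0, 0.5]")
    s = normalize_sequence(seq)
    hits: list[MotifHit] = []
    for entry in library:
        name, motif = entry[0], normalize_sequence(entry[1])
        source = entry[2] if len(entry) > 2 else ""
        if not motif:
            raise ValueError(f"motif {name!r} is empty")
        m = len(motif)
        if m > len(s):
            warnings.warn(f"motif {name!r} longer than sequence; no hit possible")
            continue
        budget = int(max_mismatch_frac * m)
        raw = []
        for i in range(len(s) - m + 1):
            d = sum(1 for a, b in zip(s[i:i + m], motif) if a != b)
            if d <= budget:
                raw.append(MotifHit(name, i + 1, i + m, d, source))
        hits.extend(_local_minima(raw))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    # flag the best (fewest mismatches, leftmost) hit per motif name
    best: dict[str, MotifHit] = {}
    for h in hits:
        b = best.get(h.motif_name)
        if b is None or h.mismatches < b.mismatches:
            best[h.motif_name] = h
    for h in best.values():
        h.is_best = True
    return hits


def _local_minima(raw: list[MotifHit]) -> list[MotifHit]:
    """Drop a hit when an overlapping hit of the same motif is strictly
    better; equal-quality overlapping hits all survive, so a zero-mismatch
    budget degenerates to plain substring search."""
    kept = []
    for h in raw:
        dominated = any(
            o is not h and o.start <= h.end and h.start <= o.end
            and o.mismatches < h.mismatches
            for o in raw)
        if not dominated:
            kept.append(h)
    return kept


def cr_feature_map(seq: str, repeats: Sequence[RepeatArray],
                   hits: Sequence[MotifHit]) -> list[dict]:
    """Merge repeat arrays and motif hits into one 5'->3' annotation map.

    Overlapping elements are allowed and flagged (``overlaps_previous``).
    """
    elements: list[dict] = []
    for a in repeats:
        elements.append({"kind": "repeat", "name": format_array(a),
                         "start": a.start, "end": a.end,
                         "period": a.period, "copy_number": a.copy_number})
    for h in hits:
        elements.append({"kind": "motif", "name": h.motif_name,
                         "start": h.start, "end": h.end,
                         "mismatches": h.mismatches,
                         "source": h.motif_source})
    elements.sort(key=lambda e: (e["start"], e["end"]))
    prev_end = None
    for e in elements:
        e["overlaps_previous"] = prev_end is not None and e["start"] <= prev_end
        prev_end = max(prev_end, e["end"]) if prev_end is not None else e["end"]
    return elements
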