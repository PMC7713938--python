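"""Nucleotide composition and strand-asymmetry (skew) statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C) measure the
asymmetry between the two strands of the molecule; ambiguity codes are
excluded from all denominators.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

__all__ = [
    "CompositionSummary",
    "base_composition",
    "at_content_from_percentages",
    "codon_position_composition",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed mitogenome tables)."""
    q = 10 ** ndigits
    sign = -1.0 if x < 0 else 1.0
    return sign * (int(abs(x) * q + 0.5)) / q


@dataclasses.dataclass
class CompositionSummary:
    """Base counts, fractions, A+T content and the two skews for a sequence.

    ``at_skew_defined``/``gc_skew_defined`` are False when the corresponding
    denominator is zero; the skew is then reported as 0.0 rather than raising.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    at_content: float
    at_skew: float
    gc_skew: float
    at_skew_defined: bool = True
    gc_skew_defined: bool = True

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percent(self, base: str) -> float:
        return round_half_away(100.0 * self.fractions[base], 2)


def base_composition(seq: str) -> CompositionSummary:
    """Composition summary over the unambiguous bases of ``seq``."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    c = Counter(s)
    counts = {b: c.get(b, 0) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    fractions = {b: counts[b] / total for b in "ACGT"}
    a, t, g, cc = counts["A"], counts["T"], counts["G"], counts["C"]
    at_def = (a + t) > 0
    gc_def = (g + cc) > 0
    return CompositionSummary(
        counts=counts,
        fractions=fractions,
        at_content=fractions["A"] + fractions["T"],
        at_skew=(a - t) / (a + t) if at_def else 0.0,
        gc_skew=(g - cc) / (g + cc) if gc_def else 0.0,
        at_skew_defined=at_def,
        gc_skew_defined=gc_def,
    )


def at_content_from_percentages(a_pct: float, t_pct: float) -> float:
    """A+T content assembled from printed per-base percentages (2 decimals)."""
    if not (0 <= a_pct <= 100 and 0 <= t_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    return round_half_away(a_pct + t_pct, 2)


def codon_position_composition(cds_set: Sequence[str]) -> tuple[
        CompositionSummary, CompositionSummary, CompositionSummary]:
    """Pooled composition at codon positions 1, 2, 3 across all complete codons.

    Trailing incomplete codons (CDS length not a multiple of 3) have their
    1-2 leftover bases excluded.
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    pools = ["", "", ""]
    for cds in cds_set:
        s = cds.upper().replace("U", "T")
        n = len(s) - len(s) % 3
        for pos in range(3):
            pools[pos] += s[pos:n:3]
    return tuple(base_composition(p) for p in pools)  # type: ignore[return-value]
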