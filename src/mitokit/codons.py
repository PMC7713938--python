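"""Codon counting, relative synonymous codon usage (RSCU), and start/stop
codon classification under the vertebrate mitochondrial genetic code.

RSCU(c) = observed count of codon c divided by the count expected if all
codons in its synonymous family were used equally, i.e.
``count(c) * family_size / family_total``.  Stop codons form their own
4-codon family (UAA/UAG/AGA/AGG); complete terminal stop codons are counted,
incomplete ones (CDS ending in T or TA, completed by polyadenylation) are
excluded and flagged.
"""

from __future__ import annotations

import dataclasses
import warnings

from Bio.Data import CodonTable

from .composition import round_half_away

__all__ = [
    "CodonUsageTable",
    "VERTEBRATE_MITO",
    "genetic_code_families",
    "count_codons",
    "rscu",
    "codon_frequency_ranking",
    "codon_share",
    "classify_start_stop",
]

VERTEBRATE_MITO = "vertebrate_mitochondrial"
_CODE_IDS = {VERTEBRATE_MITO: 2, "standard": 1}

_BASES = "UCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


def _to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def _to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def genetic_code_families(code: str = VERTEBRATE_MITO) -> dict[str, tuple[str, ...]]:
    """Synonymous families (amino acid -> RNA codons; '*' = stop) for a code."""
    table = CodonTable.unambiguous_dna_by_id[_CODE_IDS[code]]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(_to_rna(codon))
    fams["*"] = [_to_rna(c) for c in table.stop_codons]
    return {aa: tuple(sorted(cods)) for aa, cods in sorted(fams.items())}


@dataclasses.dataclass
class CodonUsageTable:
    """Codon counts with family structure; ``rscu`` is filled by :func:`rscu`.

    Codons are keyed in the RNA alphabet.  ``incomplete_stops`` counts CDS
    whose trailing 1-2 bases were excluded as an incomplete terminal codon;
    ``zero_families`` lists amino acids whose family had zero total count
    (their members get RSCU 0 by convention).
    """

    genetic_code: str = VERTEBRATE_MITO
    counts: dict[str, int] = dataclasses.field(
        default_factory=lambda: {c: 0 for c in ALL_CODONS})
    rscu: dict[str, float] = dataclasses.field(default_factory=dict)
    incomplete_stops: int = 0
    zero_families: list[str] = dataclasses.field(default_factory=list)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        return genetic_code_families(self.genetic_code)

    @classmethod
    def from_counts(cls, counts: dict[str, int],
                    code: str = VERTEBRATE_MITO) -> "CodonUsageTable":
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            full[_to_rna(codon)] = int(n)
        return cls(genetic_code=code, counts=full)


def count_codons(cds_set, code: str = VERTEBRATE_MITO) -> CodonUsageTable:
    """Count every complete in-frame codon over a set of coding sequences.

    CDS are given 5'->3' on their coding strand (DNA or RNA alphabet).
    Complete terminal stop codons are included; a trailing incomplete codon
    is excluded and counted in ``incomplete_stops``.
    """
    table = CodonUsageTable(genetic_code=code)
    for i, cds in enumerate(cds_set):
        s = _to_rna(cds)
        if not s:
            warnings.warn(f"CDS #{i} is empty; skipped")
            continue
        n = len(s) - len(s) % 3
        for j in range(0, n, 3):
            codon = s[j:j + 3]
            if codon not in table.counts:
                raise ValueError(f"CDS #{i}: non-nucleotide codon {codon!r}")
            table.counts[codon] += 1
        if len(s) % 3:
            table.incomplete_stops += 1
    return table


def rscu(t: CodonUsageTable) -> CodonUsageTable:
    """Return a copy of ``t`` with the RSCU column filled.

    Within each synonymous family with nonzero total, RSCU values sum to the
    family size (mean 1); zero-total families get RSCU 0 for every member
    and are recorded in ``zero_families``.
    """
    out = dataclasses.replace(t, counts=dict(t.counts), rscu={},
                              zero_families=[])
    for aa, fam in out.families.items():
        fam_total = sum(out.counts[c] for c in fam)
        if fam_total == 0:
            out.zero_families.append(aa)
            for c in fam:
                out.rscu[c] = 0.0
        else:
            for c in fam:
                out.rscu[c] = out.counts[c] * len(fam) / fam_total
    out.rscu = {c: out.rscu[c] for c in ALL_CODONS}
    return out


def codon_frequency_ranking(t: CodonUsageTable, k: int):
    """Top-k and bottom-k codons with percent of total (2 decimals).

    Ties are broken by codon lexicographic order.  Returns
    ``(top, bottom)`` where each entry is ``(codon, count, percent)``.
    """
    if t.total_codons == 0:
        raise ValueError("empty codon table")
    total = t.total_codons
    items = sorted(t.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    def fmt(sub):
        return [(c, n, round_half_away(100.0 * n / total, 2)) for c, n in sub]
    top = fmt(items[:k])
    bottom = fmt(sorted(t.counts.items(), key=lambda kv: (kv[1], kv[0]))[:k])
    return top, bottom


def codon_share(t: CodonUsageTable, codons) -> float:
    """Combined percent of total for a set of codons (2 decimals)."""
    if t.total_codons == 0:
        raise ValueError("empty codon table")
    n = sum(t.counts[_to_rna(c)] for c in codons)
    return round_half_away(100.0 * n / t.total_codons, 2)


def classify_start_stop(cds: str, code: str = VERTEBRATE_MITO) -> tuple[str, str]:
    """Start codon and stop status of a coding sequence.

    Returns ``(start, stop)`` in the DNA alphabet.  ``stop`` is the complete
    terminal stop codon when the CDS length is a multiple of 3 and its last
    codon is a stop under the code; ``"T--"``/``"TA-"`` when the trailing
    1-2 bases are T/TA (a stop completed by polyadenylation); else
    ``"none"``.
    """
    s = _to_dna(cds)
    if len(s) < 3:
        raise ValueError("CDS shorter than one codon")
    start = s[:3]
    stops = {_to_dna(c) for c in genetic_code_families(code)["*"]}
    rem = len(s) % 3
    if rem == 0:
        last = s[-3:]
        return start, (last if last in stops else "none")
    if rem == 1 and s[-1] == "T":
        return start, "T--"
    if rem == 2 and s[-2:] == "TA":
        return start, "TA-"
    return start, "none"
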