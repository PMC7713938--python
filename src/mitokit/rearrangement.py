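"""Circular mitochondrial gene-order comparison and TDRL scenario search.

Gene orders are circular sequences of signed tokens (strand +/- for the H
and L strand); rotation-equivalent orders compare equal, reflections do not
(the two strands are biologically distinct).  Rearranged orders are compared
against the neobatrachian-type reference by breakpoint distance (adjacencies
present in one circle but not the other), diffed into
lost/duplicated/pseudogenized/translocated gene sets, classified into the
ten ranid arrangement types, and explained where possible by tandem
duplication-random loss (TDRL): a contiguous block is duplicated in tandem
and one copy of each redundant gene is subsequently deleted (both copies
may persist only for control-region class tokens).
"""

from __future__ import annotations

import dataclasses
import re
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .genome import CircularGenome, ParseError, canonical_name

__all__ = [
    "Token",
    "GeneOrder",
    "TdrlEvent",
    "RearrangementReport",
    "CANONICAL_TOKENS",
    "parse_gene_order",
    "order_from_genome",
    "reference_order",
    "breakpoint_distance",
    "diff_orders",
    "classify_type",
    "apply_tdrl",
    "tdrl_search",
    "TYPE_LIBRARY",
]

_PCGS = ("ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
         "COI", "COII", "COIII", "ATP6", "ATP8", "Cytb")
_TRNAS = tuple("trn" + x for x in
               ("A", "C", "D", "E", "F", "G", "H", "I", "K", "M", "N", "P",
                "Q", "R", "T", "V", "W", "Y", "L1", "L2", "S1", "S2"))
CANONICAL_TOKENS = frozenset(_PCGS + _TRNAS + ("12S", "16S", "CR", "OL", "NCR"))

# Duplicate copies are allowed for any token (distinguished by dup_index);
# "both copies kept" after a TDRL is allowed only for these classes.
_BOTH_OK = ("CR", "NCR")


@dataclasses.dataclass(frozen=True)
class Token:
    name: str
    strand: str = "+"          # '+' = H strand, '-' = L strand
    pseudo: bool = False
    dup_index: int = 0

    @property
    def key(self) -> tuple:
        """Identity used in adjacency comparisons (copies indistinct)."""
        return (self.name, self.strand, self.pseudo)

    def __str__(self) -> str:
        return ("-" if self.strand == "-" else "") + \
            ("ps" if self.pseudo else "") + self.name


def _reindex(tokens: Iterable[Token]) -> tuple[Token, ...]:
    seen: Counter = Counter()
    out = []
    for t in tokens:
        out.append(dataclasses.replace(t, dup_index=seen[t.name]))
        seen[t.name] += 1
    return tuple(out)


@dataclasses.dataclass
class GeneOrder:
    """A circular signed gene order; rotations of the same circle are equal."""

    tokens: tuple[Token, ...]
    name: str = ""

    def __post_init__(self) -> None:
        self.tokens = _reindex(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def keys(self, drop_ncr: bool = False) -> tuple[tuple, ...]:
        return tuple(t.key for t in self.tokens
                     if not (drop_ncr and t.name == "NCR"))

    def names(self, drop_ncr: bool = True) -> tuple[str, ...]:
        return tuple(t.name for t in self.tokens
                     if not (drop_ncr and t.name == "NCR"))

    def rotated(self, i: int) -> "GeneOrder":
        n = len(self.tokens)
        i %= n
        return GeneOrder(self.tokens[i:] + self.tokens[:i], name=self.name)

    def anchored(self) -> "GeneOrder":
        """Rotate to start at trnF when present, else 12S, else the
        lexicographically minimal rotation (stable display convention)."""
        for anchor in ("trnF", "12S"):
            for i, t in enumerate(self.tokens):
                if t.name == anchor and not t.pseudo:
                    return self.rotated(i)
        return self.rotated(_min_rotation(self.keys()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return circular_equal(self.keys(), other.keys())

    def __str__(self) -> str:
        return "-".join(str(t) for t in self.tokens)


def _min_rotation(seq: Sequence) -> int:
    return min(range(len(seq)), key=lambda i: tuple(seq[i:]) + tuple(seq[:i]))


def circular_equal(a: Sequence, b: Sequence) -> bool:
    if len(a) != len(b):
        return False
    if len(a) == 0:
        return True
    ia, ib = _min_rotation(a), _min_rotation(b)
    ra = tuple(a[ia:]) + tuple(a[:ia])
    rb = tuple(b[ib:]) + tuple(b[:ib])
    if ra == rb:
        return True
    # minimal rotation may be ambiguous under repeated keys; fall back to scan
    return any(tuple(b[i:]) + tuple(b[:i]) == tuple(a) for i in range(len(b)))


# ---------------------------------------------------------------------------
# Parsing

def _canon_token(raw: str) -> Token:
    tok = raw.strip()
    if not tok:
        raise ParseError("empty token")
    strand = "+"
    if tok[0] in "-−":
        strand = "-"
        tok = tok[1:]
    elif tok[:2] in ("L:", "l:"):
        strand = "-"
        tok = tok[2:]
    pseudo = False
    if tok.lower().startswith("ps"):
        pseudo = True
        tok = tok[2:]
    name = tok if tok in CANONICAL_TOKENS else canonical_name(tok)
    if name not in CANONICAL_TOKENS:
        # bare one/two-letter tRNA shorthand (W, A, L1, S2, ...)
        cand = canonical_name("trn" + tok)
        if cand in CANONICAL_TOKENS:
            name = cand
        else:
            raise ParseError(f"unknown gene-order token {raw!r}")
    return Token(name=name, strand=strand, pseudo=pseudo)


def parse_gene_order(text: str, name: str = "") -> GeneOrder:
    """Parse a dash- or whitespace-separated gene-order string.

    ``ps`` prefixes mark pseudogenes; a leading ``-`` (whitespace dialect),
    unicode minus, or ``L:`` marks an L-strand token.  Multi-part synonyms
    (``D-loop``, ``rep-origin``, ``tRNA-Xxx``) are normalized before the
    dash split so they survive the dash dialect.
    """
    s = text.strip()
    if not s:
        raise ParseError("empty gene-order string")
    s = re.sub(r"(?i)d[-_ ]?loop", "CR", s)
    s = re.sub(r"(?i)rep[-_ ]?origin", "OL", s)
    s = re.sub(r"(?i)trna[-_]", "trn", s)

    def _anticodon(m):
        prefix = m.group(1)
        if prefix and prefix[-1].isdigit():   # already qualified (trnL2 (CUN))
            return prefix
        return prefix + {"UUR": "1", "CUN": "2",
                         "AGY": "1", "UCN": "2"}[m.group(2)]

    s = re.sub(r"(\w*)\s*\(\s*(UUR|CUN|AGY|UCN)\s*\)", _anticodon, s)
    chunks = s.split()
    if len(chunks) == 1 and "-" in chunks[0]:
        chunks = [c for c in chunks[0].split("-") if c]
    return GeneOrder(tuple(_canon_token(c) for c in chunks), name=name)


_CLASS_STRAND = {"H": "+", "L": "-"}


def order_from_genome(g: CircularGenome) -> GeneOrder:
    """Gene order of an annotated genome, in circular coordinate order."""
    toks = [Token(name=f.name, strand=_CLASS_STRAND[f.strand],
                  pseudo=f.feature_class == "pseudogene")
            for f in g.features]
    return GeneOrder(tuple(toks), name=g.name)


def reference_order() -> GeneOrder:
    """The neobatrachian-type reference order (shipped as package data)."""
    text = resources.files("mitokit.data").joinpath(
        "neobatrachian.order").read_text()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    return parse_gene_order(" ".join(lines), name="neobatrachian")


def load_gene_order(path: str | Path, name: str = "") -> GeneOrder:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    return parse_gene_order(" ".join(lines), name=name or Path(path).stem)


# ---------------------------------------------------------------------------
# Distances and diffs

def _adjacencies(keys: Sequence[tuple]) -> Counter:
    n = len(keys)
    return Counter((keys[i], keys[(i + 1) % n]) for i in range(n))


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of circular adjacencies of ``a`` absent from ``b``.

    Tokens private to one order (by identity key, NCR excluded throughout)
    are dropped before comparison, so the distance is a pseudometric on the
    shared gene content; it is symmetric on equal multisets.
    """
    ka, kb = list(a.keys(drop_ncr=True)), list(b.keys(drop_ncr=True))
    common = Counter(ka) & Counter(kb)
    fa = _restrict(ka, common)
    fb = _restrict(kb, common)
    if not fa:
        return 0
    return sum((_adjacencies(fa) - _adjacencies(fb)).values())


def _restrict(keys: list, allowed: Counter) -> list:
    budget = Counter(allowed)
    out = []
    for k in keys:
        if budget[k] > 0:
            out.append(k)
            budget[k] -= 1
    return out


@dataclasses.dataclass
class RearrangementReport:
    breakpoint_distance: int
    translocated: list[str]
    lost: list[str]
    duplicated: list[str]
    pseudogenized: list[str]
    type_label: str


def diff_orders(ref: GeneOrder, obs: GeneOrder) -> RearrangementReport:
    """Describe ``obs`` relative to ``ref`` in event vocabulary.

    ``lost`` are gene names present in ``ref`` with no functional copy in
    ``obs``; ``duplicated`` have two or more functional copies;
    ``pseudogenized`` are flagged ``ps`` in ``obs``; ``translocated`` is the
    greedy minimal set of shared genes whose removal reconciles the two
    adjacency multisets (documented heuristic).  NCR tokens are ignored.
    """
    ref_names = Counter(t.name for t in ref.tokens
                        if not t.pseudo and t.name != "NCR")
    obs_names = Counter(t.name for t in obs.tokens
                        if not t.pseudo and t.name != "NCR")
    lost = sorted(n for n in ref_names if obs_names[n] == 0)
    duplicated = sorted(n for n, c in obs_names.items()
                        if c >= 2 and n not in _BOTH_OK) + \
        sorted(n for n, c in obs_names.items() if c >= 2 and n in _BOTH_OK)
    pseudogenized = sorted({t.name for t in obs.tokens if t.pseudo})
    translocated = _greedy_translocated(ref, obs)
    return RearrangementReport(
        breakpoint_distance=breakpoint_distance(ref, obs),
        translocated=translocated,
        lost=lost,
        duplicated=sorted(set(duplicated)),
        pseudogenized=pseudogenized,
        type_label=classify_type(obs),
    )


def _greedy_translocated(ref: GeneOrder, obs: GeneOrder) -> list[str]:
    ka = list(ref.keys(drop_ncr=True))
    kb = list(obs.keys(drop_ncr=True))
    common = Counter(ka) & Counter(kb)
    fa, fb = _restrict(ka, common), _restrict(kb, common)
    removed: list[str] = []
    while fa and _adjacencies(fa) != _adjacencies(fb):
        names = sorted({k[0] for k in fa})
        def broken(name: str) -> int:
            ra = [k for k in fa if k[0] != name]
            rb = [k for k in fb if k[0] != name]
            before = sum((_adjacencies(fa) - _adjacencies(fb)).values())
            after = sum((_adjacencies(ra) - _adjacencies(rb)).values()) if ra else 0
            return before - after
        # ties (e.g. an adjacent exchange, explainable by either partner)
        # prefer the mobile non-gene elements, which translocate most often
        best = max(names, key=lambda n: (broken(n), n in _BOTH_OK or n == "OL"))
        if broken(best) <= 0:
            break
        removed.append(best)
        fa = [k for k in fa if k[0] != best]
        fb = [k for k in fb if k[0] != best]
    return sorted(removed)


# ---------------------------------------------------------------------------
# Arrangement-type classification

def _contains_segment(names: Sequence[str], segment: Sequence[str]) -> bool:
    n = len(names)
    m = len(segment)
    if m > n:
        return False
    ext = list(names) + list(names[:m - 1])
    return any(ext[i:i + m] == list(segment) for i in range(n))


def _seq(o: GeneOrder, drop_ncr: bool = True) -> list[str]:
    """Circular name sequence with pseudogenes tagged 'ps<name>'."""
    return [("ps" + t.name if t.pseudo else t.name) for t in o.tokens
            if not (drop_ncr and t.name == "NCR")]


def _is_reference(o: GeneOrder) -> bool:
    ref = reference_order()
    return circular_equal(o.keys(drop_ncr=True), ref.keys(drop_ncr=True))


TYPE_LIBRARY: list[tuple[str, Callable[[GeneOrder], bool]]] = [
    # I: trnA exchanged past the trnN-OL-trnC block, with an inserted NCR.
    ("I", lambda o: _contains_segment(
        _seq(o), ["trnW", "trnN", "OL", "trnC", "trnA", "trnY"])
        and any(t.name == "NCR" for t in o.tokens)),
    # II: pseudogenized trnS2 at its original locus.
    ("II", lambda o: any(t.name == "trnS2" and t.pseudo for t in o.tokens)),
    # III: OL translocated between trnW and trnA.
    ("III", lambda o: _contains_segment(_seq(o), ["trnW", "OL", "trnA"])),
    # IV: trnH/trnS1/ND5 moved behind the CR (old trnH a pseudogene), trnE
    # moved before the LTPF cluster.
    ("IV", lambda o: _contains_segment(_seq(o), ["CR", "pstrnH", "trnS1", "ND5"])
        and _contains_segment(_seq(o), ["trnE", "trnL2"])),
    # V: trnH pseudogene between CR and trnL2.
    ("V", lambda o: _contains_segment(_seq(o), ["CR", "pstrnH", "trnL2"])),
    # VI: trnN/OL exchange with triplicated OL; trnH between CR and LTPF.
    ("VI", lambda o: sum(t.name == "OL" for t in o.tokens) == 3
        and _contains_segment(_seq(o), ["CR", "trnH", "trnL2"])),
    # VII: trnH translocated immediately before the LTPF cluster.
    ("VII", lambda o: _contains_segment(_seq(o), ["trnH", "trnL2", "trnT"])),
    # VIII: trnN/OL exchange and loss of trnH.
    ("VIII", lambda o: _contains_segment(_seq(o), ["trnA", "OL", "trnN"])
        and all(t.name != "trnH" for t in o.tokens)),
    # IX: loss of trnP and trnF (the LTPF cluster truncated to trnL2-trnT).
    ("IX", lambda o: all(t.name not in ("trnP", "trnF") for t in o.tokens)
        and _contains_segment(_seq(o), ["trnL2", "trnT"])),
    # X: duplicated CR flanking a translocated ND5 behind trnL2.
    ("X", lambda o: _contains_segment(_seq(o), ["CR", "trnL2", "ND5", "CR"])),
]


def classify_type(obs: GeneOrder,
                  type_library: Sequence[tuple[str, Callable]] | None = None
                  ) -> str:
    """Assign an arrangement-type label.

    Returns ``"neobatrachian"`` for the reference order, the first matching
    label from the library (fixed evaluation order I..X), else ``"unknown"``.
    """
    if _is_reference(obs):
        return "neobatrachian"
    for label, pred in (type_library or TYPE_LIBRARY):
        if pred(obs):
            return label
    return "unknown"


# ---------------------------------------------------------------------------
# TDRL model

@dataclasses.dataclass(frozen=True)
class TdrlEvent:
    """One tandem duplication-random loss event.

    ``block_start``/``block_length`` index a contiguous token interval of the
    source circle; ``kept`` records, per block position, which duplicated
    copy survives (``first``/``second``; ``both`` only for CR/NCR tokens).
    """

    block_start: int
    block_length: int
    kept: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.kept) != self.block_length:
            raise ValueError("kept assignment must cover the whole block")
        if any(k not in ("first", "second", "both") for k in self.kept):
            raise ValueError("kept entries must be first/second/both")


def apply_tdrl(o: GeneOrder, e: TdrlEvent) -> GeneOrder:
    """Duplicate the event block in tandem and delete the non-surviving copies."""
    n = len(o.tokens)
    if not (1 <= e.block_length <= n):
        raise ValueError("block length outside the circle")
    rot = o.tokens[e.block_start % n:] + o.tokens[:e.block_start % n]
    block, rest = rot[:e.block_length], rot[e.block_length:]
    for tok, k in zip(block, e.kept):
        if k == "both" and tok.name not in _BOTH_OK:
            raise ValueError(
                f"'both' copies kept is only allowed for CR/NCR, not {tok.name}")
    survivors = [t for t, k in zip(block, e.kept) if k in ("first", "both")]
    survivors += [t for t, k in zip(block, e.kept) if k in ("second", "both")]
    return GeneOrder(tuple(survivors) + rest, name=o.name)


def tdrl_search(source: GeneOrder, target: GeneOrder,
                max_events: int = 1) -> list[list[TdrlEvent]]:
    """Exhaustive search for TDRL scenarios turning ``source`` into ``target``.

    Considers every contiguous block (all start/length pairs on the circle)
    and, per block, every kept-assignment consistent with the target found
    by aligning the target against the duplicated block string.  Scenarios
    are returned sorted by total block length (shortest first); the empty
    list means no scenario within ``max_events`` exists.  ``source ==
    target`` yields the single empty scenario.
    """
    if max_events > 2:
        raise ValueError("search supports at most 2 events")
    extra = Counter(t.name for t in target.tokens) - \
        Counter(t.name for t in source.tokens)
    if any(name not in _BOTH_OK for name in extra):
        return []
    if Counter(t.name for t in source.tokens) - \
            Counter(t.name for t in target.tokens):
        return []  # genes lost outright are outside the duplication model
    if source == target:
        return [[]]
    scenarios = [[e] for e in _single_events(source, target)]
    if not scenarios and max_events >= 2:
        seen = set()
        for e1 in _all_events(source):
            mid = apply_tdrl(source, e1)
            key = tuple(mid.anchored().keys())
            if key in seen:
                continue
            seen.add(key)
            for e2 in _single_events(mid, target):
                scenarios.append([e1, e2])
    scenarios.sort(key=lambda sc: (sum(e.block_length for e in sc), len(sc)))
    return scenarios


def _single_events(source: GeneOrder, target: GeneOrder) -> list[TdrlEvent]:
    n = len(source.tokens)
    tkeys = [t.key for t in target.tokens]
    m = len(tkeys)
    found: dict[tuple, TdrlEvent] = {}
    for start in range(n):
        rot = source.tokens[start:] + source.tokens[:start]
        for length in range(1, n + 1):
            block, rest = rot[:length], rot[length:]
            seg_len = m - len(rest)
            if seg_len < length:
                continue
            rest_keys = [t.key for t in rest]
            for r in range(m):
                trot = tkeys[r:] + tkeys[:r]
                if trot[seg_len:] != rest_keys:
                    continue
                for kept in _alignments(block, trot[:seg_len]):
                    e = TdrlEvent(block_start=start, block_length=length,
                                  kept=kept)
                    sig = (tuple(t.key for t in block), kept,
                           tuple(rest_keys))
                    if sig not in found:
                        cand = apply_tdrl(source, e)
                        if cand == target:
                            found[sig] = e
    return sorted(found.values(),
                  key=lambda e: (e.block_length, e.block_start))


def _alignments(block: Sequence[Token], seg: Sequence[tuple]
                ) -> list[tuple[str, ...]]:
    """All embeddings of the target segment into the duplicated block.

    The duplicated string is ``block + block``; the segment must map onto it
    as an increasing subsequence using each non-CR block position exactly
    once (CR/NCR positions once or twice)."""
    l = len(block)
    dup = [t.key for t in block] + [t.key for t in block]
    results: list[tuple[str, ...]] = []

    def backtrack(si: int, di: int, used: list[int]) -> None:
        remaining = len(seg) - si
        if remaining > len(dup) - di:
            return
        if si == len(seg):
            kept = []
            for k in range(l):
                u = used[k] + used[k + l] * 2   # 1=first, 2=second, 3=both
                if u == 0:
                    return
                if u == 3 and block[k].name not in _BOTH_OK:
                    return
                kept.append({1: "first", 2: "second", 3: "both"}[u])
            results.append(tuple(kept))
            return
        for d in range(di, len(dup)):
            if dup[d] == seg[si]:
                used[d] = 1
                backtrack(si + 1, d + 1, used)
                used[d] = 0

    backtrack(0, 0, [0] * (2 * l))
    return list(dict.fromkeys(results))


def _all_events(o: GeneOrder) -> list[TdrlEvent]:
    """Every valid TDRL event on ``o`` (used for 2-event composition).

    Exponential in block length; intended for short orders."""
    n = len(o.tokens)
    events = []
    for start in range(n):
        rot = o.tokens[start:] + o.tokens[:start]
        for length in range(1, n + 1):
            block = rot[:length]
            choices = [("first", "second", "both")
                       if t.name in _BOTH_OK else ("first", "second")
                       for t in block]
            stack: list[tuple[str, ...]] = [()]
            for opts in choices:
                stack = [k + (opt,) for k in stack for opt in opts]
            for kept in stack:
                events.append(TdrlEvent(start, length, kept))
    return events
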