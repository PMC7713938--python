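"""Data model and I/O for circular mitochondrial genomes.

Coordinates throughout are 1-based, fully closed intervals on the H strand,
as in published mitogenome annotation tables.  The genome is a circle; a
feature that spans the coordinate origin carries an explicit ``wraps_origin``
flag (its ``end`` is then numerically smaller than its ``start``).
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Feature",
    "CircularGenome",
    "ParseError",
    "ValidationError",
    "FEATURE_CLASSES",
    "canonical_name",
    "read_feature_table",
    "write_feature_table",
    "read_fasta",
    "write_report",
    "feature_length",
    "extract_sequence",
]


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class ValidationError(ValueError):
    """An input violated a structural invariant (coordinates, strand, ...)."""


FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "CR", "OL", "NCR", "pseudogene")

_IUPAC = set("ACGTRYSWKMBDHVN")

# Amino-acid one/three letter codes used to canonicalize tRNA gene names.
_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "lys": "K", "met": "M",
    "phe": "F", "pro": "P", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# Direct synonyms for non-tRNA tokens (lower-cased, punctuation stripped).
_SYNONYMS = {
    "dloop": "CR", "d loop": "CR", "controlregion": "CR", "cr": "CR",
    "reporigin": "OL", "replicationorigin": "OL", "ol": "OL",
    "lstrandorigin": "OL", "originoflightstrandreplication": "OL",
    "ncr": "NCR", "noncodingregion": "NCR",
    "miscfeaturenoncodingregion": "NCR", "nc": "NCR",
    "12sribosomalrna": "12S", "12srrna": "12S", "rrns": "12S", "srrna": "12S",
    "12s": "12S",
    "16sribosomalrna": "16S", "16srrna": "16S", "rrnl": "16S", "lrrna": "16S",
    "16s": "16S",
    "co1": "COI", "cox1": "COI", "coi": "COI",
    "co2": "COII", "cox2": "COII", "coii": "COII",
    "co3": "COIII", "cox3": "COIII", "coiii": "COIII",
    "cob": "Cytb", "cytb": "Cytb",
    "atpase6": "ATP6", "atp6": "ATP6", "atpase8": "ATP8", "atp8": "ATP8",
    "nad1": "ND1", "nad2": "ND2", "nad3": "ND3", "nad4": "ND4",
    "nad4l": "ND4L", "nad5": "ND5", "nad6": "ND6",
    "nd1": "ND1", "nd2": "ND2", "nd3": "ND3", "nd4": "ND4", "nd4l": "ND4L",
    "nd5": "ND5", "nd6": "ND6",
}

# Ambiguous duplicated-tRNA labels.  In ranid annotation tables the
# unnumbered Leu/Ser gene is the "1" copy: Leu(UUR) between 16S and ND1,
# Ser(AGY) before ND5; the "2" copies are Leu(CUN) in the LTPF cluster and
# Ser(UCN) after COI.  Anticodon-qualified labels map both conventions.
_TRNA_SPECIAL = {
    "leu": "trnL1", "leu1": "trnL1", "leu2": "trnL2",
    "leuuur": "trnL1", "leucun": "trnL2",
    "ser": "trnS1", "ser1": "trnS1", "ser2": "trnS2",
    "seragy": "trnS1", "serucn": "trnS2",
    "l": "trnL1", "l1": "trnL1", "l2": "trnL2",
    "s": "trnS1", "s1": "trnS1", "s2": "trnS2",
}


def canonical_name(name: str) -> str:
    """Map a gene/region label to its canonical token.

    Handles the common synonym families (``D-loop`` -> ``CR``,
    ``rep-origin`` -> ``OL``, ``tRNA-Leu (CUN)`` -> ``trnL2``,
    ``12S ribosomal RNA`` -> ``12S`` ...).  Unknown labels are returned
    unchanged so that bespoke annotations survive a round trip.
    """
    raw = name.strip()
    key = re.sub(r"[\s_\-()/.]+", "", raw).lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    m = re.match(r"^(?:trn[a\-]?|trna)(.+)$", key)
    if m:
        rest = m.group(1)
        if rest in _TRNA_SPECIAL:
            return _TRNA_SPECIAL[rest]
        for aa3, aa1 in _AA3_TO_1.items():
            if rest == aa3 or (rest.startswith(aa3) and rest[len(aa3):].isdigit()):
                return "trn" + aa1 + rest[len(aa3):]
        if len(rest) == 1 and rest.upper() in _AA3_TO_1.values():
            return "trn" + rest.upper()
        if len(rest) == 2 and rest[0].upper() in "LS" and rest[1] in "12":
            return "trn" + rest.upper()
    return raw


@dataclasses.dataclass
class Feature:
    """One annotated gene or region on the circle.

    ``start``/``end`` are 1-based inclusive H-strand coordinates; ``strand``
    is ``"H"`` or ``"L"``.  ``stop_codon`` may be an incomplete token
    (``"T--"`` or ``"TA-"``) for reading frames completed by polyadenylation.
    """

    name: str
    feature_class: str
    start: int
    end: int
    strand: str
    start_codon: str | None = None
    stop_codon: str | None = None
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValidationError(
                f"feature {self.name!r}: strand must be 'H' or 'L', got {self.strand!r}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"feature {self.name!r}: unknown feature class {self.feature_class!r}"
            )
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"feature {self.name!r}: coordinates are 1-based")
        if self.end < self.start and not self.wraps_origin:
            raise ValidationError(
                f"feature {self.name!r}: end {self.end} < start {self.start} "
                "without wraps_origin"
            )

    def length(self, genome_length: int) -> int:
        return feature_length(self, genome_length)


def feature_length(f: Feature, genome_length: int) -> int:
    """Nucleotide span of a feature on a circle of ``genome_length``."""
    if f.wraps_origin:
        return genome_length - f.start + 1 + f.end
    return f.end - f.start + 1


@dataclasses.dataclass
class CircularGenome:
    """A circular genome: length, optional H-strand sequence, ordered features."""

    name: str
    length: int
    sequence: str | None = None
    features: list[Feature] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError("genome length must be positive")
        if self.sequence is not None:
            self.sequence = normalize_sequence(self.sequence)
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise ValidationError(
                    f"feature {f.name!r} ({f.start}..{f.end}) exceeds genome "
                    f"length {self.length}"
                )
        # Sort by start; identical starts put the longer feature first.
        self.features.sort(key=lambda f: (f.start, -feature_length(f, self.length)))

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def extract(self, f: Feature) -> str:
        return extract_sequence(self, f)


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T, and reject non-IUPAC characters."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _IUPAC
    if bad:
        raise ValidationError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


def extract_sequence(g: CircularGenome, f: Feature) -> str:
    """Feature subsequence on its coding strand.

    H-strand features are returned verbatim, L-strand features
    reverse-complemented; wrapping features are concatenated across the
    origin before strand correction.
    """
    if g.sequence is None:
        raise ValueError("genome carries no sequence")
    if f.wraps_origin:
        s = g.sequence[f.start - 1:] + g.sequence[: f.end]
    else:
        s = g.sequence[f.start - 1: f.end]
    if f.strand == "L":
        s = str(Seq(s).reverse_complement())
    return s


# ---------------------------------------------------------------------------
# Feature-table I/O

_TSV_REQUIRED = ("name", "class", "start", "end", "strand")


def read_feature_table(path: str | Path, dialect: str = "tsv",
                       length: int | None = None,
                       sequence: str | None = None) -> CircularGenome:
    """Read an annotation table into a :class:`CircularGenome`.

    ``dialect`` is ``"tsv"`` (bespoke tab-separated table with header columns
    name, class, start, end, strand[, start_codon, stop_codon,
    wraps_origin]) or ``"genbank"`` (flat-file subset: LOCUS length plus
    CDS/tRNA/rRNA/D-loop/rep_origin features).  For TSV input the genome
    length is ``length`` if given, else a ``# length=N`` pragma, else the
    maximum end coordinate.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path, length=length, sequence=sequence)
    if dialect == "genbank":
        return _read_genbank(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path, length: int | None, sequence: str | None) -> CircularGenome:
    header: list[str] | None = None
    feats: list[Feature] = []
    declared = length
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            m = re.search(r"length\s*[=:]\s*(\d[\d,]*)", line)
            if m and declared is None:
                declared = int(m.group(1).replace(",", ""))
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip().lower() for c in cells]
            missing = [c for c in _TSV_REQUIRED if c not in header]
            if missing:
                raise ParseError(
                    f"{path}:{lineno}: header lacks required column(s) {missing}"
                )
            continue
        row = dict(zip(header, (c.strip() for c in cells)))
        try:
            feats.append(Feature(
                name=canonical_name(row["name"]),
                feature_class=row["class"],
                start=int(row["start"].replace(",", "")),
                end=int(row["end"].replace(",", "")),
                strand=row["strand"],
                start_codon=row.get("start_codon") or None,
                stop_codon=row.get("stop_codon") or None,
                wraps_origin=row.get("wraps_origin", "").lower()
                in ("1", "true", "yes"),
            ))
        except (KeyError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
    if header is None:
        raise ParseError(f"{path}: no header line found")
    if declared is None:
        if not feats:
            raise ParseError(f"{path}: empty table and no declared length")
        declared = max(f.end for f in feats)
    return CircularGenome(name=path.stem, length=declared,
                          sequence=sequence, features=feats)


_GENBANK_TYPES = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "CR",
    "rep_origin": "OL",
    "misc_feature": "NCR",
}


def _read_genbank(path: Path) -> CircularGenome:
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq) if len(record.seq) else None
    feats: list[Feature] = []
    for sf in record.features:
        cls = _GENBANK_TYPES.get(sf.type)
        if cls is None:
            continue
        quals = sf.qualifiers
        label = (quals.get("gene") or quals.get("product")
                 or quals.get("note") or [sf.type])[0]
        parts = sf.location.parts
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        wraps = len(parts) > 1 and int(parts[0].start) > int(parts[-1].end)
        feats.append(Feature(
            name=canonical_name(label),
            feature_class=cls,
            start=start,
            end=end,
            strand="H" if sf.location.strand != -1 else "L",
            wraps_origin=wraps,
        ))
    return CircularGenome(name=record.id or path.stem, length=len(record.seq)
                          or max(f.end for f in feats),
                          sequence=seq, features=feats)


def write_feature_table(g: CircularGenome, path: str | Path) -> None:
    """Write the canonical TSV dialect (1-based closed coordinates)."""
    lines = [
        "# mitokit feature table; coordinates 1-based, closed; strand H/L",
        f"# length={g.length}",
        "name\tclass\tstart\tend\tstrand\tstart_codon\tstop_codon\twraps_origin",
    ]
    for f in g.features:
        lines.append("\t".join([
            f.name, f.feature_class, str(f.start), str(f.end), f.strand,
            f.start_codon or "", f.stop_codon or "",
            "1" if f.wraps_origin else "",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA and report I/O

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(name, sequence)`` pairs.

    Sequences are uppercased with U mapped to T; non-IUPAC characters raise
    :class:`ValidationError`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, normalize_sequence(str(rec.seq))))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def write_report(obj, path: str | Path, format: str = "json") -> None:
    """Serialize a report object deterministically.

    ``json`` writes any dataclass/dict/list structure with stable key order;
    ``tsv`` expects a list of flat records (dicts or dataclasses) and writes
    one row per record.
    """
    data = _plain(obj)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(data, indent=2, sort_keys=False) + "\n")
    elif format == "tsv":
        if isinstance(data, dict):
            data = [data]
        if not isinstance(data, list):
            raise ValueError("tsv format requires a list of records")
        cols: list[str] = []
        for rec in data:
            for k in rec:
                if k not in cols:
                    cols.append(k)
        lines = ["\t".join(cols)]
        for rec in data:
            lines.append("\t".join(_cell(rec.get(c, "")) for c in cols))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, (list, tuple, dict)):
        return json.dumps(_plain(v), sort_keys=False)
    return str(v)
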