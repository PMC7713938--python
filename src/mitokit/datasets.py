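"""Access to the small reference datasets shipped with the package.

These are published values for the *Rana omeimontis* mitogenome (GenBank
MK483118) and the ranid control-region survey it belongs to: the annotation
table, the codon-usage table of its 13 protein-coding genes, the
control-region tandem-repeat arrays and the conserved-motif library, and
the neobatrachian-type reference gene order.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome import CircularGenome, read_feature_table

__all__ = [
    "rana_omeimontis_genome",
    "published_intergenic_column",
    "codon_counts",
    "published_rscu",
    "cr_motif_library",
    "cr_repeat_units",
    "PUBLISHED_BASE_PCT",
    "PUBLISHED_AT_PCT",
]

# Printed per-base percentages (whole genome and the 12S rRNA) and the A+T
# figures they should assemble to.
PUBLISHED_BASE_PCT = {
    "genome": {"A": 27.29, "T": 28.85, "C": 28.87, "G": 15.00},
    "12S": {"A": 29.61, "T": 23.93, "C": 26.39, "G": 20.06},
}
PUBLISHED_AT_PCT = {"genome": 56.14, "12S": 53.54}


def _path(name: str):
    return resources.files("mitokit.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def rana_omeimontis_genome() -> CircularGenome:
    """The published 40-feature annotation as a :class:`CircularGenome`."""
    with resources.as_file(_path("rana_omeimontis_features.tsv")) as p:
        return read_feature_table(p, dialect="tsv")


def published_intergenic_column() -> list[int]:
    """The printed intergenic-nucleotide column, one cell per feature row
    (row i = spacer to the next feature; the last cell is the wrap-around)."""
    df = _read_tsv("rana_omeimontis_features.tsv")
    return [int(v) for v in df["intergenic_published"]]


def codon_counts() -> dict[str, int]:
    """Published codon counts of the 13 protein-coding genes (RNA keys)."""
    df = _read_tsv("rana_omeimontis_codon_usage.tsv")
    return dict(zip(df["codon"], df["count"].astype(int)))


def published_rscu() -> dict[str, float]:
    """RSCU values exactly as printed in the published codon-usage table."""
    df = _read_tsv("rana_omeimontis_codon_usage.tsv")
    return dict(zip(df["codon"], df["rscu_published"].astype(float)))


def cr_motif_library(species: str | None = None) -> list[tuple]:
    """Conserved CR segments (TAS/OH/CSB1-3) as ``(name, sequence, species)``
    triples, optionally restricted to one species (then ``(name, sequence)``)."""
    df = _read_tsv("cr_motif_library.tsv")
    if species is not None:
        sub = df[df["species"] == species]
        if sub.empty:
            raise KeyError(f"no motif entries for species {species!r}")
        return list(zip(sub["motif"], sub["sequence"]))
    return list(zip(df["motif"], df["sequence"], df["species"]))


def cr_repeat_units() -> list[dict]:
    """Published CR tandem-repeat arrays (label, counts, period, unit)."""
    df = _read_tsv("rana_omeimontis_cr_repeats.tsv")
    return df.to_dict(orient="records")
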