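"""HLA evolutionary divergence (HED) from Grantham chemical distances.

HED quantifies the functional divergence between the two alleles an
individual carries at an HLA locus: the mean Grantham distance over the
aligned peptide-binding-domain sequences of the two allele proteins
(class I: the exon 2-3 region).  A more divergent pair of alleles presents
a broader immunopeptidome; mean class I HED averages loci A, B and C and is
used here as an immunogenetic predictor of TCR repertoire reconstitution.

This module does not align: allele FASTA inputs are pre-aligned,
equal-length per locus, with '-' or '.' marking gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._grantham import GRANTHAM, RESIDUES

GAP_CHARS = ("-", ".")
CLASS1_LOCI = ("A", "B", "C")


class HEDError(ValueError):
    pass


def grantham_distance(a: str, b: str) -> float:
    """Grantham (1974) chemical distance between two residues.

    Symmetric, zero on the diagonal; raises on a nonstandard residue.
    """
    a, b = a.upper(), b.upper()
    if a not in RESIDUES:
        raise HEDError(f"nonstandard residue {a!r}")
    if b not in RESIDUES:
        raise HEDError(f"nonstandard residue {b!r}")
    return float(GRANTHAM[(a, b)])


@dataclass(frozen=True)
class AlleleProteinSequence:
    """An HLA allele's peptide-binding-domain protein sequence (pre-aligned)."""

    allele_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise HEDError(f"{self.allele_name}: empty sequence")
        bad = {
            c for c in self.sequence.upper() if c not in RESIDUES and c not in GAP_CHARS
        }
        if bad:
            raise HEDError(f"{self.allele_name}: nonstandard symbols {sorted(bad)}")

    @property
    def locus(self) -> str:
        return self.allele_name.split("*")[0]


def sequence_divergence(
    s1: AlleleProteinSequence, s2: AlleleProteinSequence, normalize: bool = True
) -> float:
    """Mean (or raw-sum) Grantham distance over aligned positions.

    Positions where either sequence has a gap are excluded from both
    numerator and denominator.  ``normalize=True`` (the default, the
    convention of the HED literature) divides by the number of compared
    positions; ``False`` returns the raw sum.
    """
    a, b = s1.sequence.upper(), s2.sequence.upper()
    if len(a) != len(b):
        raise HEDError(
            f"aligned length mismatch: {s1.allele_name}={len(a)}, {s2.allele_name}={len(b)}"
        )
    total = 0.0
    n = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        total += GRANTHAM[(x, y)]
        n += 1
    if n == 0:
        raise HEDError(
            f"{s1.allele_name} vs {s2.allele_name}: no gap-free aligned positions"
        )
    return total / n if normalize else total


@dataclass(frozen=True)
class HEDResult:
    individual_id: str
    hed_a: float
    hed_b: float
    hed_c: float
    mean_class1: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def two_field(allele: str) -> str:
    """Truncate an HLA allele name to two-field (protein-level) resolution."""
    locus, _, fields = allele.partition("*")
    parts = fields.split(":")
    return f"{locus}*{':'.join(parts[:2])}" if len(parts) >= 2 else allele


def read_allele_fasta(path: str | Path) -> dict[str, AlleleProteinSequence]:
    """Read a pre-aligned allele FASTA into a name -> sequence map.

    Headers may be plain allele names ('A*01:01') or IMGT/HLA style
    ('HLA:HLA00001 A*01:01:01:01 365 bp'); the allele name is taken from the
    second token when the first looks like an IMGT accession.  Alleles are
    indexed at two-field resolution; the first sequence seen for a two-field
    name wins.
    """
    db: dict[str, AlleleProteinSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        name = tokens[0]
        if name.startswith("HLA:") and len(tokens) > 1:
            name = tokens[1]
        key = two_field(name)
        if key not in db:
            db[key] = AlleleProteinSequence(key, str(rec.seq).upper())
    return db


def locus_divergence(
    allele1: str,
    allele2: str,
    allele_db: dict[str, AlleleProteinSequence],
    normalize: bool = True,
) -> float:
    """HED at one locus; zero for a homozygous genotype."""
    k1, k2 = two_field(allele1), two_field(allele2)
    for k in (k1, k2):
        if k not in allele_db:
            raise HEDError(f"allele {k!r} not found in the allele database")
    if k1 == k2:
        return 0.0
    return sequence_divergence(allele_db[k1], allele_db[k2], normalize=normalize)


def mean_class1_hed(
    genotype: dict[str, tuple[str, str]] | list[str],
    allele_db: dict[str, AlleleProteinSequence],
    individual_id: str = "",
    normalize: bool = True,
) -> HEDResult:
    """Per-locus HED at A, B, C and their arithmetic mean.

    ``genotype`` is either ``{"A": (a1, a2), "B": ..., "C": ...}`` or the
    flat six-allele list (A1, A2, B1, B2, C1, C2).  Unresolvable alleles
    fail loudly (no nearest-allele fallback).
    """
    if isinstance(genotype, (list, tuple)):
        if len(genotype) != 6:
            raise HEDError(f"expected six alleles, got {len(genotype)}")
        genotype = {
            "A": (genotype[0], genotype[1]),
            "B": (genotype[2], genotype[3]),
            "C": (genotype[4], genotype[5]),
        }
    per_locus = {}
    for locus in CLASS1_LOCI:
        if locus not in genotype:
            raise HEDError(f"genotype missing locus {locus}")
        a1, a2 = genotype[locus]
        per_locus[locus] = locus_divergence(a1, a2, allele_db, normalize=normalize)
    return HEDResult(
        individual_id=individual_id,
        hed_a=per_locus["A"],
        hed_b=per_locus["B"],
        hed_c=per_locus["C"],
        mean_class1=sum(per_locus.values()) / 3.0,
    )


def hed_table(
    genotypes_tsv: str | Path,
    allele_db: dict[str, AlleleProteinSequence],
    normalize: bool = True,
) -> pd.DataFrame:
    """HED per individual from a genotype TSV (individual_id, A1..C2)."""
    df = pd.read_csv(genotypes_tsv, sep="\t", dtype=str)
    required = ["individual_id", "A1", "A2", "B1", "B2", "C1", "C2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise HEDError(f"genotype table missing column(s): {missing}")
    rows = []
    for _, r in df.iterrows():
        res = mean_class1_hed(
            [r["A1"], r["A2"], r["B1"], r["B2"], r["C1"], r["C2"]],
            allele_db,
            individual_id=r["individual_id"],
            normalize=normalize,
        )
        rows.append(res.as_dict())
    return pd.DataFrame(rows)
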