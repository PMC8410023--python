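"""Reading, validation, filtering and aggregation of TCRbeta rearrangement tables.

Two TSV dialects are supported: the ImmunoSEQ v2 export format (columns
``rearrangement, amino_acid, v_resolved, j_resolved, templates, frame_type``)
and the AIRR Rearrangement schema (``junction, junction_aa, v_call, j_call,
duplicate_count, productive``).  Both are mapped onto a common
:class:`RearrangementRecord`, and productive records are aggregated into a
:class:`ClonotypeTable` keyed by CDR3 amino-acid sequence, the unit every
downstream metric operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: recognized sample groups (cohort role / longitudinal timepoint)
GROUPS = (
    "healthy_control",
    "donor",
    "recipient_pre",
    "recipient_d30",
    "recipient_d100",
    "recipient_d180",
    "other",
)

IN_FRAME = "in_frame"
OUT_OF_FRAME = "out_of_frame"
HAS_STOP = "has_stop"


class DialectError(ValueError):
    """A required column of the declared TSV dialect is missing."""


class RowParseError(ValueError):
    """A data row violates the rearrangement schema (bad count, etc.)."""


@dataclass(frozen=True)
class RearrangementRecord:
    """One sequenced TCRbeta rearrangement.

    ``templates`` counts genomic DNA molecules carrying the rearrangement
    (the abundance unit of the assay); ``frame_status`` distinguishes
    productive (in-frame, stop-free) rearrangements from non-productive ones.
    """

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    templates: int
    frame_status: str

    def __post_init__(self) -> None:
        if self.templates < 1:
            raise RowParseError(f"templates must be >= 1, got {self.templates}")
        if self.frame_status not in (IN_FRAME, OUT_OF_FRAME, HAS_STOP):
            raise RowParseError(f"unknown frame_status {self.frame_status!r}")

    @property
    def is_productive(self) -> bool:
        return (
            self.frame_status == IN_FRAME
            and bool(self.cdr3_aa)
            and "*" not in self.cdr3_aa
        )


@dataclass
class ClonotypeTable:
    """One sample's productive clonotypes with template counts.

    Rows are keyed by CDR3 amino-acid sequence (clonotype key); convergent
    nucleotide rearrangements translating to the same CDR3 are merged.
    """

    sample_id: str
    counts: pd.Series  # index: clonotype_key (unique), values: templates >= 1
    group: str = "other"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        s = pd.Series(self.counts, dtype="int64")
        if not s.index.is_unique:
            raise ValueError("clonotype keys must be unique within a sample")
        if len(s) and (s <= 0).any():
            raise ValueError("template counts must be positive")
        s.index = s.index.astype(str)
        s.index.name = "clonotype_key"
        s.name = "templates"
        self.counts = s

    @property
    def richness(self) -> int:
        """Number of unique clonotypes."""
        return int(len(self.counts))

    @property
    def total_templates(self) -> int:
        """Sample depth in templates."""
        return int(self.counts.sum())

    def frequencies(self) -> pd.Series:
        return self.counts / self.total_templates

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.reset_index()
        df.insert(0, "sample_id", self.sample_id)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClonotypeTable):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.group == other.group
            and self.counts.sort_index().equals(other.counts.sort_index())
        )


# ---------------------------------------------------------------------------
# dialect handling

_IMMUNOSEQ_COLS = {
    "cdr3_nt": "rearrangement",
    "cdr3_aa": "amino_acid",
    "v_gene": "v_resolved",
    "j_gene": "j_resolved",
    "templates": "templates",
    "frame": "frame_type",
}
_AIRR_COLS = {
    "cdr3_nt": "junction",
    "cdr3_aa": "junction_aa",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "templates": "duplicate_count",
    "frame": "productive",
}
# ImmunoSEQ exports name the abundance column either "templates" or
# "count (templates/reads)" depending on pipeline version.
_IMMUNOSEQ_COUNT_ALIASES = ("templates", "count (templates/reads)")


def _detect_dialect(columns: Sequence[str]) -> str:
    cols = set(columns)
    if {"junction_aa", "duplicate_count"} <= cols or {"v_call", "junction_aa"} <= cols:
        return "airr"
    if "amino_acid" in cols and (cols & set(_IMMUNOSEQ_COUNT_ALIASES)):
        return "immunoseq_v2"
    raise DialectError(
        "could not auto-detect dialect from header columns: " + ", ".join(columns)
    )


def _immunoseq_frame_status(value: str) -> str:
    v = str(value).strip().lower()
    if v in ("in", "in-frame", "inframe"):
        return IN_FRAME
    if v in ("out", "out-of-frame", "outofframe"):
        return OUT_OF_FRAME
    if v in ("stop", "has_stop"):
        return HAS_STOP
    raise RowParseError(f"unrecognized frame_type {value!r}")


def _airr_frame_status(productive: str, cdr3_aa: str) -> str:
    v = str(productive).strip().lower()
    if v in ("t", "true", "1", "yes"):
        return IN_FRAME
    # AIRR 'productive' conflates out-of-frame and stop-containing; recover
    # the stop case from the junction translation when available.
    if "*" in cdr3_aa:
        return HAS_STOP
    return OUT_OF_FRAME


def read_rearrangements(
    path: str | Path, dialect: str = "auto"
) -> list[RearrangementRecord]:
    """Parse a rearrangement TSV into :class:`RearrangementRecord` objects.

    Parameters
    ----------
    path:
        TSV file with one header row. Unknown columns are ignored.
    dialect:
        ``"immunoseq_v2"``, ``"airr"``, or ``"auto"`` (header inspection).

    Raises
    ------
    DialectError
        If a required column of the (declared or detected) dialect is absent.
    RowParseError
        On a non-integer or non-positive template count, with the line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "auto":
        dialect = _detect_dialect(df.columns)
    if dialect == "immunoseq_v2":
        colmap = dict(_IMMUNOSEQ_COLS)
        present = [c for c in _IMMUNOSEQ_COUNT_ALIASES if c in df.columns]
        if present:
            colmap["templates"] = present[0]
    elif dialect == "airr":
        colmap = dict(_AIRR_COLS)
    else:
        raise DialectError(f"unknown dialect {dialect!r}")

    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise DialectError(
            f"{path.name}: dialect {dialect!r} requires missing column(s): "
            + ", ".join(missing)
        )

    records: list[RearrangementRecord] = []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        r = dict(zip(df.columns, row))
        raw_count = r[colmap["templates"]].strip()
        try:
            templates = int(raw_count)
        except ValueError:
            raise RowParseError(
                f"{path.name}, line {i}: non-integer template count {raw_count!r}"
            ) from None
        if templates < 1:
            raise RowParseError(
                f"{path.name}, line {i}: template count must be >= 1, got {templates}"
            )
        cdr3_aa = r[colmap["cdr3_aa"]].strip().upper()
        if dialect == "immunoseq_v2":
            frame = _immunoseq_frame_status(r[colmap["frame"]])
        else:
            frame = _airr_frame_status(r[colmap["frame"]], cdr3_aa)
        if frame == IN_FRAME and "*" in cdr3_aa:
            frame = HAS_STOP
        records.append(
            RearrangementRecord(
                cdr3_nt=r[colmap["cdr3_nt"]].strip().upper(),
                cdr3_aa=cdr3_aa,
                v_gene=r[colmap["v_gene"]].strip(),
                j_gene=r[colmap["j_gene"]].strip(),
                templates=templates,
                frame_status=frame,
            )
        )
    if not records:
        logger.warning("%s: no data rows (header only)", path.name)
    logger.info(
        "%s: parsed %d rearrangements (%d skipped)", path.name, len(records), n_skipped
    )
    return records


def filter_productive(
    records: Iterable[RearrangementRecord],
) -> list[RearrangementRecord]:
    """Keep in-frame rearrangements whose CDR3 translation has no stop codon.

    Order-preserving and idempotent.
    """
    return [r for r in records if r.is_productive]


def aggregate_clonotypes(
    records: Iterable[RearrangementRecord],
    sample_id: str,
    group: str = "other",
    key: str = "aa",
) -> ClonotypeTable:
    """Collapse productive rearrangements into a clonotype table.

    ``key="aa"`` merges convergent nucleotide rearrangements sharing a CDR3
    amino-acid sequence (template counts summed); ``key="aa_vfamily"`` keys
    by (CDR3aa, V gene family) for sensitivity analyses.
    """
    records = list(records)
    if any(not r.is_productive for r in records):
        raise ValueError("aggregate_clonotypes expects productive records only")
    agg: dict[str, int] = {}
    for r in records:
        if key == "aa":
            k = r.cdr3_aa
        elif key == "aa_vfamily":
            k = f"{r.cdr3_aa}|{r.v_gene.split('-')[0]}"
        else:
            raise ValueError(f"unknown clonotype key scheme {key!r}")
        agg[k] = agg.get(k, 0) + r.templates
    counts = pd.Series(agg, dtype="int64")
    return ClonotypeTable(sample_id=sample_id, counts=counts, group=group)


# ---------------------------------------------------------------------------
# canonical clonotype TSV round-trip

def write_clonotype_tsv(table: ClonotypeTable, path: str | Path) -> None:
    """Write the canonical per-sample clonotype TSV (sample_id, clonotype_key, templates)."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_clonotype_tsv(path: str | Path, group: str = "other") -> ClonotypeTable:
    """Read a canonical clonotype TSV written by :func:`write_clonotype_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "clonotype_key": str})
    required = {"sample_id", "clonotype_key", "templates"}
    missing = required - set(df.columns)
    if missing:
        raise DialectError(f"{Path(path).name}: missing column(s) {sorted(missing)}")
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError(
            f"{Path(path).name}: expected exactly one sample_id, found {len(sample_ids)}"
        )
    counts = pd.Series(
        df["templates"].to_numpy("int64"), index=df["clonotype_key"], dtype="int64"
    )
    return ClonotypeTable(sample_id=str(sample_ids[0]), counts=counts, group=group)


def read_cohort(
    directory: str | Path, pattern: str = "*.tsv", groups: dict[str, str] | None = None
) -> list[ClonotypeTable]:
    """Read every canonical clonotype TSV in a directory (sorted by filename)."""
    directory = Path(directory)
    required = {"sample_id", "clonotype_key", "templates"}
    tables = []
    for p in sorted(directory.glob(pattern)):
        with open(p, encoding="utf-8") as fh:
            header = set(fh.readline().rstrip("\n").split("\t"))
        if not required <= header:
            logger.warning("%s: not a clonotype table, skipped", p.name)
            continue
        t = read_clonotype_tsv(p)
        if groups and t.sample_id in groups:
            t.group = groups[t.sample_id]
        tables.append(t)
    return tables
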