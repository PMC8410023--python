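"""CDR3 specificity annotation against aggregated reference databases.

Clonotypes are matched by exact CDR3 amino-acid identity against a reference
aggregating known TCR-epitope associations (VDJdb / McPAS style tables),
each entry carrying an epitope, an antigen source, a pathology category
(pathogen / cancer / autoimmune / allergy / other) and its source database.
A clonotype may match several entries and therefore carry several
categories; per-category summaries deliberately count it once per category
(the double-counting is surfaced, not hidden).

CMV-specific clonotype tracking is by convention run on NON-normalized
tables so that downsampling does not discard low-abundance specificities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ClonotypeTable
from .metrics import ExpansionThreshold

logger = logging.getLogger(__name__)

CATEGORIES = ("pathogen", "cancer", "autoimmune", "allergy", "other")

#: canonical reference-table columns
REF_COLUMNS = ("cdr3", "antigen_epitope", "antigen_species", "category", "disease", "source")


class ReferenceError(ValueError):
    pass


@dataclass(frozen=True)
class SpecificityEntry:
    epitope: str
    antigen_source: str
    category: str
    disease_label: str
    provenance: str


@dataclass
class SpecificityReference:
    """Map from uppercase CDR3 amino-acid sequence to its known associations."""

    entries: dict[str, list[SpecificityEntry]] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    @property
    def n_cdr3(self) -> int:
        return len(self.entries)

    def add(self, cdr3: str, entry: SpecificityEntry) -> bool:
        """Add an entry; exact-duplicate (cdr3, epitope, provenance) triples collapse."""
        cdr3 = cdr3.upper()
        existing = self.entries.setdefault(cdr3, [])
        for e in existing:
            if e.epitope == entry.epitope and e.provenance == entry.provenance:
                return False
        existing.append(entry)
        return True

    def restrict_disease(self, disease_label: str) -> "SpecificityReference":
        """Sub-reference of entries whose disease label matches (e.g. 'CMV')."""
        out = SpecificityReference()
        for cdr3, entries in self.entries.items():
            kept = [e for e in entries if e.disease_label == disease_label]
            if kept:
                out.entries[cdr3] = list(kept)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cdr3": cdr3,
                "antigen_epitope": e.epitope,
                "antigen_species": e.antigen_source,
                "category": e.category,
                "disease": e.disease_label,
                "source": e.provenance,
            }
            for cdr3, entries in sorted(self.entries.items())
            for e in entries
        ]
        return pd.DataFrame(rows, columns=list(REF_COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


DEFAULT_COLUMN_MAP = {c: c for c in REF_COLUMNS}


def load_column_map(path: str | Path) -> tuple[dict, dict]:
    """Load a YAML column/category mapping for a reference source.

    Keys: ``columns`` (canonical -> source column name) and optional
    ``categories`` (source category label -> canonical category).
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh) or {}
    return spec.get("columns", dict(DEFAULT_COLUMN_MAP)), spec.get("categories", {})


def build_reference(
    sources: list[str | Path | tuple],
) -> SpecificityReference:
    """Aggregate one or more annotation TSVs into a single reference.

    Each source is a path (canonical columns assumed) or a tuple
    ``(path, column_map, category_map)``.  Category labels must map onto the
    canonical set; unmapped labels raise, listing the offenders.
    """
    ref = SpecificityReference()
    if not sources:
        logger.warning("building an empty specificity reference (no sources)")
        return ref
    for source in sources:
        if isinstance(source, (tuple, list)):
            path, colmap, catmap = source
        else:
            path, colmap, catmap = source, dict(DEFAULT_COLUMN_MAP), {}
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in colmap.values() if c not in df.columns]
        if missing:
            raise ReferenceError(f"{Path(path).name}: missing column(s) {missing}")
        raw_cats = df[colmap["category"]].map(lambda c: catmap.get(c, c))
        bad = sorted(set(raw_cats) - set(CATEGORIES))
        if bad:
            raise ReferenceError(
                f"{Path(path).name}: unmapped category label(s): {', '.join(bad)}"
            )
        n_added = 0
        for i, row in df.iterrows():
            n_added += ref.add(
                row[colmap["cdr3"]],
                SpecificityEntry(
                    epitope=row[colmap["antigen_epitope"]],
                    antigen_source=row[colmap["antigen_species"]],
                    category=raw_cats.loc[i],
                    disease_label=row[colmap["disease"]],
                    provenance=row[colmap["source"]],
                ),
            )
        logger.info("%s: %d entries added", Path(path).name, n_added)
    return ref


def annotate(table: ClonotypeTable, ref: SpecificityReference) -> pd.DataFrame:
    """Long-format annotation of a clonotype table.

    One row per (clonotype, matching reference entry); unmatched clonotypes
    get a single row with category ``unknown``.  Exact uppercase CDR3
    amino-acid matching only — fuzzy matching would change counts in ways
    that cannot be validated against the reference.
    """
    rows = []
    for key, size in table.counts.items():
        matches = ref.entries.get(str(key).upper(), [])
        if not matches:
            rows.append(
                {
                    "sample_id": table.sample_id,
                    "clonotype_key": key,
                    "templates": int(size),
                    "category": "unknown",
                    "epitope": "",
                    "antigen_source": "",
                    "disease": "",
                    "source": "",
                }
            )
        for e in matches:
            rows.append(
                {
                    "sample_id": table.sample_id,
                    "clonotype_key": key,
                    "templates": int(size),
                    "category": e.category,
                    "epitope": e.epitope,
                    "antigen_source": e.antigen_source,
                    "disease": e.disease_label,
                    "source": e.provenance,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "clonotype_key",
            "templates",
            "category",
            "epitope",
            "antigen_source",
            "disease",
            "source",
        ],
    )


@dataclass(frozen=True)
class AnnotationSummary:
    per_category: pd.DataFrame  # index category; columns n_clonotypes, template_fraction, mean_size
    annotated_fraction_of_repertoire: float
    annotated_template_fraction: float


def category_summary(
    annotated: pd.DataFrame, depth: int | None = None
) -> AnnotationSummary:
    """Per-pathology composition of an annotated sample.

    For each category: number of distinct clonotypes, their mean template
    count, and their share of template space.  A clonotype annotated in k
    categories contributes to each of the k (documented double-counting), but
    is counted once in the overall annotated fraction.
    """
    if depth is None:
        depth = int(
            annotated.drop_duplicates("clonotype_key")["templates"].sum()
        )
    known = annotated[annotated["category"] != "unknown"]
    rows = []
    for cat in CATEGORIES:
        sub = known[known["category"] == cat].drop_duplicates("clonotype_key")
        rows.append(
            {
                "category": cat,
                "n_clonotypes": int(len(sub)),
                "template_fraction": float(sub["templates"].sum() / depth) if depth else 0.0,
                "mean_size": float(sub["templates"].mean()) if len(sub) else 0.0,
            }
        )
    per_cat = pd.DataFrame(rows).set_index("category")
    distinct = annotated.drop_duplicates("clonotype_key")
    annotated_keys = set(known["clonotype_key"])
    n_total = len(distinct)
    ann_mask = distinct["clonotype_key"].isin(annotated_keys)
    return AnnotationSummary(
        per_category=per_cat,
        annotated_fraction_of_repertoire=float(ann_mask.sum() / n_total) if n_total else 0.0,
        annotated_template_fraction=float(distinct.loc[ann_mask, "templates"].sum() / depth)
        if depth
        else 0.0,
    )


def track_category_over_time(
    samples: list[tuple[str, pd.DataFrame]], category: str
) -> pd.DataFrame:
    """Longitudinal (n clonotypes, mean size) of one category across timepoints.

    ``samples`` is an ordered list of (timepoint label, annotated table).
    Run on non-normalized annotations when tracking low-abundance
    specificities such as CMV.
    """
    rows = []
    for label, annotated in samples:
        sub = annotated[annotated["category"] == category].drop_duplicates(
            "clonotype_key"
        )
        rows.append(
            {
                "timepoint": label,
                "n_clonotypes": int(len(sub)),
                "mean_size": float(sub["templates"].mean()) if len(sub) else 0.0,
                "total_templates": int(sub["templates"].sum()),
            }
        )
    return pd.DataFrame(rows)


def cmv_clonotype_count(
    table: ClonotypeTable, cmv_ref: SpecificityReference
) -> int:
    """Distinct clonotypes with at least one CMV annotation.

    By convention applied to the non-normalized table so that rare CMV
    specificities are not lost to downsampling; duplicate annotations on one
    clonotype count once.
    """
    keys = set(cmv_ref.entries)
    return int(sum(1 for k in table.counts.index if str(k).upper() in keys))
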