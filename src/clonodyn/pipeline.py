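"""End-to-end orchestration: ingest -> normalize -> threshold -> metrics ->
overlap -> annotate -> HED -> export.

Every stage reads and writes plain TSV (no opaque binary state), so each is
independently testable and replaceable; a run manifest records inputs,
outputs, content hashes, seeds and the package version, and a rerun with an
identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io import ClonotypeTable, read_cohort, write_clonotype_tsv
from .normalization import DownsampleConfig, determine_common_depth, normalize_cohort
from .metrics import ExpansionThreshold, derive_threshold, metrics_table
from .overlap import donor_recipient_overlap, public_background
from .specificity import (
    SpecificityReference,
    annotate,
    build_reference,
    cmv_clonotype_count,
)
from . import hed as hed_mod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated settings for a full pipeline run."""

    input_dir: str
    output_dir: str
    seed: int = 0
    min_acceptable_depth: int = 5420
    target_depth: int | None = None  # None -> determined from the cohort
    tau: int | None = None  # fixed threshold; mutually exclusive with reference derivation
    pairing_manifest: str | None = None
    sample_groups: str | None = None  # TSV sample_id, group
    reference_db: str | None = None  # specificity reference TSV
    hed_alleles: str | None = None  # pre-aligned allele FASTA
    hed_genotypes: str | None = None  # genotype TSV
    hyper_cutoff: int = 100
    cmv_on_normalized: bool = False

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise PipelineError(f"input_dir {self.input_dir} does not exist")
        for name in ("pairing_manifest", "sample_groups", "reference_db",
                     "hed_alleles", "hed_genotypes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"{name} path {p} does not exist")
        if (self.hed_alleles is None) != (self.hed_genotypes is None):
            raise PipelineError("hed_alleles and hed_genotypes must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _assign_groups(
    tables: list[ClonotypeTable], config: RunConfig, pairing: pd.DataFrame | None
) -> None:
    groups: dict[str, str] = {}
    if config.sample_groups:
        df = pd.read_csv(config.sample_groups, sep="\t", dtype=str)
        groups.update(dict(zip(df["sample_id"], df["group"])))
    elif pairing is not None:
        for _, row in pairing.iterrows():
            tp = str(row.get("timepoint", "")).strip()
            groups[row["recipient_id"]] = (
                f"recipient_{tp}" if f"recipient_{tp}" in (
                    "recipient_pre", "recipient_d30", "recipient_d100", "recipient_d180"
                ) else "other"
            )
            groups[row["donor_id"]] = "donor"
    for t in tables:
        if t.sample_id in groups:
            t.group = groups[t.sample_id]
        elif pairing is not None and t.group == "other":
            t.group = "healthy_control"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages in dependency order; returns the manifest."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    t_start = time.time()

    def _stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"t": round(time.time() - t_start, 3)}

    def _emit(name: str, df: pd.DataFrame) -> Path:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = _sha256(path)
        return path

    # --- ingest
    _stage("ingest")
    pairing = (
        pd.read_csv(config.pairing_manifest, sep="\t", dtype=str)
        if config.pairing_manifest
        else None
    )
    tables = read_cohort(config.input_dir)
    if not tables:
        raise PipelineError(f"stage ingest: no clonotype TSVs in {config.input_dir}")
    _assign_groups(tables, config, pairing)
    manifest["stages"]["ingest"]["n_samples"] = len(tables)
    raw_by_id = {t.sample_id: t for t in tables}

    # --- normalize
    _stage("normalize")
    if config.target_depth is not None:
        depth = config.target_depth
        excluded: list[str] = [
            t.sample_id for t in tables if t.total_templates < depth
        ]
    else:
        depth, excluded = determine_common_depth(tables, config.min_acceptable_depth)
    normalized, norm_manifest = normalize_cohort(
        tables, DownsampleConfig(target_depth=depth, seed=config.seed)
    )
    _emit("normalization_manifest.tsv", norm_manifest)
    manifest["stages"]["normalize"].update(
        {"common_depth": depth, "excluded": excluded}
    )
    by_id = {t.sample_id: t for t in normalized}

    # --- threshold
    _stage("threshold")
    reference = [
        t for t in normalized if t.group in ("healthy_control", "donor")
    ]
    if config.tau is not None:
        threshold = ExpansionThreshold.fixed(config.tau)
    else:
        if len(reference) < 2:
            raise PipelineError(
                "stage threshold: need >= 2 reference samples or a fixed --tau"
            )
        threshold = derive_threshold(reference)
    manifest["stages"]["threshold"].update(
        {
            "tau": threshold.tau,
            "upper_ci": threshold.upper_ci,
            "reference_n": threshold.reference_n,
        }
    )

    # --- metrics
    _stage("metrics")
    _emit("metrics.tsv", metrics_table(normalized, threshold, config.hyper_cutoff))

    # --- overlap
    if pairing is not None:
        _stage("overlap")
        related = {
            (r["recipient_id"], r["donor_id"]) for _, r in pairing.iterrows()
        }
        if len(reference) >= 2:
            background = public_background(
                reference, threshold, exclude_pairs=related
            )
        else:
            raise PipelineError("stage overlap: no reference samples for background")
        rows = []
        for _, row in pairing.iterrows():
            rid, did = row["recipient_id"], row["donor_id"]
            if rid not in by_id or did not in by_id:
                logger.warning("overlap: %s or %s excluded at normalization", rid, did)
                continue
            res = donor_recipient_overlap(
                by_id[rid], by_id[did], background, threshold
            )
            rows.append(
                {
                    "recipient_id": res.recipient_id,
                    "donor_id": res.donor_id,
                    "timepoint": row.get("timepoint", ""),
                    "n_shared": res.n_shared,
                    "oc_count": res.oc_count,
                    "oc_weighted": res.oc_weighted,
                    "recipient_shared_fraction": res.recipient_shared_fraction,
                    "adjusted_fraction": res.adjusted_fraction,
                    "raw_minus_background": res.raw_minus_background,
                }
            )
        _emit("overlap.tsv", pd.DataFrame(rows))
        _emit(
            "public_background.tsv",
            pd.DataFrame(
                [
                    {
                        "fraction_all": background.fraction_all,
                        "fraction_expanded": background.fraction_expanded,
                        "fraction_path_expanded": background.fraction_path_expanded,
                        "n_pairs": background.n_pairs,
                    }
                ]
            ),
        )

    # --- annotate
    if config.reference_db is not None:
        _stage("annotate")
        ref = build_reference([config.reference_db])
        ann_frames = [annotate(t, ref) for t in normalized]
        long = pd.concat(ann_frames, ignore_index=True)
        _emit("annotation.tsv", long[long["category"] != "unknown"])
        cmv_ref = ref.restrict_disease("CMV")
        cmv_tables = normalized if config.cmv_on_normalized else list(raw_by_id.values())
        _emit(
            "cmv_counts.tsv",
            pd.DataFrame(
                [
                    {
                        "sample_id": t.sample_id,
                        "group": t.group,
                        "n_cmv_clonotypes": cmv_clonotype_count(t, cmv_ref),
                        "normalized": config.cmv_on_normalized,
                    }
                    for t in cmv_tables
                ]
            ),
        )

    # --- hed
    if config.hed_alleles is not None:
        _stage("hed")
        allele_db = hed_mod.read_allele_fasta(config.hed_alleles)
        _emit("hed.tsv", hed_mod.hed_table(config.hed_genotypes, allele_db))

    manifest["elapsed_s"] = round(time.time() - t_start, 3)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
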