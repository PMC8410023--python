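"""Depth normalization by downsampling without replacement.

Sequencing depth (total templates) varies widely across samples, and
richness-type metrics scale with depth, so every cross-sample comparison is
run at a common depth.  The common depth is the minimum depth among samples
passing a floor (`min_acceptable`), and each sample is subsampled to it by
drawing individual templates uniformly without replacement — a multivariate
hypergeometric draw over clonotypes, i.e. a physical subsampling of the
sequenced molecules, which guarantees no clonotype exceeds its original count.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClonotypeTable


@dataclass(frozen=True)
class DownsampleConfig:
    """Downsampling settings: common target depth, master seed, replicate count."""

    target_depth: int
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.target_depth < 1:
            raise ValueError("target_depth must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")


class DepthError(ValueError):
    """Requested depth incompatible with the sample/cohort depths."""


def determine_common_depth(
    cohort: list[ClonotypeTable], min_acceptable: int
) -> tuple[int, list[str]]:
    """Lowest acceptable depth across a cohort.

    Samples shallower than ``min_acceptable`` are excluded; the common depth
    is the minimum depth of the remaining samples.

    Returns
    -------
    (depth, excluded_ids):
        The common depth and the sample ids that fell below the floor.

    Raises
    ------
    DepthError
        If no sample reaches ``min_acceptable``.
    """
    if not cohort:
        raise DepthError("empty cohort")
    excluded = [t.sample_id for t in cohort if t.total_templates < min_acceptable]
    kept = [t.total_templates for t in cohort if t.total_templates >= min_acceptable]
    if not kept:
        raise DepthError(
            f"all {len(cohort)} samples fall below min_acceptable={min_acceptable}"
        )
    return min(kept), excluded


def sample_seed(master_seed: int, sample_id: str, replicate: int = 0) -> int:
    """Per-sample seed derived by hashing (master seed, sample id, replicate).

    Deterministic and independent of cohort composition: adding or removing a
    sample never perturbs another sample's draw.
    """
    digest = hashlib.blake2b(
        f"{master_seed}:{sample_id}:{replicate}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def downsample(table: ClonotypeTable, depth: int, seed: int) -> ClonotypeTable:
    """Subsample a clonotype table to ``depth`` templates without replacement.

    Per-clonotype sampled counts follow the multivariate hypergeometric law;
    clonotypes reduced to zero templates are dropped.  Identical
    (table, depth, seed) always yields the identical result.

    Raises
    ------
    DepthError
        If ``depth`` exceeds the sample's depth (no upsampling).
    """
    total = table.total_templates
    if depth > total:
        raise DepthError(
            f"{table.sample_id}: requested depth {depth} exceeds sample depth {total}"
        )
    if depth < 0:
        raise DepthError("depth must be non-negative")
    if depth == total:
        return ClonotypeTable(table.sample_id, table.counts.copy(), table.group)
    rng = np.random.default_rng(seed)
    colors = table.counts.to_numpy("int64")
    drawn = rng.multivariate_hypergeometric(colors, depth, method="marginals")
    keep = drawn > 0
    counts = pd.Series(drawn[keep], index=table.counts.index[keep], dtype="int64")
    return ClonotypeTable(table.sample_id, counts, table.group)


def normalize_cohort(
    cohort: list[ClonotypeTable], config: DownsampleConfig
) -> tuple[list[ClonotypeTable], pd.DataFrame]:
    """Downsample every sufficiently deep sample to the configured depth.

    Samples shallower than ``config.target_depth`` are excluded.  Returns the
    normalized tables and a manifest (sample_id, original_depth,
    sampled_depth, seed, included).
    """
    rows = []
    normalized = []
    for t in cohort:
        seed = sample_seed(config.seed, t.sample_id)
        included = t.total_templates >= config.target_depth
        rows.append(
            {
                "sample_id": t.sample_id,
                "group": t.group,
                "original_depth": t.total_templates,
                "sampled_depth": config.target_depth if included else 0,
                "seed": seed,
                "included": included,
            }
        )
        if included:
            normalized.append(downsample(t, config.target_depth, seed))
    return normalized, pd.DataFrame(rows)
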