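"""Per-sample diversity and clonal-expansion metrics.

Clonotypes are classed by template count: nonexpanded (1 template), expanded
(> 1), pathologically expanded (> tau, where tau is derived from a reference
cohort of donors and healthy controls), and hyperexpanded (> 100 by default).
The pathological threshold tau is the floor of the upper limit of the 95%
confidence interval of the across-sample mean size of expanded clonotypes in
the reference cohort — at the study's normalized depth this evaluates to
size > 5 templates.  Diversity is summarized by the Inverse Simpson Index
(ISI), 1 / sum(p_i^2), the effective number of equally abundant clonotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClonotypeTable


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ExpansionThreshold:
    """Reference-derived cutoff for pathological clonal expansion.

    ``tau = floor(upper_ci)``; clonotypes with size strictly greater than
    ``tau`` are pathologically expanded.
    """

    upper_ci: float
    tau: int
    reference_n: int
    mean_of_means: float
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.tau != int(np.floor(self.upper_ci)):
            raise ValueError("tau must equal floor(upper_ci)")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")

    @classmethod
    def fixed(cls, tau: int) -> "ExpansionThreshold":
        """A fixed cutoff not derived from a reference cohort."""
        return cls(upper_ci=float(tau), tau=tau, reference_n=0, mean_of_means=float("nan"))


@dataclass(frozen=True)
class RepertoireMetrics:
    sample_id: str
    group: str
    depth: int
    richness: int
    n_expanded: int
    n_path_expanded: int
    n_hyperexpanded: int
    mean_expansion_size: float
    mean_path_expansion_size: float
    median_path_expansion_size: float
    isi: float
    occupancy_nonexpanded: float
    occupancy_normal: float
    occupancy_pathological: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def inverse_simpson(table: ClonotypeTable) -> float:
    """Inverse Simpson Index: 1 / sum_i p_i^2 over clonotype frequencies.

    Ranges from 1 (one clone dominates totally) to the richness (all clones
    equally abundant).
    """
    if table.richness == 0:
        raise MetricError(f"{table.sample_id}: ISI undefined on an empty table")
    p = table.counts.to_numpy(float) / table.total_templates
    return float(1.0 / np.sum(p * p))


def mean_expanded_size(table: ClonotypeTable) -> float:
    """Mean template count of clonotypes with size > 1; NaN if none."""
    sizes = table.counts[table.counts > 1]
    return float(sizes.mean()) if len(sizes) else float("nan")


def derive_threshold(
    reference: list[ClonotypeTable], ci_level: float = 0.95
) -> ExpansionThreshold:
    """Derive the pathological-expansion cutoff from a reference cohort.

    For each reference sample, the mean size of its expanded clonotypes
    (size > 1) is computed; the across-sample mean gets a t-distribution
    confidence interval (n-1 degrees of freedom) and ``tau`` is the floor of
    its upper limit.  Samples without any expanded clonotype are excluded
    with a warning.
    """
    means = []
    for t in reference:
        m = mean_expanded_size(t)
        if np.isnan(m):
            logging.getLogger(__name__).warning(
                "%s: no expanded clonotypes; excluded from threshold derivation",
                t.sample_id,
            )
            continue
        means.append(m)
    n = len(means)
    if n < 2:
        raise MetricError(
            f"threshold derivation needs >= 2 usable reference samples, got {n}"
        )
    means = np.asarray(means, float)
    grand = float(means.mean())
    se = float(means.std(ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2, df=n - 1))
    upper = grand + tcrit * se
    return ExpansionThreshold(
        upper_ci=upper,
        tau=int(np.floor(upper)),
        reference_n=n,
        mean_of_means=grand,
        ci_level=ci_level,
    )


def compute_metrics(
    table: ClonotypeTable,
    threshold: ExpansionThreshold,
    hyper_cutoff: int = 100,
) -> RepertoireMetrics:
    """All per-sample metrics: richness, expansion counts/sizes, ISI, occupancy.

    Occupancy is measured over template space: the fraction of the sample's
    templates carried by nonexpanded (size 1), normally expanded
    (1 < size <= tau) and pathologically expanded (size > tau) clonotypes.
    """
    if table.richness == 0:
        raise MetricError(f"{table.sample_id}: metrics undefined on an empty table")
    sizes = table.counts.to_numpy("int64")
    depth = int(sizes.sum())
    tau = threshold.tau
    expanded = sizes[sizes > 1]
    path = sizes[sizes > tau]
    occ_non = float(sizes[sizes == 1].sum() / depth)
    occ_norm = float(sizes[(sizes > 1) & (sizes <= tau)].sum() / depth)
    occ_path = float(path.sum() / depth)
    return RepertoireMetrics(
        sample_id=table.sample_id,
        group=table.group,
        depth=depth,
        richness=int(len(sizes)),
        n_expanded=int(len(expanded)),
        n_path_expanded=int(len(path)),
        n_hyperexpanded=int((sizes > hyper_cutoff).sum()),
        mean_expansion_size=float(expanded.mean()) if len(expanded) else float("nan"),
        mean_path_expansion_size=float(path.mean()) if len(path) else float("nan"),
        median_path_expansion_size=float(np.median(path)) if len(path) else float("nan"),
        isi=inverse_simpson(table),
        occupancy_nonexpanded=occ_non,
        occupancy_normal=occ_norm,
        occupancy_pathological=occ_path,
    )


def metrics_table(
    cohort: list[ClonotypeTable],
    threshold: ExpansionThreshold,
    hyper_cutoff: int = 100,
) -> pd.DataFrame:
    """Per-sample metrics for a cohort, one row per sample."""
    return pd.DataFrame(
        [compute_metrics(t, threshold, hyper_cutoff).as_dict() for t in cohort]
    )


def rank_distribution(
    table: ClonotypeTable, bins: tuple[int, ...] = (10, 100, 1000, 10000)
) -> pd.Series:
    """Template-space fraction carried by clonal-size rank bands.

    Clonotypes are ranked by descending size (ties broken by key, so the
    result is reproducible); bands are [1..10], [11..100], [101..1000],
    [1001..10000] and beyond by default.  Fractions sum to 1.
    """
    ordered = table.counts.sort_index().sort_values(ascending=False, kind="stable")
    sizes = ordered.to_numpy("int64")
    depth = sizes.sum()
    labels = []
    fractions = []
    prev = 0
    for b in bins:
        labels.append(f"top_{prev + 1}_{b}")
        lo, hi = prev, min(b, len(sizes))
        fractions.append(float(sizes[lo:hi].sum() / depth) if hi > lo else 0.0)
        prev = b
    labels.append(f"beyond_{bins[-1]}")
    fractions.append(
        float(sizes[bins[-1]:].sum() / depth) if len(sizes) > bins[-1] else 0.0
    )
    return pd.Series(fractions, index=labels, name=table.sample_id)


def group_fold_change(
    group_counts: pd.Series, reference_counts: pd.Series
) -> pd.Series:
    """Elementwise ratio of per-category mean counts against a reference group.

    Categories with a zero reference count get NaN (flagged undefined) rather
    than an infinite ratio.
    """
    group_counts = pd.Series(group_counts, dtype=float)
    reference_counts = pd.Series(reference_counts, dtype=float)
    ratio = group_counts / reference_counts
    ratio[reference_counts == 0] = float("nan")
    return ratio
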