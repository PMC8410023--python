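"""Clonotype sharing between repertoires.

Donor-to-recipient sharing after transplant is confounded by "public"
clonotypes — CDR3 sequences that unrelated individuals share by convergent
recombination.  The public background is estimated as the average pairwise
sharing among unrelated reference samples at the common depth, and is
subtracted from each donor-recipient shared fraction (floored at zero) to
isolate genuine graft-derived carry-over.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClonotypeTable
from .metrics import ExpansionThreshold

SIZE_CLASSES = ("all", "expanded", "pathological")


class OverlapError(ValueError):
    pass


def _restrict(table: ClonotypeTable, size_class: str, threshold: ExpansionThreshold | None) -> pd.Series:
    if size_class == "all":
        return table.counts
    if threshold is None:
        raise OverlapError(f"size_class {size_class!r} requires a threshold")
    if size_class == "expanded":
        return table.counts[table.counts > 1]
    if size_class == "pathological":
        return table.counts[table.counts > threshold.tau]
    raise OverlapError(f"unknown size_class {size_class!r}")


def shared_clonotypes(
    a: ClonotypeTable,
    b: ClonotypeTable,
    size_class: str = "all",
    threshold: ExpansionThreshold | None = None,
    require_common_depth: bool = True,
) -> set[str]:
    """Clonotype keys present in both tables, after restricting *both* to a size class.

    Size-class comparisons are only meaningful at a common depth, so a depth
    mismatch raises unless ``require_common_depth`` is disabled.
    """
    if (
        size_class != "all"
        and require_common_depth
        and a.total_templates != b.total_templates
    ):
        raise OverlapError(
            f"size-class comparison at unequal depths: "
            f"{a.sample_id}={a.total_templates}, {b.sample_id}={b.total_templates}"
        )
    ka = _restrict(a, size_class, threshold).index
    kb = _restrict(b, size_class, threshold).index
    return set(ka.intersection(kb))


def overlap_coefficient(a: ClonotypeTable, b: ClonotypeTable, method: str = "count") -> float:
    """Pairwise repertoire similarity.

    ``count``: |A ∩ B| / min(richness_A, richness_B) — the classical overlap
    coefficient.  ``weighted``: sum over shared clonotypes of the smaller of
    the two frequencies, weighting each shared clonotype by its relative
    abundance.  Both are symmetric and lie in [0, 1].
    """
    if a.richness == 0 or b.richness == 0:
        raise OverlapError("overlap coefficient undefined for an empty table")
    shared = a.counts.index.intersection(b.counts.index)
    if method == "count":
        return float(len(shared) / min(a.richness, b.richness))
    if method == "weighted":
        fa = a.frequencies().loc[shared].to_numpy(float)
        fb = b.frequencies().loc[shared].to_numpy(float)
        return float(np.minimum(fa, fb).sum())
    raise OverlapError(f"unknown method {method!r}")


@dataclass(frozen=True)
class PublicBackground:
    """Average sharing between unrelated individuals, per size class.

    Each fraction is the mean pairwise shared-clonotype count divided by the
    mean per-sample richness of that size class, both at the common depth.
    """

    fraction_all: float
    fraction_expanded: float
    fraction_path_expanded: float
    n_pairs: int

    def fraction(self, size_class: str) -> float:
        return {
            "all": self.fraction_all,
            "expanded": self.fraction_expanded,
            "pathological": self.fraction_path_expanded,
        }[size_class]

    @classmethod
    def zero(cls) -> "PublicBackground":
        return cls(0.0, 0.0, 0.0, 0)


def public_background(
    reference: list[ClonotypeTable],
    threshold: ExpansionThreshold | None = None,
    exclude_pairs: set[tuple[str, str]] | None = None,
) -> PublicBackground:
    """Estimate public-clonotype background from unrelated reference pairs.

    For each size class the background fraction is (mean shared count over
    all unordered unrelated pairs) / (mean per-class richness across the
    reference).  ``exclude_pairs`` removes related pairs (e.g. actual
    donor-recipient couples) from the combinatorial enumeration.
    """
    if len(reference) < 2:
        raise OverlapError("public background needs >= 2 reference samples")
    depths = {t.total_templates for t in reference}
    if len(depths) > 1:
        raise OverlapError(f"reference samples not at a common depth: {sorted(depths)}")
    excluded = {frozenset(p) for p in (exclude_pairs or set())}
    pairs = [
        (a, b)
        for a, b in itertools.combinations(reference, 2)
        if frozenset((a.sample_id, b.sample_id)) not in excluded
    ]
    if not pairs:
        raise OverlapError("no eligible unrelated pairs")
    fractions = {}
    for size_class in SIZE_CLASSES:
        shared_counts = [
            len(shared_clonotypes(a, b, size_class, threshold)) for a, b in pairs
        ]
        richness = [len(_restrict(t, size_class, threshold)) for t in reference]
        mean_rich = float(np.mean(richness))
        fractions[size_class] = (
            float(np.mean(shared_counts)) / mean_rich if mean_rich > 0 else 0.0
        )
    return PublicBackground(
        fraction_all=fractions["all"],
        fraction_expanded=fractions["expanded"],
        fraction_path_expanded=fractions["pathological"],
        n_pairs=len(pairs),
    )


@dataclass(frozen=True)
class OverlapResult:
    recipient_id: str
    donor_id: str
    n_shared: int
    shared_keys: frozenset[str]
    oc_count: float
    oc_weighted: float
    recipient_shared_fraction: float
    adjusted_fraction: float
    raw_minus_background: float  # before flooring at 0
    per_class_shared: dict = field(default_factory=dict)
    per_class_adjusted: dict = field(default_factory=dict)


def donor_recipient_overlap(
    recipient: ClonotypeTable,
    donor: ClonotypeTable,
    background: PublicBackground | None = None,
    threshold: ExpansionThreshold | None = None,
) -> OverlapResult:
    """Donor-recipient sharing with public-background correction.

    ``recipient_shared_fraction`` is the fraction of the recipient's
    clonotypes also present in the donor; ``adjusted_fraction`` subtracts the
    public background and floors at zero (the raw difference is retained).
    """
    if background is None:
        background = PublicBackground.zero()
    shared = shared_clonotypes(recipient, donor, "all")
    frac = len(shared) / recipient.richness
    raw = frac - background.fraction_all
    per_class_shared: dict[str, int] = {}
    per_class_adjusted: dict[str, float] = {}
    if threshold is not None and recipient.total_templates == donor.total_templates:
        for size_class in ("expanded", "pathological"):
            keys = shared_clonotypes(recipient, donor, size_class, threshold)
            per_class_shared[size_class] = len(keys)
            class_rich = len(_restrict(recipient, size_class, threshold))
            class_frac = len(keys) / class_rich if class_rich else 0.0
            per_class_adjusted[size_class] = max(
                0.0, class_frac - background.fraction(size_class)
            )
    return OverlapResult(
        recipient_id=recipient.sample_id,
        donor_id=donor.sample_id,
        n_shared=len(shared),
        shared_keys=frozenset(shared),
        oc_count=overlap_coefficient(recipient, donor, "count"),
        oc_weighted=overlap_coefficient(recipient, donor, "weighted"),
        recipient_shared_fraction=float(frac),
        adjusted_fraction=float(max(0.0, raw)),
        raw_minus_background=float(raw),
        per_class_shared=per_class_shared,
        per_class_adjusted=per_class_adjusted,
    )


RECIPIENT_CLASSES = ("nonexpanded", "normal", "pathological")
DONOR_CLASSES = ("absent", "nonexpanded", "normal", "pathological")


def _size_class_of(size: int, tau: int) -> str:
    if size == 1:
        return "nonexpanded"
    if size <= tau:
        return "normal"
    return "pathological"


def origin_composition(
    recipient: ClonotypeTable,
    donor: ClonotypeTable,
    threshold: ExpansionThreshold,
) -> pd.DataFrame:
    """Cross-tab of recipient clonotypes by (recipient class x donor origin class).

    Every recipient clonotype lands in exactly one cell; a clonotype absent
    from the donor falls in the ``absent`` column, so row sums equal the
    recipient's class sizes.
    """
    tau = threshold.tau
    out = pd.DataFrame(
        0, index=list(RECIPIENT_CLASSES), columns=list(DONOR_CLASSES), dtype="int64"
    )
    donor_counts = donor.counts
    for key, size in recipient.counts.items():
        r_class = _size_class_of(int(size), tau)
        if key in donor_counts.index:
            d_class = _size_class_of(int(donor_counts[key]), tau)
        else:
            d_class = "absent"
        out.loc[r_class, d_class] += 1
    out.index.name = "recipient_class"
    out.columns.name = "donor_class"
    return out


def expansion_size_correlation(
    pairs: list[tuple[int, int]] | pd.DataFrame,
) -> tuple[float, float]:
    """Spearman rank correlation of shared-clonotype sizes (recipient vs donor).

    Returns (rho, p-value).  Requires >= 3 shared clonotypes; an all-tied
    input has no defined ranking and raises.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise OverlapError("Spearman correlation needs >= 3 shared clonotypes")
    if np.all(arr[:, 0] == arr[0, 0]) or np.all(arr[:, 1] == arr[0, 1]):
        raise OverlapError("correlation undefined: all sizes tied")
    rho, p = stats.spearmanr(arr[:, 0], arr[:, 1])
    return float(rho), float(p)


def shared_size_pairs(
    recipient: ClonotypeTable, donor: ClonotypeTable
) -> pd.DataFrame:
    """(recipient size, donor size) for every shared clonotype."""
    shared = sorted(shared_clonotypes(recipient, donor, "all"))
    return pd.DataFrame(
        {
            "clonotype_key": shared,
            "recipient_size": recipient.counts.loc[shared].to_numpy("int64"),
            "donor_size": donor.counts.loc[shared].to_numpy("int64"),
        }
    )
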