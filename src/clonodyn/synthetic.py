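"""Synthetic TCR repertoire cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be validated against construction-time truth:

* clone sizes follow a truncated discrete power law (most clonotypes at one
  template, a heavy tail of expanded clones capped at ``max_clone_size`` —
  larger clones only enter as explicit, labeled pathological spikes);
* a small inter-individual "public" pool of CDR3 keys appears in every
  sample, at about ``public_rate`` of a repertoire, producing the measured
  unrelated-pair background;
* each recipient inherits ``carryover_fraction`` of its clonotypes from its
  donor, with sizes rank-correlated to the donor's;
* post-transplant timepoints contract richness (multipliers < 1) and add
  growing numbers of pathologically expanded spike clones; ``gvhd_mode``
  adds hyperexpanded (> 100 templates) clones at the last timepoint;
* a minority of clonotype keys carry pathology-category labels (including a
  CMV subset), from which a matching specificity reference is built.

Clonotype keys are random CDR3-like strings (C...F, length 8-20) drawn from
a keyspace large enough (> 10^12) that accidental collisions are negligible.
All randomness derives from ``master_seed`` via per-sample hashed seeds, so
a cohort is byte-reproducible and adding a sample never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClonotypeTable
from .normalization import sample_seed
from .specificity import SpecificityEntry, SpecificityReference

AA = "ACDEFGHIKLMNPQRSTVWY"
CATEGORY_DISEASES = {
    "pathogen": "InfluenzaA",
    "cancer": "Melanoma",
    "autoimmune": "T1D",
    "allergy": "Pollen",
}


class SimulationError(ValueError):
    pass


@dataclass
class SyntheticCohortConfig:
    """Cohort-level simulation settings (defaults emulate the study design)."""

    n_hc: int = 12
    n_pairs: int = 8
    depth_min: int = 5000
    depth_max: int = 100_000
    alpha: float = 2.5  # clone-size power-law exponent
    max_clone_size: int = 30  # baseline law cap; larger clones only via spikes
    richness: int | None = None  # fixed per-sample richness; None -> emergent
    public_pool_size: int | None = None  # None -> public_rate * expected richness
    public_rate: float = 0.009
    carryover_fraction: float = 0.025
    carryover_rank_corr: float = 0.7
    timepoints: tuple[str, ...] = ("d30", "d100", "d180")
    richness_multipliers: tuple[float, ...] = (0.9, 0.85, 0.8)
    n_spikes: tuple[int, ...] = (20, 30, 50)
    spike_size_range: tuple[int, int] = (15, 45)
    gvhd_mode: bool = False
    n_hyper_spikes: int = 10
    hyper_size_range: tuple[int, int] = (120, 300)
    category_label_rates: dict = field(
        default_factory=lambda: {
            "pathogen": 0.02,
            "cancer": 0.005,
            "autoimmune": 0.004,
            "allergy": 0.002,
        }
    )
    cmv_rate: float = 0.01
    n_decoys: int = 200
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise SimulationError("power-law exponent alpha must exceed 1")
        if not (0 <= self.public_rate <= 1 and 0 <= self.carryover_fraction <= 1):
            raise SimulationError("rates must lie in [0, 1]")
        if any(not 0 <= r <= 1 for r in self.category_label_rates.values()):
            raise SimulationError("category label rates must lie in [0, 1]")
        if self.depth_min > self.depth_max:
            raise SimulationError("depth_min must be <= depth_max")
        if self.richness is not None and self.richness > self.depth_min:
            raise SimulationError(
                f"richness {self.richness} infeasible for depth >= {self.depth_min}"
            )
        if len(self.richness_multipliers) != len(self.timepoints) or len(
            self.n_spikes
        ) != len(self.timepoints):
            raise SimulationError("per-timepoint settings must match timepoints")


# ---------------------------------------------------------------------------
# clone-size law

def powerlaw_pmf(alpha: float, kmax: int) -> np.ndarray:
    """pmf of the truncated discrete power law P(k) ∝ k^-alpha, k = 1..kmax."""
    k = np.arange(1, kmax + 1, dtype=float)
    w = k**-alpha
    return w / w.sum()


def mean_clone_size(alpha: float, kmax: int) -> float:
    p = powerlaw_pmf(alpha, kmax)
    return float((np.arange(1, kmax + 1) * p).sum())


def expected_richness(depth: int, alpha: float, kmax: int) -> int:
    """Expected number of clonotypes when filling ``depth`` templates."""
    return max(1, int(round(depth / mean_clone_size(alpha, kmax))))


def _draw_sizes(rng: np.random.Generator, n: int, pmf: np.ndarray) -> np.ndarray:
    return rng.choice(len(pmf), size=n, p=pmf) + 1


def _sizes_to_depth(
    rng: np.random.Generator, depth: int, pmf: np.ndarray
) -> np.ndarray:
    """Draw i.i.d. power-law sizes until they fill ``depth`` templates exactly.

    Only the final clone is trimmed, so the drawn sizes follow the stated law.
    """
    mean = float((np.arange(1, len(pmf) + 1) * pmf).sum())
    sizes: list[np.ndarray] = []
    total = 0
    while total < depth:
        n = max(32, int((depth - total) / mean * 1.1))
        batch = _draw_sizes(rng, n, pmf)
        cum = total + np.cumsum(batch)
        if cum[-1] >= depth:
            cut = int(np.searchsorted(cum, depth))
            batch = batch[: cut + 1]
            batch[-1] -= int(cum[cut] - depth)
            if batch[-1] == 0:
                batch = batch[:-1]
            sizes.append(batch)
            total = depth
        else:
            sizes.append(batch)
            total = int(cum[-1])
    return np.concatenate(sizes).astype("int64")


# ---------------------------------------------------------------------------
# keys

def random_cdr3_keys(rng: np.random.Generator, n: int, existing: set[str] | None = None) -> list[str]:
    """Distinct CDR3-like keys: 'C' + 6-18 random residues + 'F'."""
    existing = set(existing or ())
    keys: list[str] = []
    seen = set(existing)
    while len(keys) < n:
        m = n - len(keys)
        lengths = rng.integers(6, 19, size=m)
        flat = rng.choice(list(AA), size=int(lengths.sum()))
        pos = 0
        for ln in lengths:
            k = "C" + "".join(flat[pos : pos + ln]) + "F"
            pos += ln
            if k not in seen:
                seen.add(k)
                keys.append(k)
    return keys


def _rank_correlated_sizes(
    donor_sizes: np.ndarray,
    fresh_sizes: np.ndarray,
    corr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reorder ``fresh_sizes`` so their ranks correlate with ``donor_sizes``.

    Gaussian-copula style: a latent score mixes the donor ranks with noise at
    weight ``corr``; sorted fresh sizes are assigned by score order.
    """
    n = len(donor_sizes)
    ranks = stats.rankdata(donor_sizes, method="average")
    z = (ranks - ranks.mean()) / (ranks.std() or 1.0)
    score = corr * z + np.sqrt(max(0.0, 1 - corr**2)) * rng.standard_normal(n)
    out = np.empty(n, dtype="int64")
    out[np.argsort(score)] = np.sort(fresh_sizes)
    return out


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class PairGroundTruth:
    pair_id: str
    carryover_keys: dict[str, list[str]]  # timepoint -> keys inherited from donor
    spike_keys: dict[str, list[str]]  # timepoint -> pathological spike keys
    hyper_keys: dict[str, list[str]]  # timepoint -> hyperexpanded spike keys


@dataclass
class CohortGroundTruth:
    public_keys: list[str]
    labels: dict[str, list[tuple[str, str]]]  # key -> [(category, disease)]
    pairs: dict[str, PairGroundTruth] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "public_keys": sorted(self.public_keys),
            "labels": {k: [list(t) for t in v] for k, v in sorted(self.labels.items())},
            "pairs": {pid: asdict(p) for pid, p in sorted(self.pairs.items())},
        }


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    healthy_controls: list[ClonotypeTable]
    donors: list[ClonotypeTable]
    recipients: dict[str, dict[str, ClonotypeTable]]  # pair_id -> timepoint -> table
    pre_transplant: dict[str, ClonotypeTable]  # pair_id -> pre-HCT recipient sample
    pairing: pd.DataFrame  # recipient_id, donor_id, timepoint
    ground_truth: CohortGroundTruth
    reference: SpecificityReference

    def all_tables(self) -> list[ClonotypeTable]:
        out = list(self.healthy_controls) + list(self.donors)
        out += list(self.pre_transplant.values())
        for tps in self.recipients.values():
            out.extend(tps.values())
        return out

    def reference_tables(self) -> list[ClonotypeTable]:
        """Healthy controls + donors: the normal-repertoire benchmark."""
        return list(self.healthy_controls) + list(self.donors)


def _public_pool(config: SyntheticCohortConfig) -> list[str]:
    rng = np.random.default_rng(sample_seed(config.master_seed, "public_pool"))
    if config.public_pool_size is not None:
        size = config.public_pool_size
    else:
        r_ref = config.richness or expected_richness(
            config.depth_min, config.alpha, config.max_clone_size
        )
        size = int(round(config.public_rate * r_ref))
    return random_cdr3_keys(rng, size)


def generate_repertoire(
    config: SyntheticCohortConfig,
    role: str,
    seed: int,
    sample_id: str | None = None,
    public_pool: list[str] | None = None,
    depth: int | None = None,
) -> ClonotypeTable:
    """One baseline repertoire (healthy control, donor, or pre-HCT recipient).

    Sizes fill the target depth exactly; the public pool replaces the same
    number of de-novo keys, so the pool appears (entirely) in every sample.
    """
    rng = np.random.default_rng(seed)
    pmf = powerlaw_pmf(config.alpha, config.max_clone_size)
    if public_pool is None:
        public_pool = _public_pool(config)
    if depth is None:
        depth = int(rng.integers(config.depth_min, config.depth_max + 1))
    if config.richness is not None:
        sizes = _draw_sizes(rng, config.richness, pmf)
    else:
        sizes = _sizes_to_depth(rng, depth, pmf)
    r = len(sizes)
    n_pub = min(len(public_pool), r)
    keys = list(public_pool[:n_pub]) + random_cdr3_keys(
        rng, r - n_pub, existing=set(public_pool)
    )
    rng.shuffle(sizes)  # pool keys get law-distributed sizes, not the largest
    counts = pd.Series(sizes, index=keys, dtype="int64")
    return ClonotypeTable(
        sample_id=sample_id or f"{role}_{seed}", counts=counts, group=role
    )


def _adjust_to_depth(
    counts: np.ndarray, protected: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Nudge unprotected clone counts so the total hits ``target`` exactly.

    Removal takes single templates from unprotected clones proportionally to
    their excess over 1 (dropping unprotected singletons only as a last
    resort); addition is size-proportional (preferential attachment), which
    preserves the heavy tail.  Returns counts with zeros marking dropped clones.
    """
    counts = counts.copy()
    free = ~protected
    total = int(counts.sum())
    while total > target:
        excess = np.where(free, np.maximum(counts - 1, 0), 0).astype(float)
        if excess.sum() == 0:
            singles = np.flatnonzero(free & (counts == 1))
            if len(singles) == 0:
                raise SimulationError("cannot reach target depth: all mass protected")
            n_drop = min(total - target, len(singles))
            drop = rng.choice(singles, size=n_drop, replace=False)
            counts[drop] = 0
            total -= n_drop
            continue
        step = min(total - target, int(excess.sum()))
        taken = rng.multinomial(step, excess / excess.sum())
        taken = np.minimum(taken, np.maximum(counts - 1, 0))
        counts -= taken
        total -= int(taken.sum())
    while total < target:
        weights = np.where(free, counts, 0).astype(float)
        if weights.sum() == 0:
            raise SimulationError("cannot reach target depth: no unprotected clones")
        add = rng.multinomial(target - total, weights / weights.sum())
        counts += add
        total += int(add.sum())
    return counts


def generate_pair_with_timepoints(
    config: SyntheticCohortConfig,
    pair_id: str,
    public_pool: list[str] | None = None,
) -> tuple[ClonotypeTable, ClonotypeTable, dict[str, ClonotypeTable], PairGroundTruth]:
    """A donor, a pre-HCT recipient sample, and post-HCT recipient timepoints.

    Each timepoint's repertoire mixes donor carry-over keys (sizes
    rank-correlated with the donor's), the public pool, fresh de-novo
    clones, and labeled pathological spike clones; ``gvhd_mode`` adds
    hyperexpanded spikes at the final timepoint.
    """
    if public_pool is None:
        public_pool = _public_pool(config)
    pool_set = set(public_pool)
    pmf = powerlaw_pmf(config.alpha, config.max_clone_size)
    fixed_depth = config.depth_min == config.depth_max

    donor = generate_repertoire(
        config,
        "donor",
        sample_seed(config.master_seed, f"{pair_id}:donor"),
        sample_id=f"{pair_id}_donor",
        public_pool=public_pool,
    )
    pre = generate_repertoire(
        config,
        "recipient_pre",
        sample_seed(config.master_seed, f"{pair_id}:pre"),
        sample_id=f"{pair_id}_pre",
        public_pool=public_pool,
    )

    donor_private = donor.counts.drop(
        [k for k in donor.counts.index if k in pool_set]
    )
    truth = PairGroundTruth(pair_id, {}, {}, {})
    timepoint_tables: dict[str, ClonotypeTable] = {}
    is_last = len(config.timepoints) - 1

    for i, tp in enumerate(config.timepoints):
        rng = np.random.default_rng(
            sample_seed(config.master_seed, f"{pair_id}:{tp}")
        )
        if config.richness is not None:
            r_base = config.richness
        else:
            base_depth = (
                config.depth_min
                if fixed_depth
                else int(rng.integers(config.depth_min, config.depth_max + 1))
            )
            r_base = expected_richness(base_depth, config.alpha, config.max_clone_size)
        r_t = max(1, int(round(r_base * config.richness_multipliers[i])))

        n_spike = config.n_spikes[i]
        n_hyper = (
            config.n_hyper_spikes if (config.gvhd_mode and i == is_last) else 0
        )
        n_pub = min(len(public_pool), r_t)
        n_carry = int(round(config.carryover_fraction * r_t))
        n_carry = min(n_carry, len(donor_private))
        if config.carryover_fraction > 0 and n_carry < 1:
            logging.getLogger(__name__).warning(
                "%s %s: carry-over fraction yields < 1 clonotype; none carried",
                pair_id,
                tp,
            )
        n_denovo = r_t - n_pub - n_carry - n_spike - n_hyper
        if config.carryover_fraction >= 1:
            n_denovo = 0  # full carry-over: no de-novo clones, richness emerges
        if n_denovo < 0:
            raise SimulationError(
                f"{pair_id} {tp}: richness {r_t} too small for pool+carry+spikes"
            )

        carry_keys = list(
            rng.choice(donor_private.index.to_numpy(), size=n_carry, replace=False)
        )
        carry_sizes = _rank_correlated_sizes(
            donor_private.loc[carry_keys].to_numpy("int64"),
            _draw_sizes(rng, n_carry, pmf),
            config.carryover_rank_corr,
            rng,
        ) if n_carry else np.array([], dtype="int64")

        existing = pool_set | set(donor.counts.index) | set(carry_keys)
        denovo_keys = random_cdr3_keys(rng, n_denovo, existing=existing)
        spike_keys = random_cdr3_keys(
            rng, n_spike, existing=existing | set(denovo_keys)
        )
        hyper_keys = random_cdr3_keys(
            rng, n_hyper, existing=existing | set(denovo_keys) | set(spike_keys)
        )

        keys = (
            list(public_pool[:n_pub]) + carry_keys + denovo_keys + spike_keys + hyper_keys
        )
        pub_sizes = _draw_sizes(rng, n_pub, pmf)
        denovo_sizes = _draw_sizes(rng, n_denovo, pmf)
        spike_sizes = rng.integers(
            config.spike_size_range[0], config.spike_size_range[1] + 1, size=n_spike
        )
        hyper_sizes = rng.integers(
            config.hyper_size_range[0], config.hyper_size_range[1] + 1, size=n_hyper
        )
        sizes = np.concatenate(
            [pub_sizes, carry_sizes, denovo_sizes, spike_sizes, hyper_sizes]
        ).astype("int64")

        if fixed_depth and n_denovo > 0:
            protected = np.zeros(len(sizes), dtype=bool)
            protected[: n_pub + n_carry] = True  # keep overlap ground truth intact
            protected[n_pub + n_carry + n_denovo :] = True  # and spike sizes
            sizes = _adjust_to_depth(sizes, protected, config.depth_min, rng)
            keep = sizes > 0
            keys = [k for k, ok in zip(keys, keep) if ok]
            sizes = sizes[keep]

        table = ClonotypeTable(
            sample_id=f"{pair_id}_{tp}",
            counts=pd.Series(sizes, index=keys, dtype="int64"),
            group=f"recipient_{tp}",
        )
        timepoint_tables[tp] = table
        truth.carryover_keys[tp] = sorted(carry_keys)
        truth.spike_keys[tp] = sorted(spike_keys)
        truth.hyper_keys[tp] = sorted(hyper_keys)

    return donor, pre, timepoint_tables, truth


def _assign_labels(
    config: SyntheticCohortConfig, keys: list[str]
) -> dict[str, list[tuple[str, str]]]:
    rng = np.random.default_rng(sample_seed(config.master_seed, "labels"))
    labels: dict[str, list[tuple[str, str]]] = {}
    keys = sorted(keys)
    for category, rate in config.category_label_rates.items():
        if rate <= 0:
            continue
        hit = rng.random(len(keys)) < rate
        for k in np.asarray(keys, dtype=object)[hit]:
            labels.setdefault(k, []).append((category, CATEGORY_DISEASES[category]))
    if config.cmv_rate > 0:
        hit = rng.random(len(keys)) < config.cmv_rate
        for k in np.asarray(keys, dtype=object)[hit]:
            labels.setdefault(k, []).append(("pathogen", "CMV"))
    return labels


def generate_reference_db(
    config: SyntheticCohortConfig,
    labels: dict[str, list[tuple[str, str]]],
    cohort_keys: set[str],
) -> SpecificityReference:
    """Specificity reference containing exactly the labeled keys plus decoys."""
    ref = SpecificityReference()
    for key, entries in labels.items():
        for category, disease in entries:
            ref.add(
                key,
                SpecificityEntry(
                    epitope=f"EP_{disease}",
                    antigen_source=disease,
                    category=category,
                    disease_label=disease,
                    provenance="synthetic_db",
                ),
            )
    rng = np.random.default_rng(sample_seed(config.master_seed, "decoys"))
    for key in random_cdr3_keys(rng, config.n_decoys, existing=cohort_keys):
        ref.add(
            key,
            SpecificityEntry(
                epitope="EP_DECOY",
                antigen_source="decoy",
                category="other",
                disease_label="decoy",
                provenance="synthetic_db",
            ),
        )
    return ref


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Full cohort: healthy controls, donor/recipient pairs, labels, reference."""
    pool = _public_pool(config)
    hcs = [
        generate_repertoire(
            config,
            "healthy_control",
            sample_seed(config.master_seed, f"hc{i:03d}"),
            sample_id=f"hc{i:03d}",
            public_pool=pool,
        )
        for i in range(config.n_hc)
    ]
    donors: list[ClonotypeTable] = []
    recipients: dict[str, dict[str, ClonotypeTable]] = {}
    pres: dict[str, ClonotypeTable] = {}
    truth = CohortGroundTruth(public_keys=list(pool), labels={})
    pairing_rows = []
    for j in range(config.n_pairs):
        pair_id = f"pair{j:03d}"
        donor, pre, tps, pair_truth = generate_pair_with_timepoints(
            config, pair_id, public_pool=pool
        )
        donors.append(donor)
        pres[pair_id] = pre
        recipients[pair_id] = tps
        truth.pairs[pair_id] = pair_truth
        for tp in config.timepoints:
            pairing_rows.append(
                {
                    "recipient_id": f"{pair_id}_{tp}",
                    "donor_id": donor.sample_id,
                    "timepoint": tp,
                }
            )
    pairing = pd.DataFrame(
        pairing_rows, columns=["recipient_id", "donor_id", "timepoint"]
    )
    all_keys: set[str] = set()
    tables = hcs + donors + list(pres.values())
    for tps in recipients.values():
        tables += list(tps.values())
    for t in tables:
        all_keys.update(t.counts.index)
    truth.labels = _assign_labels(config, sorted(all_keys))
    reference = generate_reference_db(config, truth.labels, all_keys)
    return SyntheticCohort(
        config=config,
        healthy_controls=hcs,
        donors=donors,
        recipients=recipients,
        pre_transplant=pres,
        pairing=pairing,
        ground_truth=truth,
        reference=reference,
    )
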