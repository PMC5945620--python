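"""Associations between signature activity and recurrent driver mutations.

Recurrent driver mutations are mapped to their causal channel; candidate
signatures are those whose causal-channel frequency is above the average of
the signatures active in the cancer type; carrier versus non-carrier
exposure differences are tested with a one-sided rank-sum test under
Benjamini-Hochberg FDR control; detection power is estimated by simulating
carrier assignment from the per-sample channel probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .channels import Channel, MutationRecord
from .exposures import ExposureVector, SignatureCatalog

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriverMutationKey:
    """A recurrent driver DNA change in one cancer type."""

    cancer_type: str
    gene: str
    chromosome: str
    position: int
    ref: str
    alt: str
    causal_channel: Channel
    recurrence: int
    protein_change: str = ""

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.chromosome}:{self.position}:{self.ref}>{self.alt}"


@dataclass
class AssociationResult:
    mutation: DriverMutationKey
    signature: str
    n_carriers: int
    n_noncarriers: int
    p_value: float
    direction: str  # "carrier_higher" or "carrier_lower"
    enriched: bool = True
    q_value: float = float("nan")
    significant: bool = False


@dataclass
class PowerEstimate:
    mutation_label: str
    signature: str
    alpha: float
    m: int
    n_set: int
    iterations: int
    power: float


def find_recurrent(
    driver_records: Sequence[MutationRecord], min_count: int = 4
) -> list[DriverMutationKey]:
    """Driver DNA changes occurring at least ``min_count`` times within a
    cancer type, keyed by (cancer type, gene, chrom, pos, ref, alt)."""
    groups: dict[tuple, list[MutationRecord]] = {}
    for r in driver_records:
        key = (r.cancer_type, r.gene, r.chromosome, r.position, r.ref_allele, r.alt_allele)
        groups.setdefault(key, []).append(r)
    out = []
    for (ctype, gene, chrom, pos, ref, alt), recs in groups.items():
        if len(recs) >= min_count:
            out.append(
                DriverMutationKey(
                    cancer_type=ctype,
                    gene=gene,
                    chromosome=chrom,
                    position=pos,
                    ref=ref,
                    alt=alt,
                    causal_channel=recs[0].channel,
                    recurrence=len(recs),
                )
            )
    out.sort(key=lambda k: (-k.recurrence, k.cancer_type, k.label))
    return out


def enriched_signatures(
    channel: Channel,
    catalog: SignatureCatalog,
    active: Sequence[str],
    exposure_weights: Mapping[str, float] | None = None,
) -> list[str]:
    """Active signatures whose probability of ``channel`` is strictly above
    the average over the active signatures.

    By default the unweighted mean across active signatures is used; pass
    ``exposure_weights`` (signature -> weight) for an exposure-weighted mean.
    """
    if not active:
        raise ValueError("active signature set must be non-empty")
    col = np.array([catalog.probs[catalog.index_of(n), channel.index] for n in active])
    if exposure_weights is None:
        mean = col.mean()
    else:
        w = np.array([exposure_weights.get(n, 0.0) for n in active], dtype=float)
        if w.sum() <= 0:
            mean = col.mean()
        else:
            mean = float(col @ (w / w.sum()))
    return [n for n, p in zip(active, col) if p > mean]


def test_association(
    carrier_exposures: Sequence[float], noncarrier_exposures: Sequence[float]
) -> float:
    """One-sided rank-sum p-value for carriers having stochastically larger
    exposure (Mann-Whitney U, alternative = greater).

    Exact null distribution when both groups have <= 20 tie-free samples,
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(carrier_exposures, dtype=float)
    y = np.asarray(noncarrier_exposures, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both carrier and non-carrier groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # fully tied: no evidence of carrier-higher
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= 20 and len(y) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def bh_fdr(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    flags, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, flags


def enrichment_direction_contrast(
    results: Sequence[AssociationResult], alpha: float = 0.05
) -> tuple[float, tuple]:
    """Fisher exact test helper: does significance associate with causal-channel
    enrichment? Returns (p, 2x2 table) over (enriched, significant)."""
    table = np.zeros((2, 2), dtype=int)
    for r in results:
        table[int(r.enriched), int(r.significant)] += 1
    _, p = fisher_exact(table)
    return float(p), tuple(map(tuple, table))


# ---------------------------------------------------------------------------
# Power simulation
# ---------------------------------------------------------------------------

def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, m: int
) -> np.ndarray:
    """Sequential weighted draws without replacement, renormalising after
    each draw. Isolated so the selection scheme can be substituted."""
    w = weights.astype(float).copy()
    chosen = np.empty(m, dtype=int)
    for k in range(m):
        total = w.sum()
        if total <= 0:
            raise ValueError("weights exhausted before m draws")
        chosen[k] = rng.choice(len(w), p=w / total)
        w[chosen[k]] = 0.0
    return chosen


def estimate_power(
    exposures: Sequence[ExposureVector],
    catalog: SignatureCatalog,
    mutation_channel: Channel,
    m: int,
    signature: str,
    alpha: float = 0.05,
    n_set: int = 10,
    iterations: int = 200,
    seed: int = 0,
    mutation_label: str = "",
) -> PowerEstimate:
    """Simulated power to detect a signature association for a mutation
    occurring ``m`` times.

    Per iteration: draw ``n_set - 1`` decoy causal channels uniformly from
    the 95 others; compute per-sample probabilities that the focal mutation
    occurred rather than a decoy (channel probabilities under the sample's
    exposure mixture, normalised over the set); select ``m`` carriers by
    weighted sampling without replacement; run the one-sided rank-sum test.
    Power is the fraction of iterations with p < alpha (p <= alpha at the
    alpha = 1.0 boundary).
    """
    from .selection import channel_probability  # deferred: avoids module cycle

    if m < 1 or m > len(exposures):
        raise ValueError("m must lie in [1, cohort size]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    sig_exposures = np.array([e.exposure_of(signature) for e in exposures])
    p_focal = np.array(
        [channel_probability(e, catalog, mutation_channel) for e in exposures]
    )
    other_channels = np.array(
        [c for c in range(96) if c != mutation_channel.index]
    )
    # per-sample mixture probability for every channel, for decoy lookups
    mix = np.array([e.exposure for e in exposures]) @ catalog.probs  # (n, 96)

    hits = 0
    skipped = 0
    for _ in range(iterations):
        decoys = rng.choice(other_channels, size=n_set - 1, replace=False)
        denom = p_focal + mix[:, decoys].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(denom > 0, p_focal / denom, 0.0)
        if p_i.sum() <= 0:
            skipped += 1
            logger.warning("power iteration skipped: all per-sample probabilities zero")
            continue
        carriers = _weighted_sample_without_replacement(rng, p_i, m)
        mask = np.zeros(len(exposures), dtype=bool)
        mask[carriers] = True
        p = test_association(sig_exposures[mask], sig_exposures[~mask])
        if (p < alpha) or (alpha >= 1.0 and p <= alpha):
            hits += 1
    done = iterations - skipped
    if done == 0:
        raise RuntimeError("all power iterations were skipped")
    return PowerEstimate(
        mutation_label=mutation_label,
        signature=signature,
        alpha=alpha,
        m=m,
        n_set=n_set,
        iterations=done,
        power=hits / done,
    )


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def run_association_scan(
    driver_records: Sequence[MutationRecord],
    exposures: Sequence[ExposureVector],
    catalog: SignatureCatalog,
    active_by_type: Mapping[str, Sequence[str]],
    min_recurrence: int = 4,
    min_mutations: int = 20,
    alpha: float = 0.05,
    restrict_to_enriched: bool = True,
    per_type_fdr: bool = False,
) -> list[AssociationResult]:
    """Scan every cancer type × recurrent driver mutation × candidate
    signature for carrier/non-carrier exposure differences.

    Samples below the mutation-count cutoff are excluded before testing. One
    result per test; BH is applied over the whole scan (or per cancer type
    with ``per_type_fdr``); results are sorted by q-value.
    """
    cohort = [e for e in exposures if not e.below_cutoff and not e.flagged]
    n_excluded = len(exposures) - len(cohort)
    if n_excluded:
        logger.info(
            "excluded %d sample(s) below the %d-mutation cutoff",
            n_excluded, min_mutations,
        )
    by_type: dict[str, list[ExposureVector]] = {}
    for e in cohort:
        by_type.setdefault(e.cancer_type, []).append(e)

    recurrent = find_recurrent(driver_records, min_count=min_recurrence)
    carrier_sets: dict[tuple, set[str]] = {}
    for r in driver_records:
        key = (r.cancer_type, r.gene, r.chromosome, r.position, r.ref_allele, r.alt_allele)
        carrier_sets.setdefault(key, set()).add(r.sample_id)

    results: list[AssociationResult] = []
    for mut in recurrent:
        samples = by_type.get(mut.cancer_type, [])
        if not samples:
            continue
        active = list(active_by_type.get(mut.cancer_type, catalog.names))
        if not active:
            continue
        enriched = set(
            enriched_signatures(mut.causal_channel, catalog, active)
        )
        tested = sorted(enriched) if restrict_to_enriched else list(active)
        if not tested:
            continue
        key = (mut.cancer_type, mut.gene, mut.chromosome, mut.position, mut.ref, mut.alt)
        carrier_ids = carrier_sets.get(key, set())
        is_carrier = np.array([e.sample_id in carrier_ids for e in samples])
        if is_carrier.all() or not is_carrier.any():
            logger.info("mutation %s: all samples in one group, skipped", mut.label)
            continue
        for sig in tested:
            expo = np.array([e.exposure_of(sig) for e in samples])
            p = test_association(expo[is_carrier], expo[~is_carrier])
            med_c = float(np.median(expo[is_carrier]))
            med_n = float(np.median(expo[~is_carrier]))
            results.append(
                AssociationResult(
                    mutation=mut,
                    signature=sig,
                    n_carriers=int(is_carrier.sum()),
                    n_noncarriers=int((~is_carrier).sum()),
                    p_value=p,
                    direction="carrier_higher" if med_c >= med_n else "carrier_lower",
                    enriched=sig in enriched,
                )
            )

    if results:
        if per_type_fdr:
            for ctype in {r.mutation.cancer_type for r in results}:
                sub = [r for r in results if r.mutation.cancer_type == ctype]
                qvals, flags = bh_fdr([r.p_value for r in sub], alpha=alpha)
                for r, qv, fl in zip(sub, qvals, flags):
                    r.q_value, r.significant = float(qv), bool(fl)
        else:
            qvals, flags = bh_fdr([r.p_value for r in results], alpha=alpha)
            for r, qv, fl in zip(results, qvals, flags):
                r.q_value, r.significant = float(qv), bool(fl)
        results.sort(key=lambda r: r.q_value)
    return results
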