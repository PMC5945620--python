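"""Differential selection between driver mutations.

Implements the quantitative framework linking mutation rates, cancer
incidence and relative risk; per-sample causal-channel probabilities under a
fitted signature mixture; the exact Poisson binomial two-tailed test for
whether two mutations' observed frequencies match their relative occurrence
probabilities; maximum-likelihood estimation of the relative risk with
bootstrap confidence intervals; and the variance-explained regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import linregress

from .association import bh_fdr
from .channels import Channel, MutationRecord
from .exposures import ExposureVector, SignatureCatalog

logger = logging.getLogger(__name__)

#: log-r search bounds for the MLE; boundary hits are reported as censored.
LOG_R_BOUND = 12.0


@dataclass
class CancerInitiationModel:
    """Multistage initiation model: mutations accrue at constant low yearly
    rates and each complete mutation sequence converts to cancer at its own
    low rate."""

    mutation_rates: Mapping[str, float]  # per-year rate per mutation label
    sequences: list[list[str]]  # ordered mutation labels, all same length
    cancer_rates: list[float]  # per-year conversion rate per sequence

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.cancer_rates):
            raise ValueError("one cancer rate per sequence required")
        if not self.sequences:
            raise ValueError("at least one sequence required")
        n = len(self.sequences[0])
        if any(len(s) != n for s in self.sequences):
            raise ValueError("all sequences must have the same length")
        if any(u <= 0 for u in self.mutation_rates.values()):
            raise ValueError("mutation rates must be positive")
        if any(lam <= 0 for lam in self.cancer_rates):
            raise ValueError("cancer rates must be positive")
        for seq in self.sequences:
            for m in seq:
                if m not in self.mutation_rates:
                    raise ValueError(f"no rate for mutation {m!r}")

    @property
    def n(self) -> int:
        return len(self.sequences[0])


def expected_incidence(model: CancerInitiationModel, t: float) -> float:
    """Probability of cancer incidence by time ``t`` (years).

    I(t) = sum_j u_1(j)···u_n(j) · λ_j · t^n / n!, valid when all rates
    times t are small.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    n = model.n
    total = 0.0
    for seq, lam in zip(model.sequences, model.cancer_rates):
        prod = lam
        for m in seq:
            prod *= model.mutation_rates[m]
        total += prod
    return total * t**n / math.factorial(n)


def conditional_probability(u1: float, u2: float, r: float) -> float:
    """P(M1 | M1 or M2) for mutations with rates u1, u2 and relative risk r
    of M1 versus M2: u1·r / (u1·r + u2)."""
    if u1 <= 0 or u2 <= 0:
        raise ValueError("rates must be positive")
    if r <= 0:
        raise ValueError("relative risk must be positive")
    return u1 * r / (u1 * r + u2)


def channel_probability(
    exposure: ExposureVector, catalog: SignatureCatalog, channel: Channel
) -> float:
    """Probability of ``channel`` under the sample's signature mixture:
    sum_k exposure_k · probs[k, channel]."""
    expo = exposure.exposure
    total = expo.sum()
    if total == 0 and exposure.flagged:
        return 0.0
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"exposure for sample {exposure.sample_id} is not normalised")
    if exposure.signature_names != catalog.names:
        expo = np.array(
            [expo[exposure.signature_names.index(n)] for n in catalog.names]
        )
    return float(expo @ catalog.probs[:, channel.index])


# ---------------------------------------------------------------------------
# Poisson binomial
# ---------------------------------------------------------------------------

def poibin_pmf(q: Sequence[float]) -> np.ndarray:
    """Exact Poisson binomial PMF over 0..len(q) successes.

    Computed by iterative convolution (dynamic programme); sums to 1 within
    1e-12.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 1:
        raise ValueError("q must be one-dimensional")
    if ((q < 0) | (q > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(len(q) + 1)
    pmf[0] = 1.0
    for i, qi in enumerate(q):
        # in-place convolution with (1-qi, qi), high index first
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - qi) + pmf[0 : i + 1] * qi
        pmf[0] *= 1 - qi
    return pmf


def poibin_two_tailed_test(
    q: Sequence[float], m1: int, method: str = "min_likelihood"
) -> float:
    """Two-tailed p-value for observing ``m1`` successes under Poibin(q).

    ``min_likelihood`` (default) sums the probabilities of all outcomes no
    more likely than the observed one (with a 1+1e-9 relative tolerance for
    float ties); ``double_tail`` doubles the smaller tail, capped at 1.
    """
    q = np.asarray(q, dtype=float)
    if not 0 <= m1 <= len(q):
        raise ValueError(f"m1 ({m1}) out of range [0, {len(q)}]")
    pmf = poibin_pmf(q)
    if method == "min_likelihood":
        p = float(pmf[pmf <= pmf[m1] * (1 + 1e-9)].sum())
    elif method == "double_tail":
        lower = float(pmf[: m1 + 1].sum())
        upper = float(pmf[m1:].sum())
        p = 2 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Comparable-sample selection and relative-risk MLE
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceProbabilities:
    """Per-sample causal-channel probabilities for a mutation pair."""

    sample_id: str
    p1: float
    p2: float
    carries_m1: bool

    @property
    def q(self) -> float:
        """P(M1 | M1 or M2) under equal risk: p1 / (p1 + p2)."""
        return self.p1 / (self.p1 + self.p2)

    def q_model(self, r: float) -> float:
        """P(M1 | M1 or M2) under relative risk r: r·p1 / (r·p1 + p2)."""
        return r * self.p1 / (r * self.p1 + self.p2)


@dataclass
class RelativeRisk:
    """MLE of the relative risk of M1 versus M2 with bootstrap CI.

    ``censored`` marks boundary estimates (e.g. no M2 carriers), where the
    likelihood is monotone and the reported value is a bound, not an
    estimate; the open CI side is NaN.
    """

    m1_label: str
    m2_label: str
    r: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    censored: str = ""  # "", "right", or "left"


def select_comparable_samples(
    carriers_m1: set[str],
    carriers_m2: set[str],
    other_carriers: set[str],
    channel_probs: Mapping[str, tuple[float, float]],
) -> list[OccurrenceProbabilities]:
    """Samples carrying exactly one of M1/M2 and no other mutation in the
    comparison set, with their causal-channel probabilities.

    ``channel_probs`` maps sample_id -> (p1, p2); samples with p1 + p2 = 0
    are excluded with a warning.
    """
    included: list[OccurrenceProbabilities] = []
    for sample_id, (p1, p2) in channel_probs.items():
        in1 = sample_id in carriers_m1
        in2 = sample_id in carriers_m2
        if in1 == in2:  # neither, or both
            continue
        if sample_id in other_carriers:
            continue
        if p1 + p2 <= 0:
            logger.warning(
                "sample %s excluded: zero probability for both causal channels",
                sample_id,
            )
            continue
        included.append(OccurrenceProbabilities(sample_id, p1, p2, carries_m1=in1))
    return included


def _neg_log_likelihood(log_r: float, p1: np.ndarray, p2: np.ndarray, y: np.ndarray) -> float:
    r = math.exp(log_r)
    q = r * p1 / (r * p1 + p2)
    eps = 1e-300
    return -float(np.sum(np.where(y, np.log(q + eps), np.log(1 - q + eps))))


def _mle_log_r(samples: Sequence[OccurrenceProbabilities]) -> float:
    p1 = np.array([s.p1 for s in samples])
    p2 = np.array([s.p2 for s in samples])
    y = np.array([s.carries_m1 for s in samples])
    if y.all():
        return LOG_R_BOUND
    if not y.any():
        return -LOG_R_BOUND
    res = minimize_scalar(
        _neg_log_likelihood,
        bounds=(-LOG_R_BOUND, LOG_R_BOUND),
        args=(p1, p2, y),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def fit_relative_risk(
    samples: Sequence[OccurrenceProbabilities],
    m1_label: str = "M1",
    m2_label: str = "M2",
    bootstrap_iters: int = 100,
    seed: int = 0,
) -> RelativeRisk:
    """Maximum-likelihood relative risk of M1 versus M2.

    Maximises L = prod_{i in I1} q_i(r) · prod_{i in I2} (1 - q_i(r)) over
    log r in [-12, 12] by bounded scalar optimisation. Bootstrap resamples
    whole samples with replacement and reports 2.5/97.5 percentile bounds.
    One-sided carrier sets give a censored boundary result.
    """
    if not samples:
        raise ValueError("at least one comparable sample required")
    y = np.array([s.carries_m1 for s in samples])
    if y.all():
        logger.info("all carriers are %s: right-censored estimate", m1_label)
        return RelativeRisk(
            m1_label, m2_label, r=math.exp(LOG_R_BOUND), censored="right"
        )
    if not y.any():
        logger.info("all carriers are %s: left-censored estimate", m2_label)
        return RelativeRisk(
            m1_label, m2_label, r=math.exp(-LOG_R_BOUND), censored="left"
        )

    log_r = _mle_log_r(samples)
    ci_low = ci_high = float("nan")
    if bootstrap_iters > 0:
        rng = np.random.default_rng(seed)
        n = len(samples)
        boot = []
        for _ in range(bootstrap_iters):
            idx = rng.integers(0, n, size=n)
            boot.append(_mle_log_r([samples[i] for i in idx]))
        lo, hi = np.percentile(boot, [2.5, 97.5])
        ci_low, ci_high = math.exp(lo), math.exp(hi)
    return RelativeRisk(
        m1_label, m2_label, r=math.exp(log_r), ci_low=ci_low, ci_high=ci_high
    )


# ---------------------------------------------------------------------------
# Pairwise scan
# ---------------------------------------------------------------------------

@dataclass
class SelectionTestResult:
    """One pairwise differential-selection test."""

    cancer_type: str
    m1_label: str
    m2_label: str
    n_included: int
    m1_count: int
    m2_count: int
    q: np.ndarray
    p_two_tailed: float
    relative_risk: RelativeRisk
    q_value: float = float("nan")
    significant: bool = False


def _common_mutations(
    driver_records: Sequence[MutationRecord],
    genes: Sequence[str],
    cancer_type: str,
    common_fraction: float,
) -> dict[str, list[MutationRecord]]:
    """Mutations in ``genes`` exceeding ``common_fraction`` of the gene set's
    non-synonymous mutations in the cancer type, keyed by DNA-change label."""
    gene_set = set(genes)
    in_scope = [
        r
        for r in driver_records
        if r.cancer_type == cancer_type and r.gene in gene_set
    ]
    total = len(in_scope)
    by_change: dict[str, list[MutationRecord]] = {}
    for r in in_scope:
        label = f"{r.gene}:{r.chromosome}:{r.position}:{r.ref_allele}>{r.alt_allele}"
        by_change.setdefault(label, []).append(r)
    return {
        label: recs
        for label, recs in by_change.items()
        if total > 0 and len(recs) / total > common_fraction
    }


def pairwise_selection_scan(
    driver_records: Sequence[MutationRecord],
    exposures: Sequence[ExposureVector],
    catalog: SignatureCatalog,
    genes: Sequence[str],
    cancer_type: str,
    common_fraction: float = 0.01,
    min_occurrence: int = 10,
    fdr: float = 0.05,
    bootstrap_iters: int = 100,
    seed: int = 0,
    two_sided_method: str = "min_likelihood",
) -> list[SelectionTestResult]:
    """Test every unordered pair of common driver mutations in a gene set
    for differential selection.

    Common mutations are those above ``common_fraction`` of the gene set's
    non-synonymous mutations in the cancer type; the scan runs only if they
    total at least ``min_occurrence`` occurrences. For each pair, comparable
    samples are those carrying exactly one of the pair and no other common
    mutation in the set; the Poisson binomial two-tailed test and the
    relative-risk MLE are computed, and BH FDR is applied over all pairs.
    """
    common = _common_mutations(driver_records, genes, cancer_type, common_fraction)
    total_common = sum(len(v) for v in common.values())
    if not common or total_common < min_occurrence:
        logger.info(
            "no qualifying mutations in %s (common total %d < %d)",
            cancer_type, total_common, min_occurrence,
        )
        return []

    cohort = {
        e.sample_id: e
        for e in exposures
        if not e.below_cutoff and not e.flagged
    }
    carriers: dict[str, set[str]] = {
        label: {r.sample_id for r in recs} & set(cohort)
        for label, recs in common.items()
    }
    channels: dict[str, Channel] = {
        label: recs[0].channel for label, recs in common.items()
    }
    # cache per-sample channel probabilities per mutation label
    probs: dict[str, dict[str, float]] = {
        label: {
            sid: channel_probability(e, catalog, channels[label])
            for sid, e in cohort.items()
        }
        for label in common
    }

    labels = sorted(common)
    results: list[SelectionTestResult] = []
    rng = np.random.default_rng(seed)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            l1, l2 = labels[i], labels[j]
            others = set().union(
                *(carriers[l] for l in labels if l not in (l1, l2))
            )
            pair_probs = {
                sid: (probs[l1][sid], probs[l2][sid]) for sid in cohort
            }
            included = select_comparable_samples(
                carriers[l1], carriers[l2], others, pair_probs
            )
            if not included:
                logger.info("pair %s vs %s: no comparable samples", l1, l2)
                continue
            m1 = sum(s.carries_m1 for s in included)
            m2 = len(included) - m1
            qvec = np.array([s.q for s in included])
            p = poibin_two_tailed_test(qvec, m1, method=two_sided_method)
            rr = fit_relative_risk(
                included,
                m1_label=l1,
                m2_label=l2,
                bootstrap_iters=bootstrap_iters,
                seed=int(rng.integers(2**31)),
            )
            results.append(
                SelectionTestResult(
                    cancer_type=cancer_type,
                    m1_label=l1,
                    m2_label=l2,
                    n_included=len(included),
                    m1_count=m1,
                    m2_count=m2,
                    q=qvec,
                    p_two_tailed=p,
                    relative_risk=rr,
                )
            )
    if results:
        qvals, flags = bh_fdr([r.p_two_tailed for r in results], alpha=fdr)
        for res, qv, fl in zip(results, qvals, flags):
            res.q_value = float(qv)
            res.significant = bool(fl)
        results.sort(key=lambda r: r.q_value)
    return results


def variance_explained(
    frequencies: Sequence[float], mean_probabilities: Sequence[float]
) -> tuple[float, float]:
    """OLS of mutation frequency on mean occurrence probability.

    Returns (R², slope sign as the correlation direction). Requires at
    least 3 mutations and non-constant probabilities.
    """
    freq = np.asarray(frequencies, dtype=float)
    prob = np.asarray(mean_probabilities, dtype=float)
    if len(freq) < 3 or len(freq) != len(prob):
        raise ValueError("need >= 3 (frequency, probability) pairs")
    if np.ptp(prob) == 0:
        raise ValueError("zero variance in probabilities: R² undefined")
    fit = linregress(prob, freq)
    return float(fit.rvalue**2), float(np.sign(fit.slope))
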