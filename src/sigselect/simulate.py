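"""Synthetic cohort generation with known ground truth.

Cohorts are generated under the same statistical model the analysis
assumes: per-sample exposures drawn from a Dirichlet prior over the active
signatures, per-sample mutation burdens (fixed or negative binomial),
channel counts drawn from the exposure-weighted multinomial mixture, and
driver mutations planted with probability proportional to relative risk
times the per-sample causal-channel probability — the multi-mutation
generalisation of the conditional occurrence probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .channels import CHANNEL_LABELS, COMPLEMENT, Channel, MutationRecord, revcomp
from .exposures import SignatureCatalog

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriverSpec:
    """One plantable driver mutation with its causal channel and risk."""

    label: str
    channel: Channel
    gene: str
    relative_risk: float = 1.0
    protein_change: str = ""

    def __post_init__(self) -> None:
        if self.relative_risk <= 0:
            raise ValueError("relative risk must be positive")


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_samples: int
    catalog: SignatureCatalog
    cancer_type: str = "SYNTH"
    burden_mean: float = 200.0
    burden_dispersion: float | None = 1.0  # None -> fixed burden
    exposure_alpha: Sequence[float] | float = 1.0  # Dirichlet concentration(s)
    drivers: list[DriverSpec] = field(default_factory=list)
    drivers_per_sample: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.burden_mean < 0:
            raise ValueError("burden_mean must be >= 0")
        alpha = self.alpha_vector()
        if (alpha <= 0).any():
            raise ValueError("Dirichlet concentrations must be positive")

    def alpha_vector(self) -> np.ndarray:
        if np.isscalar(self.exposure_alpha):
            return np.full(self.catalog.k, float(self.exposure_alpha))
        alpha = np.asarray(self.exposure_alpha, dtype=float)
        if len(alpha) != self.catalog.k:
            raise ValueError("exposure_alpha length must match catalog size")
        return alpha


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery tests."""

    sample_ids: list[str]
    exposures: np.ndarray  # (n_samples, K)
    signature_names: list[str]
    planted_drivers: dict[str, list[str]] = field(default_factory=dict)
    zero_burden_samples: list[str] = field(default_factory=list)

    def exposures_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.exposures, columns=self.signature_names)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def drivers_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": sid, "driver": label}
            for sid, labels in self.planted_drivers.items()
            for label in labels
        ]
        return pd.DataFrame(rows, columns=["sample_id", "driver"])


def generate_signatures(
    k: int, concentration: float = 1.0, seed: int = 0
) -> SignatureCatalog:
    """K synthetic signatures drawn from a symmetric Dirichlet over the 96
    channels. Deterministic under ``seed``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(96, concentration), size=k)
    names = [f"SynthSig{i + 1}" for i in range(k)]
    return SignatureCatalog(names=names, probs=probs)


def _record_for_channel(
    rng: np.random.Generator,
    channel_index: int,
    sample_id: str,
    cancer_type: str,
    position: int,
    gene: str = "",
    effect: str = "other",
    flip: bool | None = None,
) -> MutationRecord:
    """Materialise a record for a channel; by default the purine-strand
    representation is emitted half the time so classification is exercised
    both ways. Pass ``flip`` to pin the strand (a recurrent mutation must
    present identical alleles in every sample, as in a real MAF)."""
    label = CHANNEL_LABELS[channel_index]
    ref, alt = label[2], label[4]
    context = label[0] + ref + label[6]
    if flip is None:
        flip = rng.random() < 0.5
    if flip:
        ref, alt, context = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context)
    return MutationRecord(
        sample_id=sample_id,
        cancer_type=cancer_type,
        chromosome="1",
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        context=context,
        gene=gene,
        effect=effect,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[MutationRecord], GroundTruth]:
    """Generate passenger mutations and ground-truth exposures.

    Per sample: exposure ~ Dirichlet(alpha); burden fixed at
    ``burden_mean`` or negative binomial with the given mean/dispersion;
    channel counts ~ multinomial(burden, exposureᵀ·catalog). Passenger
    records carry an empty gene field and synthetic positions on
    chromosome 1.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = spec.alpha_vector()
    n, k = spec.n_samples, spec.catalog.k
    exposures = rng.dirichlet(alpha, size=n)
    if spec.burden_dispersion is None:
        burdens = np.full(n, int(round(spec.burden_mean)))
    else:
        # NB parameterised by mean and dispersion: var = mean + mean^2/disp
        disp = spec.burden_dispersion
        p = disp / (disp + spec.burden_mean)
        burdens = rng.negative_binomial(disp, p, size=n)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    records: list[MutationRecord] = []
    zero_burden: list[str] = []
    pos_counter = 1_000_000
    for i, sid in enumerate(sample_ids):
        if burdens[i] == 0:
            zero_burden.append(sid)
            logger.warning("sample %s drew zero mutation burden", sid)
            continue
        mixture = exposures[i] @ spec.catalog.probs
        counts = rng.multinomial(burdens[i], mixture)
        for c in np.nonzero(counts)[0]:
            for _ in range(counts[c]):
                pos_counter += 1
                records.append(
                    _record_for_channel(
                        rng, int(c), sid, spec.cancer_type, pos_counter
                    )
                )
    truth = GroundTruth(
        sample_ids=sample_ids,
        exposures=exposures,
        signature_names=list(spec.catalog.names),
        zero_burden_samples=zero_burden,
    )
    return records, truth


def plant_drivers(
    spec: CohortSpec, records: list[MutationRecord], truth: GroundTruth
) -> tuple[list[MutationRecord], GroundTruth]:
    """Add planted driver mutations on top of the passenger records.

    Driver j is chosen with probability r_j·p_ij / Σ_k r_k·p_ik, where
    p_ij is the causal-channel probability under the sample's *true*
    exposure. Driver records carry gene, protein change and a
    nonsynonymous effect; each driver label has a fixed position so carrier
    status is keyed consistently. Appending (rather than replacing a
    passenger) keeps passenger counts exactly multinomial.
    """
    if not spec.drivers:
        return records, truth
    rng = np.random.default_rng(spec.seed + 1)
    risks = np.array([d.relative_risk for d in spec.drivers])
    chan_idx = np.array([d.channel.index for d in spec.drivers])
    driver_positions = {d.label: 10_000 + j for j, d in enumerate(spec.drivers)}
    # one strand representation per driver, fixed across samples
    driver_flips = {d.label: bool(rng.random() < 0.5) for d in spec.drivers}
    out = list(records)
    for i, sid in enumerate(truth.sample_ids):
        p = truth.exposures[i] @ spec.catalog.probs[:, chan_idx]
        weights = risks * p
        total = weights.sum()
        if total <= 0:
            logger.warning("sample %s skipped: zero probability for all drivers", sid)
            continue
        for _ in range(spec.drivers_per_sample):
            j = rng.choice(len(spec.drivers), p=weights / total)
            d = spec.drivers[j]
            out.append(
                _record_for_channel(
                    rng,
                    d.channel.index,
                    sid,
                    spec.cancer_type,
                    driver_positions[d.label],
                    gene=d.gene,
                    effect="nonsynonymous_SNV",
                    flip=driver_flips[d.label],
                )
            )
            truth.planted_drivers.setdefault(sid, []).append(d.label)
    return out, truth


def simulate_cohort(spec: CohortSpec) -> tuple[list[MutationRecord], GroundTruth]:
    """generate_cohort followed by plant_drivers."""
    records, truth = generate_cohort(spec)
    return plant_drivers(spec, records, truth)
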