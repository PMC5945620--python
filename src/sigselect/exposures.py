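"""Signature exposure fitting by non-negative least squares.

A signature catalog is a K × 96 row-stochastic matrix over the trinucleotide
channels. Per-sample raw channel counts are regressed against the signatures
reported active in the sample's cancer type; the non-negative weights
("activities") are normalised to per-sample exposures. A simulation-based
calibration estimates how many mutations are needed before the true
generating signature dominates the regression weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .channels import CHANNEL_LABELS, ChannelCountMatrix

logger = logging.getLogger(__name__)


class CatalogError(ValueError):
    """Raised for malformed signature catalogs or frequency tables."""


@dataclass
class SignatureCatalog:
    """K mutational signatures over the 96 channels, rows summing to 1."""

    names: list[str]
    probs: np.ndarray  # (K, 96)
    aetiology: list[str] | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 96:
            raise CatalogError("signature matrix must be (K, 96)")
        if self.probs.shape[0] != len(self.names):
            raise CatalogError("names length does not match matrix")
        if (self.probs < 0).any():
            raise CatalogError("negative signature probabilities")
        rowsums = self.probs.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise CatalogError("signature rows must sum to 1 within 1e-9")

    @property
    def k(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise CatalogError(f"unknown signature {name!r}") from None

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        idx = [self.index_of(n) for n in names]
        aet = [self.aetiology[i] for i in idx] if self.aetiology else None
        return SignatureCatalog(list(names), self.probs[idx], aet)


def read_catalog(path: str | Path) -> SignatureCatalog:
    """Read a signature matrix TSV: first column channel labels in COSMIC
    notation (``A[C>A]A``), one column per signature. Rows may appear in any
    order; they are reindexed to the canonical channel ordering."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNEL_LABELS) - set(df.index)
    if missing:
        raise CatalogError(f"{path}: missing channel rows, e.g. {sorted(missing)[:3]}")
    df = df.loc[list(CHANNEL_LABELS)]
    probs = df.to_numpy(dtype=float).T
    # tolerate tiny rounding from text serialisation
    rowsums = probs.sum(axis=1)
    if np.allclose(rowsums, 1.0, atol=1e-6):
        probs = probs / rowsums[:, None]
    return SignatureCatalog(names=list(df.columns), probs=probs)


def load_cosmic_v2() -> SignatureCatalog:
    """The bundled 30-signature COSMIC v2 catalog."""
    with resources.as_file(
        resources.files("sigselect.data") / "cosmic_v2_signatures.tsv"
    ) as p:
        return read_catalog(p)


@dataclass
class TrinucleotideFrequencies:
    """Relative frequencies of the 32 pyrimidine-centred trinucleotides."""

    genome: dict[str, float]
    exome: dict[str, float]

    def __post_init__(self) -> None:
        for name, freq in (("genome", self.genome), ("exome", self.exome)):
            if len(freq) != 32:
                raise CatalogError(f"{name} frequencies must cover 32 trinucleotides")
            total = sum(freq.values())
            if abs(total - 1.0) > 1e-9:
                raise CatalogError(f"{name} frequencies sum to {total}, not 1")


def read_trinucleotide_frequencies(path: str | Path) -> TrinucleotideFrequencies:
    df = pd.read_csv(path, sep="\t")
    genome = dict(zip(df["trinucleotide"], df["genome"].astype(float)))
    exome = dict(zip(df["trinucleotide"], df["exome"].astype(float)))
    # renormalise to absorb rounding in the text fixture
    gs, es = sum(genome.values()), sum(exome.values())
    genome = {k: v / gs for k, v in genome.items()}
    exome = {k: v / es for k, v in exome.items()}
    return TrinucleotideFrequencies(genome=genome, exome=exome)


def load_default_frequencies() -> TrinucleotideFrequencies:
    with resources.as_file(
        resources.files("sigselect.data") / "trinucleotide_freqs.tsv"
    ) as p:
        return read_trinucleotide_frequencies(p)


def rescale_to_exome(
    catalog: SignatureCatalog, freqs: TrinucleotideFrequencies
) -> SignatureCatalog:
    """Rescale genome-derived signatures to exome trinucleotide frequencies.

    Each channel probability is multiplied by the exome/genome frequency
    ratio of its trinucleotide, then rows are renormalised to sum to 1.
    """
    ratios = np.empty(96)
    for i, label in enumerate(CHANNEL_LABELS):
        tri = label[0] + label[2] + label[6]
        g = freqs.genome.get(tri, 0.0)
        if g <= 0.0:
            raise CatalogError(f"zero/missing genome frequency for {tri}")
        e = freqs.exome.get(tri)
        if e is None:
            raise CatalogError(f"missing exome frequency for {tri}")
        ratios[i] = e / g
    probs = catalog.probs * ratios[None, :]
    probs = probs / probs.sum(axis=1, keepdims=True)
    return SignatureCatalog(list(catalog.names), probs, catalog.aetiology)


@dataclass
class ExposureVector:
    """Per-sample signature activities and normalised exposures.

    ``activity`` holds the raw NNLS weights on the mutation-count scale over
    *all* catalog signatures (zero for inactive ones); ``exposure`` is
    activity normalised to sum 1. ``flagged`` marks degenerate (all-zero)
    samples.
    """

    sample_id: str
    signature_names: list[str]
    activity: np.ndarray
    cancer_type: str = ""
    total_mutations: int = 0
    below_cutoff: bool = False
    flagged: bool = False
    residual: float = 0.0
    exposure: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if (self.activity < 0).any():
            raise ValueError("negative activity")
        total = self.activity.sum()
        self.exposure = self.activity / total if total > 0 else np.zeros_like(self.activity)

    def exposure_of(self, name: str) -> float:
        return float(self.exposure[self.signature_names.index(name)])


def fit_exposures(
    counts: ChannelCountMatrix,
    catalog: SignatureCatalog,
    active: Sequence[str] | None = None,
    min_mutations: int = 20,
) -> list[ExposureVector]:
    """Fit per-sample exposures by NNLS against the active signatures.

    NNLS is run on raw counts (not frequencies); activities are normalised
    to exposures afterwards. Inactive signatures get exposure 0. Samples
    with an all-zero count row are flagged with an all-zero exposure; samples
    below ``min_mutations`` are fitted but marked ``below_cutoff``.
    """
    if active is None:
        active = list(catalog.names)
    if len(active) == 0:
        raise CatalogError("active signature set must be non-empty")
    active_idx = [catalog.index_of(n) for n in active]
    design = catalog.probs[active_idx].T  # (96, n_active)

    out: list[ExposureVector] = []
    for i, sample_id in enumerate(counts.sample_ids):
        row = counts.counts[i].astype(float)
        total = int(row.sum())
        activity = np.zeros(catalog.k)
        flagged = False
        resid = 0.0
        if total == 0:
            flagged = True
            logger.warning("sample %s has zero mutations; exposure undefined", sample_id)
        else:
            weights, resid = nnls(design, row)
            activity[active_idx] = weights
        out.append(
            ExposureVector(
                sample_id=sample_id,
                signature_names=list(catalog.names),
                activity=activity,
                cancer_type=counts.cancer_types[i] if counts.cancer_types else "",
                total_mutations=total,
                below_cutoff=total < min_mutations,
                flagged=flagged,
                residual=float(resid),
            )
        )
    n_below = sum(e.below_cutoff for e in out)
    logger.info(
        "fit_exposures: %d samples, %d below the %d-mutation cutoff",
        len(out), n_below, min_mutations,
    )
    return out


def exposures_to_frame(exposures: Sequence[ExposureVector]) -> pd.DataFrame:
    """Tabular view: sample_id, cancer_type, one exposure column per
    signature, total mutation count and the below-cutoff flag."""
    if not exposures:
        return pd.DataFrame()
    names = exposures[0].signature_names
    rows = []
    for e in exposures:
        row = {"sample_id": e.sample_id, "cancer_type": e.cancer_type}
        row.update(dict(zip(names, e.exposure)))
        row["total_mutations"] = e.total_mutations
        row["below_cutoff"] = e.below_cutoff
        rows.append(row)
    return pd.DataFrame(rows)


def calibrate_min_mutations(
    catalog: SignatureCatalog,
    n_grid: Sequence[int],
    n_decoys: int = 14,
    success_threshold: float = 0.5,
    reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulation-based calibration of the minimum-mutation cutoff.

    For each signature and each n in ``n_grid``: draw ``reps`` multinomial
    samples of size n from the signature; regress each against the true
    signature plus ``n_decoys`` distinct randomly chosen other signatures
    (fresh per replicate); success iff the true signature's share of the
    summed weights exceeds ``success_threshold``. Returns a DataFrame of
    success proportions (index n, columns signatures) plus a ``mean`` column.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_decoys >= catalog.k:
        raise CatalogError(
            f"n_decoys ({n_decoys}) must be smaller than the catalog size ({catalog.k})"
        )
    if any(n < 1 or n > 96 for n in n_grid):
        raise ValueError("n_grid values must lie in [1, 96]")
    rng = np.random.default_rng(seed)
    others = {
        t: np.array([k for k in range(catalog.k) if k != t]) for t in range(catalog.k)
    }
    result = np.zeros((len(n_grid), catalog.k))
    for ni, n in enumerate(n_grid):
        for t in range(catalog.k):
            successes = 0
            for _ in range(reps):
                sample = rng.multinomial(n, catalog.probs[t]).astype(float)
                decoys = (
                    rng.choice(others[t], size=n_decoys, replace=False)
                    if n_decoys
                    else np.array([], dtype=int)
                )
                idx = np.concatenate(([t], decoys))
                weights, _ = nnls(catalog.probs[idx].T, sample)
                total = weights.sum()
                if total > 0 and weights[0] / total > success_threshold:
                    successes += 1
            result[ni, t] = successes / reps
    df = pd.DataFrame(result, index=list(n_grid), columns=list(catalog.names))
    df.index.name = "n_mutations"
    df["mean"] = df.mean(axis=1)
    return df
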