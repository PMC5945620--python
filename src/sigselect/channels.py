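"""Somatic SNV parsing and 96-channel trinucleotide classification.

Substitutions are classified under the pyrimidine-strand convention: a
mutation with a purine reference base is reverse-complemented so that every
channel has a C or T reference. Channels follow the canonical COSMIC
ordering: substitution classes C>A, C>G, C>T, T>A, T>C, T>G, and within each
class the 5' flank cycles A, C, G, T (major) and the 3' flank A, C, G, T
(minor).

Coordinates are 1-based inclusive (MAF convention).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Substitution classes in canonical COSMIC order.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels in canonical COSMIC order, e.g. ``A[C>A]A``.
CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTION_CLASSES
    for f5 in BASES
    for f3 in BASES
)

CHANNEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}

EFFECT_CLASSES = ("nonsynonymous_SNV", "stopgain", "stoploss", "synonymous", "other")
DRIVER_EFFECTS = frozenset({"nonsynonymous_SNV", "stopgain", "stoploss"})

_CANONICAL_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])


class MutationInputError(ValueError):
    """Raised when a record fails validation or a file lacks required columns."""


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def normalise_chromosome(chrom: str) -> str | None:
    """Strip any ``chr`` prefix; return None for non-canonical chromosomes."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "MT" or c == "M":
        return None
    c = c.upper() if c in ("x", "y") else c
    return c if c in _CANONICAL_CHROMS else None


@dataclass(frozen=True)
class Channel:
    """One of the 96 substitution channels, pyrimidine-strand representation."""

    index: int
    ref: str
    alt: str
    flank5: str
    flank3: str

    @property
    def label(self) -> str:
        return f"{self.flank5}[{self.ref}>{self.alt}]{self.flank3}"

    @property
    def context(self) -> str:
        return f"{self.flank5}{self.ref}{self.flank3}"

    @classmethod
    def from_label(cls, label: str) -> "Channel":
        try:
            index = CHANNEL_INDEX[label]
        except KeyError:
            raise MutationInputError(f"unknown channel label: {label!r}") from None
        return cls(
            index=index, ref=label[2], alt=label[4], flank5=label[0], flank3=label[6]
        )

    @classmethod
    def from_index(cls, index: int) -> "Channel":
        return cls.from_label(CHANNEL_LABELS[index])


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-base substitution.

    ``position`` is 1-based. ``context`` is the 5'→3' reference trinucleotide
    around the variant, on the strand of ``ref_allele`` (its middle base must
    equal ``ref_allele``).
    """

    sample_id: str
    cancer_type: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    context: str
    gene: str = ""
    effect: str = "other"
    variant_class_label: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise MutationInputError(
                f"invalid alleles {self.ref_allele!r}>{self.alt_allele!r} at "
                f"{self.sample_id}:{self.chromosome}:{self.position}"
            )
        if self.ref_allele == self.alt_allele:
            raise MutationInputError(
                f"ref equals alt ({self.ref_allele}) at "
                f"{self.sample_id}:{self.chromosome}:{self.position}"
            )
        if len(self.context) != 3 or any(b not in BASES for b in self.context):
            raise MutationInputError(
                f"invalid context {self.context!r} at "
                f"{self.sample_id}:{self.chromosome}:{self.position}"
            )
        if self.context[1] != self.ref_allele:
            raise MutationInputError(
                f"context middle base {self.context[1]!r} != ref "
                f"{self.ref_allele!r} at "
                f"{self.sample_id}:{self.chromosome}:{self.position}"
            )
        if self.effect not in EFFECT_CLASSES:
            raise MutationInputError(f"unknown effect class {self.effect!r}")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        """Identity key used for exclusion matching."""
        return (
            self.sample_id,
            self.chromosome,
            self.position,
            self.ref_allele,
            self.alt_allele,
        )

    @property
    def channel(self) -> Channel:
        return classify_channel(self.ref_allele, self.alt_allele, self.context)


def classify_channel(ref: str, alt: str, context: str) -> Channel:
    """Map a substitution to its pyrimidine-strand channel.

    Purine-reference mutations are reverse-complemented: ref and alt are
    complemented and the context is reverse-complemented.
    """
    if ref not in BASES or alt not in BASES or ref == alt:
        raise MutationInputError(f"invalid substitution {ref!r}>{alt!r}")
    if len(context) != 3 or any(b not in BASES for b in context):
        raise MutationInputError(f"invalid context {context!r}")
    if context[1] != ref:
        raise MutationInputError(
            f"context {context!r} middle base does not match ref {ref!r}"
        )
    if ref not in PYRIMIDINES:
        ref, alt, context = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return Channel.from_label(label)


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

#: Column mappings per dialect: ours -> theirs.
DIALECT_COLUMNS: dict[str, dict[str, str]] = {
    "generic": {
        "sample_id": "sample_id",
        "cancer_type": "cancer_type",
        "chrom": "chrom",
        "pos": "pos",
        "ref": "ref",
        "alt": "alt",
        "context": "context",
        "gene": "gene",
        "effect": "effect",
    },
    "tcga": {
        "sample_id": "Tumor_Sample_Barcode",
        "cancer_type": "cancer_type",
        "chrom": "Chromosome",
        "pos": "Start_Position",
        "ref": "Reference_Allele",
        "alt": "Tumor_Seq_Allele2",
        "context": "context",
        "gene": "Hugo_Symbol",
        "effect": "effect",
        "variant_class": "Variant_Type",
    },
    "icgc": {
        "sample_id": "icgc_sample_id",
        "cancer_type": "cancer_type",
        "chrom": "chromosome",
        "pos": "chromosome_start",
        "ref": "reference_genome_allele",
        "alt": "mutated_to_allele",
        "context": "context",
        "gene": "gene_affected",
        "effect": "effect",
        "variant_class": "mutation_type",
    },
}

#: Variant-class label kept per dialect (generic keeps any valid SNV).
_SNV_LABELS = {"tcga": "SNP", "icgc": "single base substitution"}

_OPTIONAL_COLUMNS = ("gene", "effect", "cancer_type")


def read_mutations(
    path: str | Path,
    dialect: str = "generic",
    columns: dict[str, str] | None = None,
) -> list[MutationRecord]:
    """Read somatic SNVs from a tab-separated table.

    Only single-base substitutions are retained (``SNP`` label for the tcga
    dialect, ``single base substitution`` for icgc, any valid SNV for
    generic); records on non-canonical chromosomes are dropped. Unparseable
    rows are skipped with a logged count. Column names can be overridden via
    ``columns`` (our field name -> file column name).
    """
    if dialect not in DIALECT_COLUMNS:
        raise MutationInputError(f"unknown dialect {dialect!r}")
    colmap = dict(DIALECT_COLUMNS[dialect])
    if columns:
        colmap.update(columns)

    records: list[MutationRecord] = []
    n_skipped = 0
    n_label_filtered = 0
    n_chrom_dropped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        required = [
            colmap[k]
            for k in ("sample_id", "chrom", "pos", "ref", "alt", "context")
        ]
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise MutationInputError(
                f"{path}: missing required column(s) {missing} for dialect "
                f"{dialect!r}"
            )
        has = {k: colmap.get(k) in reader.fieldnames for k in colmap}
        snv_label = _SNV_LABELS.get(dialect)
        for row in reader:
            label = row.get(colmap.get("variant_class", ""), "")
            if snv_label is not None and has.get("variant_class"):
                # hyphen/space variants of the ICGC label are equivalent
                if label.strip().lower().replace("-", " ") != snv_label.lower():
                    n_label_filtered += 1
                    continue
            chrom = normalise_chromosome(row[colmap["chrom"]])
            if chrom is None:
                n_chrom_dropped += 1
                continue
            try:
                rec = MutationRecord(
                    sample_id=row[colmap["sample_id"]],
                    cancer_type=row.get(colmap["cancer_type"], "") if has["cancer_type"] else "",
                    chromosome=chrom,
                    position=int(row[colmap["pos"]]),
                    ref_allele=row[colmap["ref"]].strip().upper(),
                    alt_allele=row[colmap["alt"]].strip().upper(),
                    context=row[colmap["context"]].strip().upper(),
                    gene=row.get(colmap["gene"], "") if has["gene"] else "",
                    effect=(row.get(colmap["effect"]) or "other") if has["effect"] else "other",
                    variant_class_label=label,
                )
            except (MutationInputError, KeyError, ValueError) as exc:
                n_skipped += 1
                logger.warning("skipping unparseable row in %s: %s", path, exc)
                continue
            records.append(rec)
    if n_skipped:
        logger.warning("%s: skipped %d unparseable row(s)", path, n_skipped)
    if n_label_filtered:
        logger.info("%s: filtered %d non-SNV row(s) by label", path, n_label_filtered)
    if n_chrom_dropped:
        logger.info(
            "%s: dropped %d row(s) on non-canonical chromosomes", path, n_chrom_dropped
        )
    _log_duplicates(records)
    return records


def _log_duplicates(records: Sequence[MutationRecord]) -> None:
    # Duplicates (e.g. ICGC/TCGA overlap) are kept, only counted.
    seen: set[tuple] = set()
    dups = 0
    for rec in records:
        if rec.key in seen:
            dups += 1
        seen.add(rec.key)
    if dups:
        logger.info("kept %d duplicate record(s) (same sample/position/alleles)", dups)


GENERIC_COLUMNS = (
    "sample_id",
    "cancer_type",
    "chrom",
    "pos",
    "ref",
    "alt",
    "context",
    "gene",
    "effect",
)


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as a generic-dialect TSV (round-trips with read_mutations)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENERIC_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.cancer_type,
                    r.chromosome,
                    r.position,
                    r.ref_allele,
                    r.alt_allele,
                    r.context,
                    r.gene,
                    r.effect,
                ]
            )


def filter_driver_nonsynonymous(
    records: Iterable[MutationRecord], driver_genes: Iterable[str]
) -> list[MutationRecord]:
    """Retain non-synonymous/stopgain/stoploss records in driver genes.

    Input order is preserved.
    """
    genes = set(driver_genes)
    return [r for r in records if r.gene in genes and r.effect in DRIVER_EFFECTS]


def read_driver_genes(path: str | Path) -> set[str]:
    """Read a driver gene list, one symbol per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


@dataclass
class ChannelCountMatrix:
    """Per-sample counts over the 96 channels."""

    sample_ids: list[str]
    counts: np.ndarray  # (n_samples, 96) int
    cancer_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 96:
            raise ValueError("counts must be (n_samples, 96)")
        if self.counts.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match counts")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def total_per_sample(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]


def count_channels(
    records: Sequence[MutationRecord],
    exclude: Sequence[MutationRecord] = (),
) -> ChannelCountMatrix:
    """Build the samples × 96 channel count matrix.

    Records matching an entry of ``exclude`` on (sample, chromosome,
    position, ref, alt) are removed before counting; samples whose records
    are all excluded keep an all-zero row.
    """
    excluded_keys = {r.key for r in exclude}
    order: dict[str, int] = {}
    ctypes: dict[str, str] = {}
    for rec in records:
        if rec.sample_id not in order:
            order[rec.sample_id] = len(order)
            ctypes[rec.sample_id] = rec.cancer_type
    counts = np.zeros((len(order), 96), dtype=np.int64)
    n_excluded = 0
    for rec in records:
        if rec.key in excluded_keys:
            n_excluded += 1
            continue
        counts[order[rec.sample_id], rec.channel.index] += 1
    if n_excluded:
        logger.info("count_channels: excluded %d record(s)", n_excluded)
    sample_ids = list(order)
    return ChannelCountMatrix(
        sample_ids=sample_ids,
        counts=counts,
        cancer_types=[ctypes[s] for s in sample_ids],
    )
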