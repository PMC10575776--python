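"""Shared domain types.

Coordinate conventions: CNV and exon intervals are BED-style 0-based
half-open; SNV/coding-variant positions are VCF-style 1-based. Conversions
happen only in the I/O layer (:mod:`triocog.cohort_io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InheritanceClass(str, enum.Enum):
    """Per-trio inheritance class of a variant (exactly one per variant)."""

    DE_NOVO = "de_novo"
    TRANSMITTED = "transmitted"
    NON_TRANSMITTED = "non_transmitted"
    ABSENT = "absent"
    MENDELIAN_ERROR = "mendelian_error"
    FILTERED = "filtered"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class TrioGenotype:
    """One member's genotype and QC fields at one site.

    ``dosage`` is the alt-allele count (0/1/2) or ``None`` when missing.
    ``allele_balance`` is the alternative-allele read fraction; it is only
    meaningful when ``depth > 0``.
    """

    role: str  # proband | father | mother
    dosage: int | None
    depth: int = 0
    gq: float = 0.0
    allele_balance: float = float("nan")


@dataclass
class AnnotatedVariant:
    """Functional annotation of a rare coding variant."""

    gene: str
    consequence: str  # frameshift|stop_gain|splice_donor|splice_acceptor|missense|other
    cadd: float
    mpc: float | None = None
    parent_allele_count: int = 0
    reference_allele_count: int = 0


@dataclass
class CodingVariantCall:
    """One rare coding variant observed in one trio."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    fid: str
    annotation: AnnotatedVariant
    genotypes: dict[str, TrioGenotype] = field(default_factory=dict)
    inheritance: InheritanceClass | None = None


@dataclass
class CnvCall:
    """One copy-number variant call for one individual.

    ``start``/``end`` are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    cnv_type: str  # del | dup
    probes: int
    sample_id: str
    fid: str
    role: str
    inheritance: InheritanceClass | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneSets:
    """Gene-set membership plus exon intervals.

    ``lofi``: loss-of-function-intolerant genes (pLI > 0.9 in real data);
    ``dd``: monoallelic developmental-disorder genes. ``exons`` has columns
    chrom/start/end/gene, BED half-open.
    """

    lofi: frozenset[str]
    dd: frozenset[str]
    exons: pd.DataFrame

    def members(self, which: str) -> frozenset[str]:
        if which == "lofi":
            return self.lofi
        if which == "dd":
            return self.dd
        raise ValueError(f"unknown gene set {which!r}")

    @property
    def known_genes(self) -> frozenset[str]:
        if not hasattr(self, "_known"):
            self._known = frozenset(self.exons["gene"]) | self.lofi | self.dd
        return self._known


@dataclass
class SnpPanel:
    """Per-individual alt-allele dosages for common biallelic SNPs.

    ``dosages`` is float (n_samples, n_snps) with NaN for missing calls;
    ``snps`` has columns snp/chrom/pos/a1/a2 (a1 = effect/alt allele whose
    copies are counted) and optionally maf.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def rows(self, sample_ids: list[str]) -> np.ndarray:
        idx = [self._sample_index[s] for s in sample_ids]
        return self.dosages[idx]


@dataclass
class RegressionResult:
    """Fitted logistic-regression summary (one row per predictor)."""

    params: pd.Series
    se: pd.Series
    p: pd.Series
    conf_int: pd.DataFrame  # columns: low, high (beta scale)
    loglik: float
    loglik_null: float
    converged: bool
    n_used: int
    method: str  # firth | ml

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def or_conf_int(self) -> pd.DataFrame:
        return np.exp(self.conf_int)


@dataclass
class BinomialCI:
    """Exact (Clopper-Pearson) binomial proportion interval."""

    k: int
    n: int
    estimate: float
    lower: float
    upper: float
    level: float = 0.95
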