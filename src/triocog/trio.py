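"""Trio genotype QC and inheritance classification.

Implements the trio-level genotype filters (depth, genotype quality and
allele-balance thresholds applied to every member of a carrier trio), the
de novo / transmitted / non-transmitted classification of single-nucleotide
and copy-number variants, the per-SNP pseudo-control dosage used to build
non-transmitted polygenic scores, and the cohort-wide Mendelian-consistency
screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from triocog.types import CnvCall, InheritanceClass, SnpPanel, TrioGenotype

# QC thresholds for trio genotypes at carrier sites.
MIN_DEPTH = 10
MIN_GQ = 30
HET_AB_RANGE = (0.2, 0.8)
HOM_ALT_MIN_AB = 0.9
HOM_REF_MAX_AB = 0.1


def _member_passes(g: TrioGenotype) -> bool:
    if g.dosage is None:
        return False
    if g.depth < MIN_DEPTH or g.gq < MIN_GQ:
        return False
    ab = g.allele_balance
    if not np.isfinite(ab):
        return False
    if g.dosage == 1:
        return HET_AB_RANGE[0] <= ab <= HET_AB_RANGE[1]
    if g.dosage == 2:
        return ab >= HOM_ALT_MIN_AB
    return ab <= HOM_REF_MAX_AB


def pass_genotype_filters(trio: dict[str, TrioGenotype]) -> bool:
    """True iff every trio member passes depth/GQ/allele-balance thresholds.

    The thresholds are: depth >= 10, GQ >= 30, het allele balance in
    [0.2, 0.8], hom-alt balance >= 0.9, hom-ref balance <= 0.1. They are
    applied to all three members of any trio in which at least one member
    carries the variant.
    """
    for role in ("proband", "father", "mother"):
        if role not in trio:
            raise ValueError(f"trio is missing member {role!r}")
    return all(_member_passes(trio[r]) for r in ("proband", "father", "mother"))


# Possible offspring dosages given one parent's dosage.
_TRANSMISSIBLE = {0: {0}, 1: {0, 1}, 2: {1}}


def mendelian_consistent(proband: int, father: int, mother: int) -> bool:
    """Whether the proband dosage is reachable from the parents at a
    biallelic site (ignoring mutation)."""
    return any(
        proband == a + b
        for a in _TRANSMISSIBLE[father]
        for b in _TRANSMISSIBLE[mother]
    )


def classify_snv(
    proband: int | None, father: int | None, mother: int | None
) -> InheritanceClass:
    """Classify one variant in one trio from the three alt-allele dosages.

    Proband carrier with both parents non-carriers is de novo; otherwise a
    Mendelian-impossible triple (e.g. hom-alt parent with non-carrier
    proband) is a Mendelian error; proband carrier with a carrier parent is
    transmitted; parent-only carriage is non-transmitted; no carriers means
    absent. Missing dosages yield ``filtered``.
    """
    if proband is None or father is None or mother is None:
        return InheritanceClass.FILTERED
    if proband > 0 and father == 0 and mother == 0:
        return InheritanceClass.DE_NOVO
    if not mendelian_consistent(proband, father, mother):
        return InheritanceClass.MENDELIAN_ERROR
    if proband > 0:
        return InheritanceClass.TRANSMITTED
    if father > 0 or mother > 0:
        return InheritanceClass.NON_TRANSMITTED
    return InheritanceClass.ABSENT


def pseudo_control_dosage(
    father: float | None, mother: float | None, proband: float | None
):
    """Non-transmitted alt-allele count: father + mother - proband.

    This is the phase-free dosage of the pseudo-control assembled from the
    four non-transmitted parental alleles. Returns ``None`` for missing
    input and raises for a Mendelian-inconsistent triple (result outside
    {0,1,2}).
    """
    if father is None or mother is None or proband is None:
        return None
    d = father + mother - proband
    if d < 0 or d > 2:
        raise ValueError(
            f"Mendelian error: pseudo-control dosage {d} from "
            f"(father={father}, mother={mother}, proband={proband})"
        )
    return d


def pseudo_control_matrix(
    proband: np.ndarray, father: np.ndarray, mother: np.ndarray
) -> np.ndarray:
    """Vectorised pseudo-control dosages with Mendelian masking.

    Entries where the triple is inconsistent (result outside [0, 2]) or any
    member is missing are set to NaN, mirroring the per-trio masking policy
    for common SNPs (the SNP is dropped for that trio only).
    """
    nt = father + mother - proband
    bad = ~((nt >= 0) & (nt <= 2))
    nt = nt.astype(float)
    nt[bad] = np.nan
    return nt


def _overlaps(a: CnvCall, b: CnvCall) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def classify_cnv(
    proband_cnvs: list[CnvCall],
    father_cnvs: list[CnvCall],
    mother_cnvs: list[CnvCall],
) -> list[tuple[CnvCall, InheritanceClass]]:
    """Classify a trio's CNVs by interval overlap.

    A proband CNV with any (>= 1 bp) same-type overlap with a parental CNV
    is transmitted, otherwise de novo. A parental CNV with no same-type
    overlap with any proband CNV is non-transmitted. Requiring matching type
    reflects that a deletion cannot transmit as a duplication.
    """
    for c in proband_cnvs + father_cnvs + mother_cnvs:
        if c.end <= c.start:
            raise ValueError(f"malformed CNV interval [{c.start}, {c.end})")
    parental = father_cnvs + mother_cnvs
    out: list[tuple[CnvCall, InheritanceClass]] = []
    for c in proband_cnvs:
        hit = any(_overlaps(c, p) and c.cnv_type == p.cnv_type for p in parental)
        out.append(
            (c, InheritanceClass.TRANSMITTED if hit else InheritanceClass.DE_NOVO)
        )
    for p in parental:
        hit = any(_overlaps(c, p) and c.cnv_type == p.cnv_type for c in proband_cnvs)
        if not hit:
            out.append((p, InheritanceClass.NON_TRANSMITTED))
    return out


def _consistency_table() -> np.ndarray:
    """27-entry lookup: consistent[p, f, m] for dosages in {0,1,2}."""
    t = np.zeros((3, 3, 3), dtype=bool)
    for p in range(3):
        for f in range(3):
            for m in range(3):
                t[p, f, m] = mendelian_consistent(p, f, m)
    return t


_CONSISTENT = _consistency_table()


def mendelian_screen(
    panel: SnpPanel, trios: pd.DataFrame, threshold: float = 0.90
) -> dict:
    """Cohort-wide Mendelian consistency rates for a common-SNP panel.

    Returns per-SNP and per-trio consistency rates (fraction of non-missing
    trio x SNP genotype triples reachable under Mendelian inheritance) and
    flags entries below ``threshold`` (default 0.90). Missing genotypes are
    excluded from the denominators.
    """
    if len(panel.snps) == 0:
        raise ValueError("empty SNP panel")
    pro = panel.rows(list(trios["proband"]))
    fat = panel.rows(list(trios["father"]))
    mot = panel.rows(list(trios["mother"]))
    ok_mask = np.isfinite(pro) & np.isfinite(fat) & np.isfinite(mot)
    p = np.where(ok_mask, pro, 0).astype(int)
    f = np.where(ok_mask, fat, 0).astype(int)
    m = np.where(ok_mask, mot, 0).astype(int)
    consistent = _CONSISTENT[p, f, m] & ok_mask

    with np.errstate(invalid="ignore"):
        snp_rate = consistent.sum(axis=0) / ok_mask.sum(axis=0)
        trio_rate = consistent.sum(axis=1) / ok_mask.sum(axis=1)
    snp_rates = pd.Series(snp_rate, index=panel.snps["snp"].to_numpy())
    trio_rates = pd.Series(trio_rate, index=trios["fid"].to_numpy())
    return {
        "snp_rates": snp_rates,
        "trio_rates": trio_rates,
        "flagged_snps": snp_rates.index[snp_rates < threshold].tolist(),
        "flagged_trios": trio_rates.index[trio_rates < threshold].tolist(),
        "consistent_mask": consistent,
        "informative_mask": ok_mask,
    }
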