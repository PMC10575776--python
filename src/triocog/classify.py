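"""Damaging-variant prioritisation, ultra-rare filtering, CNV filters,
gene-set membership, and the 12-category burden matrix.

Six mutation classes (damaging de novo / transmitted / non-transmitted
coding variants; de novo / transmitted / non-transmitted CNVs) are counted
in each of two gene sets (loss-of-function-intolerant genes and the
developmental-disorder subset), giving twelve burden categories per proband.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from triocog.types import (
    AnnotatedVariant,
    CnvCall,
    CodingVariantCall,
    GeneSets,
    InheritanceClass,
)

log = logging.getLogger(__name__)

PTV_CONSEQUENCES = frozenset({"frameshift", "stop_gain", "splice_donor", "splice_acceptor"})
CADD_DAMAGING = 20.0
MPC_DAMAGING = 1.0

# Minimum sizes: 15 kb for de novo CNVs, 100 kb for transmitted and
# non-transmitted CNVs (the latter lack independent validation).
CNV_MIN_LENGTH_DENOVO = 15_000
CNV_MIN_LENGTH_INHERITED = 100_000
CNV_MIN_PROBES = 15
CNV_MAX_FREQ = 0.01
CNV_MAX_SEGDUP_OVERLAP = 0.5

MUTATION_CLASSES = ("dn_coding", "trans_coding", "nt_coding", "dn_cnv", "trans_cnv", "nt_cnv")
GENE_SET_NAMES = ("lofi", "dd")
BURDEN_CATEGORIES = tuple(f"{c}_{s}" for c in MUTATION_CLASSES for s in GENE_SET_NAMES)

_CODING_CLASS = {
    InheritanceClass.DE_NOVO: "dn_coding",
    InheritanceClass.TRANSMITTED: "trans_coding",
    InheritanceClass.NON_TRANSMITTED: "nt_coding",
}
_CNV_CLASS = {
    InheritanceClass.DE_NOVO: "dn_cnv",
    InheritanceClass.TRANSMITTED: "trans_cnv",
    InheritanceClass.NON_TRANSMITTED: "nt_cnv",
}


def is_damaging_ptv(v: AnnotatedVariant) -> bool:
    """Damaging protein-truncating variant: any frameshift, or a stop-gain /
    splice donor / splice acceptor variant with scaled CADD >= 20."""
    if v.consequence == "frameshift":
        return True
    if v.consequence in ("stop_gain", "splice_donor", "splice_acceptor"):
        if v.cadd is None or not np.isfinite(v.cadd):
            log.warning("missing CADD for %s at %s; treated as non-damaging", v.consequence, v.gene)
            return False
        return v.cadd >= CADD_DAMAGING
    return False


def is_damaging_missense(v: AnnotatedVariant) -> bool:
    """Damaging missense variant: MPC >= 1 and scaled CADD >= 20."""
    if v.consequence != "missense":
        return False
    if v.mpc is None or not np.isfinite(v.mpc):
        log.warning("missing MPC for missense variant in %s; treated as non-damaging", v.gene)
        return False
    return v.mpc >= MPC_DAMAGING and v.cadd >= CADD_DAMAGING


def is_damaging(v: AnnotatedVariant) -> bool:
    """Damaging coding variant: damaging PTV or damaging missense."""
    return is_damaging_ptv(v) or is_damaging_missense(v)


def is_ultra_rare(v: AnnotatedVariant) -> bool:
    """Ultra-rare: the allele is seen exactly once among all cohort parents
    and is absent from the external reference panel.

    Applied to transmitted and non-transmitted analyses only; de novo
    variants bypass this filter by definition.
    """
    if v.parent_allele_count < 0 or v.reference_allele_count < 0:
        raise ValueError("allele counts must be non-negative")
    return v.parent_allele_count == 1 and v.reference_allele_count == 0


def cnv_passes_filters(
    c: CnvCall,
    cohort_freq: float,
    segdup_overlap: float,
    n_probes: int,
    inheritance: InheritanceClass,
) -> bool:
    """CNV quality filters.

    All CNVs require cohort frequency <= 1%, >= 15 probes, segmental-
    duplication overlap <= 50% of length, and length >= 15 kb; transmitted
    and non-transmitted CNVs additionally require length >= 100 kb.
    """
    if cohort_freq > CNV_MAX_FREQ:
        return False
    if n_probes < CNV_MIN_PROBES:
        return False
    if segdup_overlap > CNV_MAX_SEGDUP_OVERLAP:
        return False
    min_len = (
        CNV_MIN_LENGTH_DENOVO
        if inheritance == InheritanceClass.DE_NOVO
        else CNV_MIN_LENGTH_INHERITED
    )
    return c.length >= min_len


def variant_in_set(v: CodingVariantCall | AnnotatedVariant, sets: GeneSets, which: str) -> bool:
    """Whether a coding variant's gene belongs to the given gene set."""
    gene = v.gene if isinstance(v, AnnotatedVariant) else v.annotation.gene
    if gene not in sets.known_genes:
        log.warning("unknown gene symbol %r", gene)
        return False
    return gene in sets.members(which)


def cnv_in_set(c: CnvCall, sets: GeneSets, which: str) -> bool:
    """Whether a CNV overlaps (>= 1 bp) any exon of any gene in the set."""
    members = sets.members(which)
    ex = sets.exons
    hit = (
        (ex["chrom"] == c.chrom)
        & (ex["start"] < c.end)
        & (c.start < ex["end"])
        & ex["gene"].isin(members)
    )
    return bool(hit.any())


def cnv_cohort_frequencies(cnvs: list[CnvCall], n_individuals: int) -> list[float]:
    """Fraction of cohort individuals (probands and parents) carrying a
    same-type CNV overlapping each call, including the carrier itself."""
    freqs = []
    for c in cnvs:
        carriers = {
            o.sample_id
            for o in cnvs
            if o.cnv_type == c.cnv_type
            and o.chrom == c.chrom
            and o.start < c.end
            and c.start < o.end
        }
        freqs.append(len(carriers) / n_individuals)
    return freqs


def segdup_overlap_fraction(c: CnvCall, segdups: pd.DataFrame | None) -> float:
    """Fraction of the CNV length covered by segmental-duplication intervals."""
    if segdups is None or len(segdups) == 0:
        return 0.0
    sel = segdups[
        (segdups["chrom"] == c.chrom)
        & (segdups["start"] < c.end)
        & (c.start < segdups["end"])
    ]
    covered = 0
    for _, row in sel.iterrows():
        covered += min(c.end, row["end"]) - max(c.start, row["start"])
    return covered / c.length


def build_burden_matrix(
    coding_calls: list[CodingVariantCall],
    cnv_calls: list[CnvCall],
    sets: GeneSets,
    trios: pd.DataFrame,
    segdups: pd.DataFrame | None = None,
    return_support: bool = False,
):
    """Per-proband counts for the 12 rare-variant burden categories.

    Coding variants must carry an inheritance class: de novo variants are
    counted when damaging (no ultra-rare filter); transmitted and
    non-transmitted variants are counted when damaging *and* ultra-rare.
    CNVs are counted when they pass the CNV quality filters for their
    inheritance class. Counts are of variants, not genes: two qualifying
    variants in one gene both count. Rows are indexed by trio family id.

    With ``return_support`` the qualifying variant objects backing each
    cell are also returned, for audit and recount tests.
    """
    fids = trios["fid"].tolist()
    burden = pd.DataFrame(0, index=pd.Index(fids, name="fid"), columns=list(BURDEN_CATEGORIES))
    support: dict[str, list] = {c: [] for c in BURDEN_CATEGORIES}
    fid_set = set(fids)

    for call in coding_calls:
        if call.fid not in fid_set:
            raise KeyError(f"coding call for unknown trio {call.fid!r}")
        cls = _CODING_CLASS.get(call.inheritance)
        if cls is None:
            continue
        if not is_damaging(call.annotation):
            continue
        if cls != "dn_coding" and not is_ultra_rare(call.annotation):
            continue
        for s in GENE_SET_NAMES:
            if variant_in_set(call, sets, s):
                burden.loc[call.fid, f"{cls}_{s}"] += 1
                support[f"{cls}_{s}"].append(call)

    n_individuals = 3 * len(fids)
    freqs = cnv_cohort_frequencies(cnv_calls, n_individuals)
    for c, freq in zip(cnv_calls, freqs):
        cls = _CNV_CLASS.get(c.inheritance)
        if cls is None:
            continue
        if c.fid not in fid_set:
            raise KeyError(f"CNV call for unknown trio {c.fid!r}")
        sd = segdup_overlap_fraction(c, segdups)
        if not cnv_passes_filters(c, freq, sd, c.probes, c.inheritance):
            continue
        for s in GENE_SET_NAMES:
            if cnv_in_set(c, sets, s):
                burden.loc[c.fid, f"{cls}_{s}"] += 1
                support[f"{cls}_{s}"].append(c)

    if return_support:
        return burden, support
    return burden
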