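"""Synthetic proband-parent trio cohorts.

The generator produces every input the analysis consumes, with the
statistical structure the pipeline assumes: Mendelian transmission of
common alleles drawn at stated minor-allele frequencies, Poisson de novo
mutation concentrated in constrained gene sets, ultra-rare inherited
singletons transmitted with probability one half, copy-number variants on
a single pseudo-chromosome, and a liability-threshold binary phenotype.

Liability model: with z the standardised true polygenic score and D the
proband's count of damaging de novo variants in developmental-disorder
(DD) genes,

    liability = -sqrt(r2_prs) * z + dn_effect * D + s * noise,

where s^2 = max(0, 1 - r2_prs - dn_effect^2 * dn_rate_dd) keeps total
variance near 1. Liability points toward *lower* school performance, so a
higher cognition PRS protects and DD de novo variants harm. The phenotype
is 1 (lower performance) when liability exceeds the cohort quantile
threshold (median by default, giving near-balanced groups).

Randomness: one master seed; per-stage substreams are spawned as
``default_rng([seed, k])`` with fixed stage offsets k (0 common variants,
1 covariates, 2 de novo, 3 inherited singletons, 4 CNVs, 5 GWAS noise,
6 liability noise, 7 error injection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from triocog.types import (
    AnnotatedVariant,
    CnvCall,
    CodingVariantCall,
    GeneSets,
    SnpPanel,
    TrioGenotype,
)

# genome layout of the single pseudo-chromosome
CHROM = "1"
GENE_SPACING = 200_000
GENE_N_EXONS = 10
EXON_WIDTH = 200
EXON_SPACING = 5_000

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]

DAMAGING_CLASS_PROPS = {
    "frameshift": 0.35,
    "stop_gain": 0.20,
    "splice_donor": 0.075,
    "splice_acceptor": 0.075,
    "missense": 0.30,
}


@dataclass
class SynthConfig:
    """Cohort-generator configuration.

    Defaults are fixed at the study scale: 656 trios, 13 expected damaging
    DD de novo variants cohort-wide (rate 0.02/proband), 53 in LoFi-only
    genes (0.08), ~1.5 damaging ultra-rare singletons per parent in LoFi
    genes, gene sets of 300 LoFi / 72 DD genes (DD a subset of LoFi), and
    a PRS explaining 5% of liability variance.
    """

    n_trios: int = 656
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_snp_fraction: float = 0.1
    r2_prs: float = 0.05
    dn_rate_dd: float = 0.02
    dn_rate_lofi_only: float = 0.08
    dn_effect: float = 1.5
    inherited_singleton_rate: float = 1.5
    cnv_rate: float = 0.2
    n_genes_lofi: int = 300
    n_genes_dd: int = 72
    seed: int = 0
    # secondary knobs
    dn_rate_benign: float = 0.3
    inherited_nonur_rate: float = 0.3
    cnv_dn_rate: float = 0.03
    n_genes_background: int = 150
    phenotype_quantile: float = 0.5  # fraction assigned to the lower group
    gwas_noise: float = 0.3  # SD of estimation noise added to true weights
    ld_block_size: int = 1  # SNPs per LD block; 1 = independent SNPs
    ld_rho: float = 0.0  # within-block haplotype correlation
    mendelian_error_rate: float = 0.0
    qc_fail_rate: float = 0.0  # fraction of coding calls given a failing genotype
    class_props: dict = field(default_factory=lambda: dict(DAMAGING_CLASS_PROPS))

    def __post_init__(self) -> None:
        checks = {
            "n_trios": self.n_trios >= 1,
            "n_snps": self.n_snps >= 1,
            "maf_range": 0.0 < self.maf_range[0] <= self.maf_range[1] < 1.0,
            "effect_snp_fraction": 0.0 <= self.effect_snp_fraction <= 1.0,
            "r2_prs": np.isfinite(self.r2_prs) and 0.0 <= self.r2_prs <= 1.0,
            "dn_rate_dd": np.isfinite(self.dn_rate_dd) and self.dn_rate_dd >= 0,
            "dn_rate_lofi_only": self.dn_rate_lofi_only >= 0,
            "dn_effect": np.isfinite(self.dn_effect),
            "inherited_singleton_rate": self.inherited_singleton_rate >= 0,
            "cnv_rate": self.cnv_rate >= 0,
            "n_genes_dd": 0 <= self.n_genes_dd <= self.n_genes_lofi,
            "phenotype_quantile": 0.0 < self.phenotype_quantile < 1.0,
            "mendelian_error_rate": 0.0 <= self.mendelian_error_rate < 1.0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid SynthConfig field {name!r}: {getattr(self, name)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class SynthCohort:
    cfg: SynthConfig
    trios: pd.DataFrame  # fid, proband, father, mother, sex, phenotype, PC1..PC10
    snp_panel: SnpPanel
    true_weights: np.ndarray
    summary_stats: dict[str, pd.DataFrame]  # trait -> SNP/chrom/pos/a1/a2/beta/p
    coding_calls: list[CodingVariantCall]
    cnv_calls: list[CnvCall]
    gene_sets: GeneSets
    liabilities: np.ndarray
    true_prs_z: np.ndarray
    tracking: dict  # generator-truth bookkeeping (de novo and singleton counts)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


def _make_gene_sets(cfg: SynthConfig) -> GeneSets:
    n_total = cfg.n_genes_lofi + cfg.n_genes_background
    genes = [f"G{i:04d}" for i in range(n_total)]
    rows = []
    for i, g in enumerate(genes):
        gstart = 10_000 + i * GENE_SPACING
        for e in range(GENE_N_EXONS):
            s = gstart + e * EXON_SPACING
            rows.append((CHROM, s, s + EXON_WIDTH, g))
    exons = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    lofi = frozenset(genes[: cfg.n_genes_lofi])
    dd = frozenset(genes[: cfg.n_genes_dd])
    return GeneSets(lofi=lofi, dd=dd, exons=exons)


def _gene_span(gene: str) -> tuple[int, int]:
    i = int(gene[1:])
    gstart = 10_000 + i * GENE_SPACING
    return gstart, gstart + (GENE_N_EXONS - 1) * EXON_SPACING + EXON_WIDTH


def _haplotypes(rng, n_hap: int, mafs: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """0/1 haplotype matrix (n_hap, n_snps); optional block-correlated mode
    via a Gaussian copula with a shared within-block factor."""
    n_snps = len(mafs)
    if cfg.ld_block_size <= 1 or cfg.ld_rho == 0.0:
        return (rng.random((n_hap, n_snps)) < mafs).astype(np.int8)
    rho = cfg.ld_rho
    n_blocks = int(np.ceil(n_snps / cfg.ld_block_size))
    shared = np.repeat(
        rng.standard_normal((n_hap, n_blocks)), cfg.ld_block_size, axis=1
    )[:, :n_snps]
    z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n_hap, n_snps))
    return (z < sps.norm.ppf(mafs)).astype(np.int8)


def _qc_genotype(rng, role: str, dosage: int, failing: bool = False) -> TrioGenotype:
    """Genotype with QC fields; passing the trio filters unless ``failing``."""
    depth = int(rng.integers(15, 80))
    gq = float(rng.integers(35, 99))
    if dosage == 1:
        ad_alt = int(np.clip(rng.binomial(depth, 0.5), int(np.ceil(0.2 * depth)), int(0.8 * depth)))
    elif dosage == 2:
        ad_alt = int(np.clip(rng.binomial(depth, 0.98), int(np.ceil(0.9 * depth)), depth))
    else:
        ad_alt = int(np.clip(rng.binomial(depth, 0.02), 0, int(0.1 * depth)))
    if failing:
        depth = int(rng.integers(0, 10))  # fails the depth >= 10 filter
        ad_alt = min(ad_alt, depth)
    ab = ad_alt / depth if depth > 0 else float("nan")
    return TrioGenotype(role=role, dosage=dosage, depth=depth, gq=gq, allele_balance=ab)


def _sample_annotation(rng, gene: str, damaging: bool, cfg: SynthConfig) -> AnnotatedVariant:
    if damaging:
        classes = list(cfg.class_props)
        props = np.array([cfg.class_props[c] for c in classes], dtype=float)
        csq = classes[rng.choice(len(classes), p=props / props.sum())]
        if csq == "frameshift":
            cadd, mpc = float(rng.uniform(10, 40)), None
        elif csq == "missense":
            cadd, mpc = float(rng.uniform(20, 40)), float(rng.uniform(1.0, 3.0))
        else:
            cadd, mpc = float(rng.uniform(20, 45)), None
    else:
        if rng.random() < 0.5:
            csq, cadd, mpc = "missense", float(rng.uniform(0, 19.5)), float(rng.uniform(0, 0.99))
        else:
            csq, cadd, mpc = "other", float(rng.uniform(0, 10)), None
    return AnnotatedVariant(gene=gene, consequence=csq, cadd=cadd, mpc=mpc)


def _coding_call(rng, cfg, fid, gene, dosages, damaging, pac, rac) -> CodingVariantCall:
    lo, hi = _gene_span(gene)
    pos = int(rng.integers(lo + 1, hi))  # 1-based
    ref, alt = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
    ann = _sample_annotation(rng, gene, damaging, cfg)
    ann.parent_allele_count = pac
    ann.reference_allele_count = rac
    failing_member = None
    if cfg.qc_fail_rate > 0 and rng.random() < cfg.qc_fail_rate:
        failing_member = ("proband", "father", "mother")[rng.integers(3)]
    gts = {
        role: _qc_genotype(rng, role, d, failing=(role == failing_member))
        for role, d in zip(("proband", "father", "mother"), dosages)
    }
    return CodingVariantCall(
        chrom=CHROM, pos=pos, ref=ref, alt=alt, fid=fid, annotation=ann, genotypes=gts
    )


def generate_cohort(cfg: SynthConfig) -> SynthCohort:
    """Generate a complete synthetic trio cohort. Deterministic given
    ``cfg.seed``; proband common-SNP dosages are Mendelian-consistent with
    their parents by construction (before optional error injection)."""
    n = cfg.n_trios
    gene_sets = _make_gene_sets(cfg)
    genes_lofi = sorted(gene_sets.lofi)
    genes_dd = sorted(gene_sets.dd)
    genes_lofi_only = sorted(gene_sets.lofi - gene_sets.dd)
    genes_all = sorted(gene_sets.known_genes)

    # ---- common variants -------------------------------------------------
    rng_c = _rng(cfg.seed, 0)
    mafs = rng_c.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_snps)
    span = (cfg.n_genes_lofi + cfg.n_genes_background) * GENE_SPACING + 20_000
    positions = np.linspace(50_000, span, cfg.n_snps).astype(int)
    pair_idx = rng_c.integers(len(_ALLELE_PAIRS), size=cfg.n_snps)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    snps = pd.DataFrame(
        {
            "snp": [f"rs{i:06d}" for i in range(cfg.n_snps)],
            "chrom": CHROM,
            "pos": positions,
            "a1": a1,
            "a2": a2,
            "maf": mafs,
        }
    )

    fat_h1 = _haplotypes(rng_c, n, mafs, cfg)
    fat_h2 = _haplotypes(rng_c, n, mafs, cfg)
    mot_h1 = _haplotypes(rng_c, n, mafs, cfg)
    mot_h2 = _haplotypes(rng_c, n, mafs, cfg)
    pick_f = rng_c.random((n, cfg.n_snps)) < 0.5
    pick_m = rng_c.random((n, cfg.n_snps)) < 0.5
    tx_f = np.where(pick_f, fat_h1, fat_h2)
    tx_m = np.where(pick_m, mot_h1, mot_h2)
    pro_d = (tx_f + tx_m).astype(float)
    fat_d = (fat_h1 + fat_h2).astype(float)
    mot_d = (mot_h1 + mot_h2).astype(float)

    # ---- true weights and polygenic liability ---------------------------
    k = int(round(cfg.effect_snp_fraction * cfg.n_snps))
    effect_idx = rng_c.choice(cfg.n_snps, size=k, replace=False)
    w = np.zeros(cfg.n_snps)
    w[effect_idx] = rng_c.standard_normal(k)
    raw_prs = pro_d @ w
    sd = raw_prs.std()
    true_prs_z = (raw_prs - raw_prs.mean()) / sd if sd > 0 else np.zeros(n)

    # ---- pedigree and covariates ----------------------------------------
    rng_cov = _rng(cfg.seed, 1)
    fids = [f"F{i:04d}" for i in range(n)]
    trios = pd.DataFrame(
        {
            "fid": fids,
            "proband": [f"{f}-P" for f in fids],
            "father": [f"{f}-F" for f in fids],
            "mother": [f"{f}-M" for f in fids],
            "sex": rng_cov.integers(1, 3, size=n),  # 1 male, 2 female
        }
    )
    for j in range(1, 11):
        trios[f"PC{j}"] = rng_cov.standard_normal(n)

    # ---- de novo coding variants ----------------------------------------
    rng_dn = _rng(cfg.seed, 2)
    dn_dd_counts = rng_dn.poisson(cfg.dn_rate_dd, size=n)
    dn_lofi_counts = rng_dn.poisson(cfg.dn_rate_lofi_only, size=n)
    dn_benign_counts = rng_dn.poisson(cfg.dn_rate_benign, size=n)
    coding_calls: list[CodingVariantCall] = []
    for i, fid in enumerate(fids):
        for _ in range(dn_dd_counts[i]):
            g = genes_dd[rng_dn.integers(len(genes_dd))]
            coding_calls.append(_coding_call(rng_dn, cfg, fid, g, (1, 0, 0), True, 0, 0))
        for _ in range(dn_lofi_counts[i]):
            g = genes_lofi_only[rng_dn.integers(len(genes_lofi_only))]
            coding_calls.append(_coding_call(rng_dn, cfg, fid, g, (1, 0, 0), True, 0, 0))
        for _ in range(dn_benign_counts[i]):
            g = genes_all[rng_dn.integers(len(genes_all))]
            coding_calls.append(_coding_call(rng_dn, cfg, fid, g, (1, 0, 0), False, 0, 0))

    # ---- inherited ultra-rare singletons --------------------------------
    rng_inh = _rng(cfg.seed, 3)
    tracking = {
        "dn_dd_counts": dn_dd_counts,
        "dn_lofi_only_counts": dn_lofi_counts,
        "singletons_transmitted": 0,
        "singletons_non_transmitted": 0,
    }
    for i, fid in enumerate(fids):
        for parent_role in ("father", "mother"):
            n_sing = rng_inh.poisson(cfg.inherited_singleton_rate)
            for _ in range(n_sing):
                g = genes_lofi[rng_inh.integers(len(genes_lofi))]
                transmitted = rng_inh.random() < 0.5
                dos = {
                    "proband": 1 if transmitted else 0,
                    "father": 1 if parent_role == "father" else 0,
                    "mother": 1 if parent_role == "mother" else 0,
                }
                coding_calls.append(
                    _coding_call(
                        rng_inh, cfg, fid, g,
                        (dos["proband"], dos["father"], dos["mother"]),
                        True, 1, 0,
                    )
                )
                key = "singletons_transmitted" if transmitted else "singletons_non_transmitted"
                tracking[key] += 1
            # damaging but not ultra-rare (seen more than once / in reference)
            n_non = rng_inh.poisson(cfg.inherited_nonur_rate)
            for _ in range(n_non):
                g = genes_lofi[rng_inh.integers(len(genes_lofi))]
                transmitted = rng_inh.random() < 0.5
                pac = int(rng_inh.integers(2, 6))
                rac = int(rng_inh.integers(0, 10))
                coding_calls.append(
                    _coding_call(
                        rng_inh, cfg, fid, g,
                        (
                            1 if transmitted else 0,
                            1 if parent_role == "father" else 0,
                            1 if parent_role == "mother" else 0,
                        ),
                        True, pac, rac,
                    )
                )

    # ---- CNVs ------------------------------------------------------------
    rng_cnv = _rng(cfg.seed, 4)
    cnv_calls: list[CnvCall] = []

    def _draw_cnv(sample_id, fid, role):
        length = int(np.exp(rng_cnv.uniform(np.log(20_000), np.log(1_000_000))))
        start = int(rng_cnv.integers(0, max(span - length, 1)))
        ctype = "del" if rng_cnv.random() < 0.5 else "dup"
        probes = max(1, int(round(length / 5000)) + int(rng_cnv.poisson(2)))
        return CnvCall(
            chrom=CHROM, start=start, end=start + length, cnv_type=ctype,
            probes=probes, sample_id=sample_id, fid=fid, role=role,
        )

    for i, fid in enumerate(fids):
        row = trios.iloc[i]
        for role in ("father", "mother"):
            for _ in range(rng_cnv.poisson(cfg.cnv_rate)):
                c = _draw_cnv(row[role], fid, role)
                cnv_calls.append(c)
                if rng_cnv.random() < 0.5:  # transmitted copy
                    cnv_calls.append(
                        CnvCall(
                            chrom=c.chrom, start=c.start, end=c.end,
                            cnv_type=c.cnv_type, probes=c.probes,
                            sample_id=row["proband"], fid=fid, role="proband",
                        )
                    )
        for _ in range(rng_cnv.poisson(cfg.cnv_dn_rate)):
            cnv_calls.append(_draw_cnv(row["proband"], fid, "proband"))

    # ---- GWAS summary statistics ----------------------------------------
    rng_g = _rng(cfg.seed, 5)
    se = cfg.gwas_noise if cfg.gwas_noise > 0 else None

    def _sumstats(weights: np.ndarray) -> pd.DataFrame:
        if se is None:
            beta_hat = weights.copy()
            p = np.where(weights != 0.0, 1e-20, 1.0)
        else:
            beta_hat = weights + rng_g.normal(0.0, se, size=cfg.n_snps)
            p = 2.0 * sps.norm.sf(np.abs(beta_hat) / se)
        return pd.DataFrame(
            {
                "snp": snps["snp"], "chrom": snps["chrom"], "pos": snps["pos"],
                "a1": snps["a1"], "a2": snps["a2"],
                "beta": beta_hat, "p": np.clip(p, 1e-300, 1.0),
            }
        )

    summary_stats = {
        "ea": _sumstats(w),
        "iq": _sumstats(w),
        "scz": _sumstats(rng_g.permutation(w)),
    }

    # ---- liability and phenotype ----------------------------------------
    rng_l = _rng(cfg.seed, 6)
    noise_var = max(0.0, 1.0 - cfg.r2_prs - cfg.dn_effect**2 * cfg.dn_rate_dd)
    liab = (
        -np.sqrt(cfg.r2_prs) * true_prs_z
        + cfg.dn_effect * dn_dd_counts
        + np.sqrt(noise_var) * rng_l.standard_normal(n)
    )
    thr = np.quantile(liab, 1.0 - cfg.phenotype_quantile)
    trios["phenotype"] = (liab > thr).astype(int)  # 1 = lower performance

    # ---- optional Mendelian-error injection ------------------------------
    if cfg.mendelian_error_rate > 0:
        rng_e = _rng(cfg.seed, 7)
        n_cells = n * cfg.n_snps
        n_target = rng_e.binomial(n_cells, cfg.mendelian_error_rate)
        made = 0
        attempts = 0
        from triocog.trio import mendelian_consistent

        while made < n_target and attempts < 20 * n_target + 100:
            attempts += 1
            i = int(rng_e.integers(n))
            j = int(rng_e.integers(cfg.n_snps))
            options = [
                d for d in (0, 1, 2)
                if d != pro_d[i, j]
                and not mendelian_consistent(d, int(fat_d[i, j]), int(mot_d[i, j]))
            ]
            if options:
                pro_d[i, j] = options[int(rng_e.integers(len(options)))]
                made += 1

    samples, dosage_rows = [], []
    for i, fid in enumerate(fids):
        samples += [trios.at[i, "proband"], trios.at[i, "father"], trios.at[i, "mother"]]
        dosage_rows += [pro_d[i], fat_d[i], mot_d[i]]
    panel = SnpPanel(samples=samples, snps=snps, dosages=np.vstack(dosage_rows))

    return SynthCohort(
        cfg=cfg,
        trios=trios,
        snp_panel=panel,
        true_weights=w,
        summary_stats=summary_stats,
        coding_calls=coding_calls,
        cnv_calls=cnv_calls,
        gene_sets=gene_sets,
        liabilities=liab,
        true_prs_z=true_prs_z,
        tracking=tracking,
    )
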