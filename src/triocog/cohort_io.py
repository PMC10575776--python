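"""Reading and writing cohort files.

Formats: FAM-style pedigree TSV (one row per trio), VCF 4.2 for common-SNP
genotypes (GT) and rare coding variants (GT:DP:GQ:AD plus INFO GENE / CSQ /
CADD / MPC / FID / PAC / RAC), BED 0-based half-open for exons, BED-like
TSV for CNVs, and TSV for GWAS summary statistics. VCFs are read back with
cyvcf2; CADD/MPC are carried as VCF strings so values survive a round trip
bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from triocog.synth import SynthCohort, SynthConfig
from triocog.types import (
    AnnotatedVariant,
    CnvCall,
    CodingVariantCall,
    GeneSets,
    SnpPanel,
    TrioGenotype,
)

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _vcf_header(samples: list[str], info_lines: list[str], fmt_lines: list[str], contig_len: int) -> str:
    lines = ["##fileformat=VCFv4.2", f"##contig=<ID=1,length={contig_len}>"]
    lines += info_lines + fmt_lines
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    return "\n".join(lines) + "\n"


def write_genotype_vcf(panel: SnpPanel, path: Path) -> None:
    contig_len = int(panel.snps["pos"].max()) + 1000
    with open(path, "w") as fh:
        fh.write(
            _vcf_header(
                panel.samples,
                [],
                ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'],
                contig_len,
            )
        )
        d = panel.dosages
        for j, row in enumerate(panel.snps.itertuples(index=False)):
            gts = "\t".join(
                _GT[int(d[i, j])] if np.isfinite(d[i, j]) else "./."
                for i in range(len(panel.samples))
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp}\t{row.a2}\t{row.a1}\t.\t.\t.\tGT\t{gts}\n")


def read_genotype_vcf(path: Path, snp_meta: pd.DataFrame | None = None) -> SnpPanel:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps, rows = [], []
    for v in vcf:
        snps.append((v.ID, v.CHROM, v.POS, v.ALT[0], v.REF))
        gt = np.asarray(v.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        rows.append(gt.sum(axis=1))
    meta = pd.DataFrame(snps, columns=["snp", "chrom", "pos", "a1", "a2"])
    if snp_meta is not None and "maf" in snp_meta.columns:
        meta = meta.merge(snp_meta[["snp", "maf"]], on="snp", how="left")
    return SnpPanel(samples=samples, snps=meta, dosages=np.column_stack(rows))


_CODING_INFO = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">',
    '##INFO=<ID=CADD,Number=1,Type=String,Description="Scaled CADD score">',
    '##INFO=<ID=MPC,Number=1,Type=String,Description="MPC score">',
    '##INFO=<ID=FID,Number=1,Type=String,Description="Family carrying the call">',
    '##INFO=<ID=PAC,Number=1,Type=Integer,Description="Parental allele count in cohort">',
    '##INFO=<ID=RAC,Number=1,Type=Integer,Description="Reference-panel allele count">',
]
_CODING_FMT = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
]


def write_coding_vcf(calls: list[CodingVariantCall], trios: pd.DataFrame, path: Path) -> None:
    trio_members = {
        r.fid: {"proband": r.proband, "father": r.father, "mother": r.mother}
        for r in trios.itertuples(index=False)
    }
    samples = [s for fid in trios["fid"] for s in trio_members[fid].values()]
    col = {s: i for i, s in enumerate(samples)}
    contig_len = max((c.pos for c in calls), default=1000) + 1000
    ordered = sorted(calls, key=lambda c: (c.pos, c.fid, c.ref, c.alt))
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples, _CODING_INFO, _CODING_FMT, contig_len))
        for c in ordered:
            a = c.annotation
            info = f"GENE={a.gene};CSQ={a.consequence};CADD={a.cadd!r}"
            if a.mpc is not None:
                info += f";MPC={a.mpc!r}"
            info += f";FID={c.fid};PAC={a.parent_allele_count};RAC={a.reference_allele_count}"
            fields = ["./.:.:.:.,."] * len(samples)
            for role, g in c.genotypes.items():
                sid = trio_members[c.fid][role]
                dp = int(g.depth)
                ad_alt = int(round(g.allele_balance * dp)) if dp > 0 else 0
                fields[col[sid]] = f"{_GT[g.dosage]}:{dp}:{int(g.gq)}:{dp - ad_alt},{ad_alt}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t.\t{info}\tGT:DP:GQ:AD\t"
                + "\t".join(fields)
                + "\n"
            )


def read_coding_vcf(path: Path, trios: pd.DataFrame) -> list[CodingVariantCall]:
    member_of = {}
    for r in trios.itertuples(index=False):
        member_of[r.fid] = {"proband": r.proband, "father": r.father, "mother": r.mother}
    vcf = VCF(str(path))
    col = {s: i for i, s in enumerate(vcf.samples)}
    calls = []
    for v in vcf:
        fid = v.INFO.get("FID")
        mpc_raw = v.INFO.get("MPC")
        ann = AnnotatedVariant(
            gene=v.INFO.get("GENE"),
            consequence=v.INFO.get("CSQ"),
            cadd=float(v.INFO.get("CADD")),
            mpc=float(mpc_raw) if mpc_raw is not None else None,
            parent_allele_count=int(v.INFO.get("PAC")),
            reference_allele_count=int(v.INFO.get("RAC")),
        )
        gt = np.asarray(v.genotype.array())[:, :2]
        dp = v.format("DP")
        gq = v.format("GQ")
        ad = v.format("AD")
        gts = {}
        for role, sid in member_of[fid].items():
            i = col[sid]
            depth = int(dp[i][0])
            ad_alt = int(ad[i][1])
            ab = ad_alt / depth if depth > 0 else float("nan")
            dose = int(gt[i][0] + gt[i][1]) if gt[i][0] >= 0 else None
            gts[role] = TrioGenotype(
                role=role, dosage=dose, depth=depth, gq=float(gq[i][0]), allele_balance=ab
            )
        calls.append(
            CodingVariantCall(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0],
                fid=fid, annotation=ann, genotypes=gts,
            )
        )
    return calls


def write_cohort(cohort: SynthCohort, outdir: str | Path) -> dict[str, Path]:
    """Emit the full cohort file set; returns the path of each artefact."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fam = cohort.trios[["fid", "proband", "father", "mother", "sex", "phenotype"]]
    paths["fam"] = out / "trios.fam"
    fam.to_csv(paths["fam"], sep="\t", header=False, index=False)

    cov_cols = ["fid"] + [f"PC{j}" for j in range(1, 11)]
    paths["covariates"] = out / "covariates.tsv"
    cohort.trios[cov_cols].to_csv(paths["covariates"], sep="\t", index=False, float_format="%.17g")

    paths["genotypes"] = out / "genotypes.vcf"
    write_genotype_vcf(cohort.snp_panel, paths["genotypes"])

    paths["coding"] = out / "coding.vcf"
    write_coding_vcf(cohort.coding_calls, cohort.trios, paths["coding"])

    paths["cnvs"] = out / "cnvs.tsv"
    pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.cnv_type, c.probes, c.sample_id, c.fid, c.role)
            for c in cohort.cnv_calls
        ],
        columns=["chrom", "start", "end", "type", "probes", "sample_id", "fid", "role"],
    ).to_csv(paths["cnvs"], sep="\t", index=False)

    paths["genes"] = out / "genes.tsv"
    genes = sorted(cohort.gene_sets.known_genes)
    pd.DataFrame(
        {
            "gene": genes,
            "lofi": [int(g in cohort.gene_sets.lofi) for g in genes],
            "dd": [int(g in cohort.gene_sets.dd) for g in genes],
        }
    ).to_csv(paths["genes"], sep="\t", index=False)

    paths["exons"] = out / "exons.bed"
    cohort.gene_sets.exons.to_csv(paths["exons"], sep="\t", header=False, index=False)

    for trait, df in cohort.summary_stats.items():
        p = out / f"gwas_{trait}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        paths[f"gwas_{trait}"] = p

    paths["weights"] = out / "weights.tsv"
    pd.DataFrame({"snp": cohort.snp_panel.snps["snp"], "weight": cohort.true_weights}).to_csv(
        paths["weights"], sep="\t", index=False, float_format="%.17g"
    )

    paths["liabilities"] = out / "liabilities.tsv"
    pd.DataFrame(
        {"fid": cohort.trios["fid"], "liability": cohort.liabilities, "true_prs_z": cohort.true_prs_z}
    ).to_csv(paths["liabilities"], sep="\t", index=False, float_format="%.17g")

    paths["snps"] = out / "snps.tsv"
    cohort.snp_panel.snps.to_csv(paths["snps"], sep="\t", index=False, float_format="%.17g")

    paths["tracking"] = out / "tracking.json"
    track = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in cohort.tracking.items()
    }
    paths["tracking"].write_text(json.dumps(track, indent=1))

    paths["config"] = out / "config.json"
    paths["config"].write_text(json.dumps(cohort.cfg.to_dict(), indent=1))
    return paths


def read_cohort(outdir: str | Path) -> SynthCohort:
    """Reconstruct a cohort from the file set emitted by ``write_cohort``."""
    out = Path(outdir)
    cfg = SynthConfig.from_dict(json.loads((out / "config.json").read_text()))

    fam = pd.read_csv(
        out / "trios.fam", sep="\t", header=None,
        names=["fid", "proband", "father", "mother", "sex", "phenotype"],
    )
    cov = pd.read_csv(out / "covariates.tsv", sep="\t", float_precision="round_trip")
    trios = fam.merge(cov, on="fid")
    trios = trios[
        ["fid", "proband", "father", "mother", "sex"]
        + [f"PC{j}" for j in range(1, 11)]
        + ["phenotype"]
    ]

    snp_meta = pd.read_csv(out / "snps.tsv", sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    panel = read_genotype_vcf(out / "genotypes.vcf", snp_meta)
    panel.snps["maf"] = snp_meta["maf"].to_numpy()

    coding = read_coding_vcf(out / "coding.vcf", trios)

    cnv_df = pd.read_csv(out / "cnvs.tsv", sep="\t", dtype={"chrom": str})
    cnvs = [
        CnvCall(
            chrom=r.chrom, start=int(r.start), end=int(r.end), cnv_type=r.type,
            probes=int(r.probes), sample_id=r.sample_id, fid=r.fid, role=r.role,
        )
        for r in cnv_df.itertuples(index=False)
    ]

    genes = pd.read_csv(out / "genes.tsv", sep="\t")
    exons = pd.read_csv(
        out / "exons.bed", sep="\t", header=None, names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str},
    )
    gene_sets = GeneSets(
        lofi=frozenset(genes.loc[genes["lofi"] == 1, "gene"]),
        dd=frozenset(genes.loc[genes["dd"] == 1, "gene"]),
        exons=exons,
    )

    summary_stats = {
        t: pd.read_csv(out / f"gwas_{t}.tsv", sep="\t", dtype={"chrom": str},
                       float_precision="round_trip")
        for t in ("ea", "iq", "scz")
        if (out / f"gwas_{t}.tsv").exists()
    }
    weights = pd.read_csv(out / "weights.tsv", sep="\t", float_precision="round_trip")["weight"].to_numpy()
    liab_df = pd.read_csv(out / "liabilities.tsv", sep="\t", float_precision="round_trip")
    tracking = json.loads((out / "tracking.json").read_text())
    tracking = {k: (np.asarray(v) if isinstance(v, list) else v) for k, v in tracking.items()}

    return SynthCohort(
        cfg=cfg,
        trios=trios,
        snp_panel=panel,
        true_weights=weights,
        summary_stats=summary_stats,
        coding_calls=coding,
        cnv_calls=cnvs,
        gene_sets=gene_sets,
        liabilities=liab_df["liability"].to_numpy(),
        true_prs_z=liab_df["true_prs_z"].to_numpy(),
        tracking=tracking,
    )
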