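"""LD clumping, thresholded polygenic scoring, transmitted versus
non-transmitted scores, and the polygenic transmission disequilibrium test.

A polygenic risk score (PRS) is the weighted sum of effect-allele dosages
over GWAS-significant SNPs surviving LD clumping. For each trio the
pseudo-control score (nt-PRS) is computed on the non-transmitted dosages
(father + mother - proband per SNP), indexing genetic-nurture effects; the
pTDT deviation is (proband PRS - midparent PRS) divided by the cohort
standard deviation of the midparent PRS.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from triocog.trio import pseudo_control_matrix
from triocog.types import SnpPanel

log = logging.getLogger(__name__)

THRESHOLDS = (0.001, 0.05, 0.5)
PRIMARY_THRESHOLD = 0.05  # explains the most case-control variance

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def align_stats(stats: pd.DataFrame, panel: SnpPanel, drop_ambiguous: bool = True) -> pd.DataFrame:
    """Match summary-statistic rows to panel SNPs and orient effect sizes.

    Returns the intersected table with columns ``panel_col`` (column index
    into the panel dosage matrix) and ``beta_aligned`` (per-copy effect of
    the panel's counted allele). Alleles are matched directly or after
    strand complement; a swapped match negates the effect. Strand-ambiguous
    SNPs (A/T, C/G) are dropped by default; unalignable SNPs are dropped
    with a warning.
    """
    panel_snps = panel.snps.reset_index(drop=True)
    lookup = {s: j for j, s in enumerate(panel_snps["snp"])}
    rows = []
    for rec in stats.itertuples(index=False):
        j = lookup.get(rec.snp)
        if j is None:
            continue
        a1, a2 = rec.a1, rec.a2
        if drop_ambiguous and _is_ambiguous(a1, a2):
            continue
        pa1 = panel_snps.at[j, "a1"]
        pa2 = panel_snps.at[j, "a2"]
        ca1, ca2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
        if (a1, a2) == (pa1, pa2) or (ca1, ca2) == (pa1, pa2):
            beta = rec.beta
        elif (a2, a1) == (pa1, pa2) or (ca2, ca1) == (pa1, pa2):
            beta = -rec.beta
        else:
            log.warning("unalignable alleles for %s: %s/%s vs %s/%s", rec.snp, a1, a2, pa1, pa2)
            continue
        rows.append((rec.snp, rec.chrom, rec.pos, beta, rec.p, j))
    if not rows:
        raise ValueError("no summary-statistic SNPs could be aligned to the panel")
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "beta_aligned", "p", "panel_col"])


def _ld_r2(dosages: np.ndarray, j: int, k: int) -> float:
    """Squared Pearson correlation of two dosage columns (pairwise-complete)."""
    x, y = dosages[:, j], dosages[:, k]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return 0.0
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def clump(
    aligned: pd.DataFrame,
    ld_dosages: np.ndarray,
    window_kb: float = 250.0,
    r2_max: float = 0.2,
) -> pd.DataFrame:
    """Greedy LD clumping of aligned summary statistics.

    Sorted by ascending p (ties broken by chromosome then position), the
    best remaining SNP is retained and every unprocessed SNP within
    ``window_kb`` of it with dosage r-squared above ``r2_max`` is removed.
    ``ld_dosages`` is the genotype matrix used for LD (parental genotypes,
    so transmitted alleles are not double-counted).
    """
    if len(aligned) == 0:
        raise ValueError("empty summary-statistic / panel intersection")
    df = aligned.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    window = window_kb * 1000.0
    alive = np.ones(len(df), dtype=bool)
    kept: list[int] = []
    pos = df["pos"].to_numpy(float)
    chrom = df["chrom"].to_numpy()
    cols = df["panel_col"].to_numpy()
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept.append(i)
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        near[i] = False
        for k in np.flatnonzero(near):
            if _ld_r2(ld_dosages, cols[i], cols[k]) > r2_max:
                alive[k] = False
    out = df.iloc[kept].sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out


def score(dosages: np.ndarray, aligned: pd.DataFrame, threshold: float) -> np.ndarray:
    """Raw PRS: sum over clumped SNPs with p < threshold of beta x dosage.

    Missing dosages contribute the SNP's mean dosage in the supplied
    matrix times its effect (mean imputation, as common scorers do).
    """
    sel = aligned[aligned["p"] < threshold]
    if len(sel) == 0:
        return np.zeros(dosages.shape[0])
    mat = dosages[:, sel["panel_col"].to_numpy()]
    col_mean = np.nanmean(np.where(np.isfinite(mat), mat, np.nan), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    filled = np.where(np.isfinite(mat), mat, col_mean)
    return filled @ sel["beta_aligned"].to_numpy()


def ptdt(proband_prs: np.ndarray, midparent_prs: np.ndarray) -> np.ndarray:
    """Per-trio pTDT deviation.

    (proband PRS - midparent PRS) / SD over trios of the midparent PRS.
    Scale-invariant; requires at least two trios with non-degenerate
    midparent variation.
    """
    if len(proband_prs) < 2:
        raise ValueError("pTDT needs at least two trios")
    sd = np.std(midparent_prs, ddof=1)
    if sd == 0:
        raise ValueError("midparent PRS standard deviation is zero")
    return (np.asarray(proband_prs) - np.asarray(midparent_prs)) / sd


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=0)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)


def build_profiles(
    panel: SnpPanel,
    trios: pd.DataFrame,
    stats: pd.DataFrame,
    thresholds: tuple[float, ...] = THRESHOLDS,
    window_kb: float = 250.0,
    r2_max: float = 0.2,
    max_missing: float = 0.05,
) -> pd.DataFrame:
    """Per-trio PRS profiles at each p-value threshold.

    Mendelian-inconsistent trio/SNP entries are masked (set missing for
    that trio only) before scoring; LD for clumping is estimated from the
    parental genotypes. Output columns include raw proband, father,
    mother, midparent and non-transmitted (pseudo-control) scores, their
    cohort-standardised versions (suffix ``_z``), the pTDT deviation, and
    a ``flagged`` indicator for trios whose missing-SNP fraction exceeds
    ``max_missing``.
    """
    pro = panel.rows(list(trios["proband"])).copy()
    fat = panel.rows(list(trios["father"])).copy()
    mot = panel.rows(list(trios["mother"])).copy()
    nt = pseudo_control_matrix(pro, fat, mot)
    bad = ~np.isfinite(nt)
    for m in (pro, fat, mot):
        m[bad] = np.nan

    parental = np.vstack([fat, mot])
    aligned = align_stats(stats, panel)
    clumped = clump(aligned, parental, window_kb=window_kb, r2_max=r2_max)

    miss_frac = (~np.isfinite(pro)).mean(axis=1)
    out = []
    for thr in thresholds:
        s_pro = score(pro, clumped, thr)
        s_fat = score(fat, clumped, thr)
        s_mot = score(mot, clumped, thr)
        s_nt = score(nt, clumped, thr)
        mid = (s_fat + s_mot) / 2.0
        dev = ptdt(s_pro, mid)
        out.append(
            pd.DataFrame(
                {
                    "fid": trios["fid"].to_numpy(),
                    "threshold": thr,
                    "proband_prs": s_pro,
                    "father_prs": s_fat,
                    "mother_prs": s_mot,
                    "midparent_prs": mid,
                    "nt_prs": s_nt,
                    "proband_prs_z": _zscore(s_pro),
                    "midparent_prs_z": _zscore(mid),
                    "nt_prs_z": _zscore(s_nt),
                    "ptdt_deviation": dev,
                    "flagged": miss_frac > max_missing,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
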