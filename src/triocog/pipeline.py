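"""End-to-end analysis orchestration.

The primary analysis is 18 univariable logistic-regression tests of a
binary school-performance phenotype: 6 common-variant predictors
(transmitted and non-transmitted PRS for three traits) fitted by ordinary
binomial logistic regression, and 12 rare-variant burden categories fitted
by Firth's penalised regression, all adjusting for sex and 10 principal
components. Bonferroni significance is 0.05 / 18. Secondary analyses are
the pTDT group comparisons and rare-variant transmission disequilibrium
tests; a multivariable joint model quantifies independent effects and
per-factor Nagelkerke delta-R2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from triocog import classify as cls
from triocog import stats as tstats
from triocog import trio as trio_mod
from triocog.prs import PRIMARY_THRESHOLD, build_profiles
from triocog.synth import SynthCohort
from triocog.types import InheritanceClass

log = logging.getLogger(__name__)

N_PRIMARY_TESTS = 18
BONFERRONI_ALPHA = 0.05 / N_PRIMARY_TESTS  # = 0.0027, the primary threshold

COVARIATE_COLS = ["sex"] + [f"PC{j}" for j in range(1, 11)]

TRAITS = ("scz", "ea", "iq")


def covariate_matrix(trios: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(trios))})
    for c in COVARIATE_COLS:
        X[c] = trios[c].to_numpy(dtype=float)
    return X


def classify_coding_calls(cohort: SynthCohort) -> list:
    """Apply the trio genotype filters, then assign an inheritance class to
    every coding call. Logs input/retained counts per filter."""
    n_in, n_filtered = 0, 0
    for call in cohort.coding_calls:
        n_in += 1
        if not trio_mod.pass_genotype_filters(call.genotypes):
            call.inheritance = InheritanceClass.FILTERED
            n_filtered += 1
            continue
        call.inheritance = trio_mod.classify_snv(
            call.genotypes["proband"].dosage,
            call.genotypes["father"].dosage,
            call.genotypes["mother"].dosage,
        )
    log.info("coding calls: %d in, %d failed trio genotype filters", n_in, n_filtered)
    return cohort.coding_calls


def classify_cnv_calls(cohort: SynthCohort) -> list:
    """Assign inheritance classes to CNV calls trio by trio."""
    by_fid: dict[str, dict[str, list]] = {}
    for c in cohort.cnv_calls:
        by_fid.setdefault(c.fid, {"proband": [], "father": [], "mother": []})[c.role].append(c)
    out = []
    for fid, groups in by_fid.items():
        for c, klass in trio_mod.classify_cnv(groups["proband"], groups["father"], groups["mother"]):
            c.inheritance = klass
            out.append(c)
    return out


def build_cohort_burden(cohort: SynthCohort, return_support: bool = False):
    classify_coding_calls(cohort)
    classify_cnv_calls(cohort)
    return cls.build_burden_matrix(
        cohort.coding_calls, cohort.cnv_calls, cohort.gene_sets, cohort.trios,
        return_support=return_support,
    )


def build_cohort_profiles(
    cohort: SynthCohort, thresholds=(0.001, 0.05, 0.5)
) -> dict[str, pd.DataFrame]:
    return {
        trait: build_profiles(cohort.snp_panel, cohort.trios, stats_df, thresholds=thresholds)
        for trait, stats_df in cohort.summary_stats.items()
    }


def _prs_at(profiles: pd.DataFrame, threshold: float) -> pd.DataFrame:
    sel = profiles[profiles["threshold"] == threshold]
    if len(sel) == 0:
        raise KeyError(f"no PRS profile at threshold {threshold}")
    return sel.reset_index(drop=True)


def run_univariable(
    burden: pd.DataFrame,
    profiles_by_trait: dict[str, pd.DataFrame],
    trios: pd.DataFrame,
    prs_threshold: float = PRIMARY_THRESHOLD,
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """The 18-test primary analysis table.

    Internally the outcome is always 1 = lower performance. Rare-variant
    rows report the odds ratio for lower performance (Firth fit); PRS rows
    report the odds ratio per SD of score for *higher* performance (sign
    inverted at presentation, the convention of the source analyses), each
    with 95% CI, the uncorrected penalised-LR or LR p-value, and a
    Bonferroni flag at ``alpha``.
    """
    y_lower = trios["phenotype"].to_numpy(dtype=float)
    Xbase = covariate_matrix(trios)
    rows = []

    traits = [t for t in TRAITS if t in profiles_by_trait]
    traits += [t for t in profiles_by_trait if t not in traits]
    for trait in traits:
        prof = _prs_at(profiles_by_trait[trait], prs_threshold)
        for kind, colname in (("transmitted_prs", "proband_prs_z"), ("nt_prs", "nt_prs_z")):
            X = Xbase.copy()
            X["score"] = prof[colname].to_numpy()
            res = tstats.binomial_logistic(y_lower, X, plr_terms=["score"])
            beta = res.params["score"]
            lo, hi = res.conf_int.loc["score", "low"], res.conf_int.loc["score", "high"]
            p = res.p["score"]
            rows.append(
                {
                    "test": f"{trait}_{kind}",
                    "category": "common",
                    "model": res.method,
                    "n": res.n_used,
                    "beta": -beta,  # toward higher performance
                    "odds_ratio": float(np.exp(-beta)),
                    "ci_low": float(np.exp(-hi)),
                    "ci_high": float(np.exp(-lo)),
                    "p": float(p),
                    "outcome_coding": "higher=1",
                    "bonferroni_significant": bool(p < alpha),
                }
            )

    for cat in cls.BURDEN_CATEGORIES:
        if cat not in burden.columns:
            raise KeyError(f"burden matrix is missing category {cat!r}")
        X = Xbase.copy()
        X["burden"] = burden.loc[trios["fid"], cat].to_numpy(dtype=float)
        if X["burden"].nunique() <= 1:
            # no carriers (or all identical): the effect is not estimable
            rows.append(
                {
                    "test": cat, "category": "rare", "model": "degenerate",
                    "n": len(y_lower), "beta": np.nan, "odds_ratio": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                    "outcome_coding": "lower=1", "bonferroni_significant": False,
                }
            )
            continue
        res = tstats.firth_logistic(y_lower, X, plr_terms=["burden"])
        beta = res.params["burden"]
        rows.append(
            {
                "test": cat,
                "category": "rare",
                "model": res.method,
                "n": res.n_used,
                "beta": float(beta),
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(res.conf_int.loc["burden", "low"])),
                "ci_high": float(np.exp(res.conf_int.loc["burden", "high"])),
                "p": float(res.p["burden"]),
                "outcome_coding": "lower=1",
                "bonferroni_significant": bool(res.p["burden"] < alpha),
            }
        )
    return pd.DataFrame(rows)


def run_secondary(
    profiles_by_trait: dict[str, pd.DataFrame],
    burden: pd.DataFrame,
    trios: pd.DataFrame,
    prs_threshold: float = PRIMARY_THRESHOLD,
) -> dict[str, pd.DataFrame]:
    """Secondary tests: per-trait pTDT deviations compared between
    phenotype groups, and rare-variant TDT chi-squares on cohort-total
    transmitted versus non-transmitted counts."""
    y = trios["phenotype"].to_numpy()
    ptdt_rows = []
    for trait, prof_all in profiles_by_trait.items():
        prof = _prs_at(prof_all, prs_threshold)
        dev = prof["ptdt_deviation"].to_numpy()
        lower, higher = dev[y == 1], dev[y == 0]
        if np.allclose(lower.var() + higher.var(), 0) and np.allclose(lower.mean(), higher.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = tstats.two_sample_t(lower, higher)
        ptdt_rows.append(
            {
                "trait": trait,
                "mean_dev_lower": lower.mean(),
                "mean_dev_higher": higher.mean(),
                "t": t,
                "p": p,
            }
        )

    tdt_rows = []
    for kind in ("coding", "cnv"):
        prefix = "trans_coding" if kind == "coding" else "trans_cnv"
        nt_prefix = "nt_coding" if kind == "coding" else "nt_cnv"
        for s in cls.GENE_SET_NAMES:
            t_count = int(burden[f"{prefix}_{s}"].sum())
            nt_count = int(burden[f"{nt_prefix}_{s}"].sum())
            if t_count + nt_count == 0:
                stat, p = np.nan, np.nan
            else:
                stat, p = tstats.tdt_chisq(t_count, nt_count)
            tdt_rows.append(
                {
                    "variant_kind": kind,
                    "gene_set": s,
                    "transmitted": t_count,
                    "non_transmitted": nt_count,
                    "chisq": stat,
                    "p": p,
                }
            )
    return {"ptdt": pd.DataFrame(ptdt_rows), "tdt": pd.DataFrame(tdt_rows)}


def run_multivariable(
    factors: pd.DataFrame, trios: pd.DataFrame, alpha: float = BONFERRONI_ALPHA
) -> dict:
    """Joint model of the selected genetic factors.

    The outcome here is coded 1 = higher performance. Betas, CIs and
    penalised-LR p-values come from a joint Firth fit including sex and 10
    PCs; each factor's Nagelkerke delta-R2 comes from nested ordinary
    binomial fits (full versus the model excluding that factor), and the
    total variance explained compares the full model with covariates only.
    """
    y_higher = 1.0 - trios["phenotype"].to_numpy(dtype=float)
    Xbase = covariate_matrix(trios)
    factor_names = list(factors.columns)
    Xfull = pd.concat([Xbase, factors.reset_index(drop=True)], axis=1)

    firth_full = tstats.firth_logistic(y_higher, Xfull, plr_terms=factor_names)
    ml_full = tstats.binomial_logistic(y_higher, Xfull)
    ml_base = tstats.binomial_logistic(y_higher, Xbase)

    rows = []
    for name in factor_names:
        reduced_cols = [c for c in Xfull.columns if c != name]
        ml_red = tstats.binomial_logistic(y_higher, Xfull[reduced_cols])
        delta = tstats.nagelkerke_delta_r2(ml_full, ml_red)
        rows.append(
            {
                "factor": name,
                "beta": float(firth_full.params[name]),
                "ci_low": float(firth_full.conf_int.loc[name, "low"]),
                "ci_high": float(firth_full.conf_int.loc[name, "high"]),
                "p": float(firth_full.p[name]),
                "delta_r2": float(delta),
            }
        )
    total = tstats.nagelkerke_delta_r2(ml_full, ml_base)
    return {
        "table": pd.DataFrame(rows),
        "total_delta_r2": float(total),
        "joint_fit": firth_full,
        "outcome_coding": "higher=1",
    }


def carrier_phenotype_table(
    carrier: pd.Series,
    phenotype: pd.Series,
    grades: pd.Series | None = None,
    id_status: pd.Series | None = None,
) -> dict:
    """Phenotypic description of carriers of one variant class.

    Reports the carrier count, the exact binomial CI for the proportion of
    carriers in the lower-performance group, the carrier grade
    distribution (percent per grade) when grades are supplied, and
    Fisher's exact test of comorbid-ID enrichment among lower-performance
    probands (ID status crossed with carrier status) when available.
    """
    carrier = carrier.astype(bool)
    pheno = phenotype.astype(int)
    n_car = int(carrier.sum())
    out: dict = {"n_carriers": n_car}
    if n_car == 0:
        out["grade_distribution"] = {}
        return out
    in_lower = int((carrier & (pheno == 1)).sum())
    out["carriers_in_lower"] = in_lower
    out["lower_proportion_ci"] = tstats.clopper_pearson(in_lower, n_car)
    if grades is not None:
        g = grades[carrier]
        counts = g.value_counts().sort_index()
        out["grade_distribution"] = {
            int(k): round(100.0 * v / n_car) for k, v in counts.items()
        }
    if id_status is not None:
        mask = pheno == 1
        a = int((id_status & carrier & mask).sum())
        b = int((~id_status.astype(bool) & carrier & mask).sum())
        c = int((id_status & ~carrier & mask).sum())
        d = int((~id_status.astype(bool) & ~carrier & mask).sum())
        out["id_table"] = [[a, b], [c, d]]
        out["id_fisher"] = tstats.fisher_exact([[a, b], [c, d]])
    return out


def run_analysis(cohort: SynthCohort, prs_threshold: float = PRIMARY_THRESHOLD) -> dict:
    """Convenience driver: burden + profiles + primary, secondary and
    multivariable analyses on one cohort."""
    burden = build_cohort_burden(cohort)
    profiles = build_cohort_profiles(cohort, thresholds=(prs_threshold,))
    uni = run_univariable(burden, profiles, cohort.trios, prs_threshold=prs_threshold)
    secondary = run_secondary(profiles, burden, cohort.trios, prs_threshold=prs_threshold)

    hits = uni[uni["bonferroni_significant"]]
    factors = pd.DataFrame(index=range(len(cohort.trios)))
    for _, row in hits.iterrows():
        name = row["test"]
        if row["category"] == "rare":
            factors[name] = burden.loc[cohort.trios["fid"], name].to_numpy(dtype=float)
        else:
            trait, _, kind = name.partition("_")
            prof = _prs_at(profiles[trait], prs_threshold)
            col = "proband_prs_z" if kind == "transmitted_prs" else "nt_prs_z"
            factors[name] = prof[col].to_numpy()
    multi = run_multivariable(factors, cohort.trios) if len(factors.columns) else None
    return {
        "burden": burden,
        "profiles": profiles,
        "univariable": uni,
        "secondary": secondary,
        "multivariable": multi,
    }
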