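"""Clumping, scoring, pseudo-control PRS and pTDT."""

import numpy as np
import pandas as pd
import pytest

from triocog.prs import align_stats, build_profiles, clump, ptdt, score
from triocog.synth import SynthConfig, generate_cohort
from triocog.types import SnpPanel


def _panel(dosages, pos, a1="A", a2="C"):
    n_samples, n_snps = dosages.shape
    snps = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(n_snps)],
            "chrom": "1",
            "pos": pos,
            "a1": a1 if isinstance(a1, list) else [a1] * n_snps,
            "a2": a2 if isinstance(a2, list) else [a2] * n_snps,
        }
    )
    return SnpPanel(samples=[f"i{i}" for i in range(n_samples)], snps=snps, dosages=dosages)


def _stats(panel, beta, p):
    return pd.DataFrame(
        {
            "snp": panel.snps["snp"],
            "chrom": panel.snps["chrom"],
            "pos": panel.snps["pos"],
            "a1": panel.snps["a1"],
            "a2": panel.snps["a2"],
            "beta": beta,
            "p": p,
        }
    )


class TestClump:
    def test_correlated_pair_within_window_keeps_best_p(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 400).astype(float)
        noise = rng.integers(0, 3, 400).astype(float)
        y = np.where(rng.random(400) < 0.8, x, noise)  # r2 > 0.2
        d = np.column_stack([x, y])
        panel = _panel(d, [100_000, 200_000])
        aligned = align_stats(_stats(panel, [0.1, 0.2], [1e-8, 1e-4]), panel)
        kept = clump(aligned, d)
        assert kept["snp"].tolist() == ["s0"]

    def test_outside_window_both_kept(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 400).astype(float)
        d = np.column_stack([x, x])  # r2 = 1 but 300 kb apart
        panel = _panel(d, [100_000, 400_000])
        aligned = align_stats(_stats(panel, [0.1, 0.2], [1e-8, 1e-4]), panel)
        assert len(clump(aligned, d)) == 2

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (600, 20)).astype(float)
        panel = _panel(d, np.arange(20) * 10_000 + 1)
        aligned = align_stats(_stats(panel, rng.normal(size=20), rng.uniform(size=20)), panel)
        assert len(clump(aligned, d)) == 20

    def test_matches_quadratic_oracle_and_order_invariance(self):
        """Greedy clumping equals an independently coded O(n^2) oracle on a
        30-SNP block-correlated fixture, and is input-order invariant."""
        rng = np.random.default_rng(42)
        n, m = 500, 30
        base = rng.integers(0, 3, (n, 10)).astype(float)
        cols, pos = [], []
        for j in range(m):
            src = base[:, j // 3]
            mix = np.where(rng.random(n) < 0.7, src, rng.integers(0, 3, n))
            cols.append(mix)
            pos.append(50_000 * (j + 1))
        d = np.column_stack(cols)
        panel = _panel(d, pos)
        stats_df = _stats(panel, rng.normal(size=m), rng.uniform(1e-9, 1, size=m))
        aligned = align_stats(stats_df, panel)
        kept = set(clump(aligned, d, window_kb=250, r2_max=0.2)["snp"])

        # oracle: repeatedly take the lowest-p survivor, re-checking every pair
        def r2(a, b):
            return np.corrcoef(d[:, a], d[:, b])[0, 1] ** 2

        df = aligned.sort_values(["p", "chrom", "pos"]).reset_index(drop=True)
        remaining = list(df.index)
        oracle = set()
        while remaining:
            best = remaining.pop(0)
            oracle.add(df.at[best, "snp"])
            remaining = [
                k for k in remaining
                if not (
                    abs(df.at[k, "pos"] - df.at[best, "pos"]) <= 250_000
                    and r2(df.at[best, "panel_col"], df.at[k, "panel_col"]) > 0.2
                )
            ]
        assert kept == oracle

        shuffled = stats_df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        kept2 = set(clump(align_stats(shuffled, panel), d)["snp"])
        assert kept2 == kept


class TestScore:
    def test_zero_betas_zero_score(self):
        d = np.ones((4, 3))
        panel = _panel(d, [1, 2, 3])
        aligned = align_stats(_stats(panel, [0.0] * 3, [0.01] * 3), panel)
        np.testing.assert_array_equal(score(d, aligned, 0.5), np.zeros(4))

    def test_single_snp_arithmetic_and_threshold_semantics(self):
        d = np.array([[2.0], [0.0]])
        panel = _panel(d, [100])
        aligned = align_stats(_stats(panel, [0.5], [1e-3]), panel)
        np.testing.assert_allclose(score(d, aligned, 0.05), [1.0, 0.0])
        # p = 0.1 contributes at threshold 0.5 but not at 0.05
        aligned2 = align_stats(_stats(panel, [0.5], [0.1]), panel)
        assert score(d, aligned2, 0.05)[0] == 0.0
        assert score(d, aligned2, 0.5)[0] == 1.0

    def test_missing_dosage_mean_imputed(self):
        d = np.array([[2.0], [0.0], [np.nan]])
        panel = _panel(d, [100])
        aligned = align_stats(_stats(panel, [1.0], [1e-4]), panel)
        np.testing.assert_allclose(score(d, aligned, 0.05), [2.0, 0.0, 1.0])

    def test_allele_alignment(self):
        d = np.array([[2.0], [1.0]])
        panel = _panel(d, [100], a1=["A"], a2=["C"])
        # swapped alleles: effect allele is the panel's other allele
        swapped = _stats(panel, [0.5], [1e-4]).assign(a1="C", a2="A")
        aligned = align_stats(swapped, panel)
        assert aligned["beta_aligned"].iloc[0] == -0.5
        # ambiguous A/T SNP dropped
        ambiguous = _stats(panel, [0.5], [1e-4]).assign(a1="A", a2="T")
        with pytest.raises(ValueError):
            align_stats(ambiguous, panel)


@pytest.fixture(scope="module")
def profiles():
    cohort = generate_cohort(
        SynthConfig(n_trios=200, n_snps=150, n_genes_lofi=30, n_genes_dd=8,
                    n_genes_background=10, seed=3)
    )
    return build_profiles(cohort.snp_panel, cohort.trios, cohort.summary_stats["ea"])


class TestProfiles:
    def test_transmission_identity_per_raw_score(self, profiles):
        """proband PRS + pseudo-control PRS = father PRS + mother PRS,
        exactly, at every threshold."""
        lhs = profiles["proband_prs"] + profiles["nt_prs"]
        rhs = profiles["father_prs"] + profiles["mother_prs"]
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_standardised_scores_centred(self, profiles):
        for col in ("proband_prs_z", "nt_prs_z", "midparent_prs_z"):
            for _, grp in profiles.groupby("threshold"):
                assert abs(grp[col].mean()) < 1e-10

    def test_profile_thresholds_present(self, profiles):
        assert sorted(profiles["threshold"].unique()) == [0.001, 0.05, 0.5]


class TestPtdt:
    def test_midparent_proband_zero_deviation(self):
        mid = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(ptdt(mid.copy(), mid), np.zeros(4))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        pro, mid = rng.normal(size=50), rng.normal(size=50)
        np.testing.assert_allclose(ptdt(pro, mid), ptdt(2 * pro, 2 * mid))

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError):
            ptdt(np.array([1.0, 2.0]), np.array([1.0, 1.0]))

    def test_null_cohort_mean_deviation_near_zero(self):
        """Random transmission: mean pTDT deviation is not significantly
        different from zero at n = 2000."""
        from scipy import stats as sps

        cohort = generate_cohort(
            SynthConfig(n_trios=2000, n_snps=150, r2_prs=0.0, n_genes_lofi=30,
                        n_genes_dd=8, n_genes_background=10, seed=5)
        )
        prof = build_profiles(
            cohort.snp_panel, cohort.trios, cohort.summary_stats["ea"], thresholds=(0.5,)
        )
        t, p = sps.ttest_1samp(prof["ptdt_deviation"], 0.0)
        assert p > 0.01

    def test_selection_on_prs_shifts_deviations(self):
        """Probands selected for high true PRS show positive deviations."""
        cohort = generate_cohort(
            SynthConfig(n_trios=1500, n_snps=150, r2_prs=0.5, dn_rate_dd=0.0,
                        n_genes_lofi=30, n_genes_dd=8, n_genes_background=10, seed=6)
        )
        prof = build_profiles(
            cohort.snp_panel, cohort.trios, cohort.summary_stats["ea"], thresholds=(0.5,)
        )
        # phenotype 0 = higher performance = selected for high cognition PRS
        dev = prof["ptdt_deviation"].to_numpy()
        y = cohort.trios["phenotype"].to_numpy()
        assert dev[y == 0].mean() > dev[y == 1].mean()
        assert dev[y == 0].mean() > 0

    def test_nt_prs_uncorrelated_with_transmitted_prs(self):
        """Under random transmission the pseudo-control score carries no
        information about the transmitted (proband) score: with p = h + d
        and nt = h - d for midparent h and transmission deviation d,
        cov(p, nt) = var(h) - var(d) = 0 per SNP (n = 5000).

        The deviation d itself is anti-correlated with nt by construction
        (r -> -1/sqrt(2)); that identity is pinned down too."""
        cohort = generate_cohort(
            SynthConfig(n_trios=5000, n_snps=120, r2_prs=0.0, n_genes_lofi=30,
                        n_genes_dd=8, n_genes_background=10, seed=8)
        )
        prof = build_profiles(
            cohort.snp_panel, cohort.trios, cohort.summary_stats["ea"], thresholds=(0.5,)
        )
        r = np.corrcoef(prof["nt_prs"], prof["proband_prs"])[0, 1]
        assert abs(r) < 0.05
        dev = prof["proband_prs"] - prof["midparent_prs"]
        r_dev = np.corrcoef(prof["nt_prs"], dev)[0, 1]
        assert r_dev == pytest.approx(-1 / np.sqrt(2), abs=0.07)
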