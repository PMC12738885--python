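"""Differential expression: preprocessing, OLS, moderation, BH, DEG calling."""

import subprocess
import textwrap
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from degbrin import dge
from degbrin.simdata import SyntheticConfig, generate_cohort


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestPreprocess:
    def test_gene_below_threshold_in_61_percent_removed(self):
        # 61 of 100 samples below threshold -> above the 60% bound -> removed
        row_bad = np.concatenate([np.zeros(61), np.full(39, 10.0)])
        row_ok = np.concatenate([np.zeros(60), np.full(40, 10.0)])
        expr = _matrix([row_bad, row_ok])
        out = dge.preprocess(expr, detection_threshold=1.0, max_below_fraction=0.6)
        assert list(out.index) == ["g1"]

    def test_clean_matrix_unchanged(self):
        expr = _matrix(np.full((3, 4), 5.0))
        out = dge.preprocess(expr, detection_threshold=1.0)
        pd.testing.assert_frame_equal(out, expr)

    def test_duplicate_gene_ids_averaged(self):
        expr = _matrix([[1.0, 3.0], [3.0, 5.0]], genes=["g", "g"])
        out = dge.preprocess(expr, detection_threshold=-np.inf)
        assert out.shape == (1, 2)
        np.testing.assert_allclose(out.loc["g"], [2.0, 4.0])

    def test_missing_value_rows_removed(self):
        expr = _matrix([[1.0, np.nan], [2.0, 3.0]])
        out = dge.preprocess(expr, detection_threshold=-np.inf)
        assert list(out.index) == ["g1"]

    def test_all_removed_raises(self):
        expr = _matrix(np.zeros((2, 10)))
        with pytest.raises(dge.EmptyResultError):
            dge.preprocess(expr, detection_threshold=1.0)


class TestFitLinearModels:
    def _groups(self, labels):
        return pd.Series(labels, index=[f"s{j}" for j in range(len(labels))])

    def test_noiseless_shift(self):
        expr = _matrix([[1.0, 1.0, 1.0, 0.0, 0.0, 0.0]])
        groups = self._groups(["MCI"] * 3 + ["CON"] * 3)
        fit = dge.fit_linear_models(expr, groups, "MCI-CON")
        assert fit.coef[0] == pytest.approx(1.0)
        assert fit.sigma[0] == pytest.approx(0.0)
        assert fit.df_residual == 4

    def test_balanced_design_variance_factor(self):
        rng = np.random.default_rng(0)
        for n in (3, 5, 8):
            expr = _matrix(rng.normal(size=(2, 2 * n)))
            groups = self._groups(["MCI"] * n + ["CON"] * n)
            fit = dge.fit_linear_models(expr, groups, "MCI-CON")
            assert fit.stdev_unscaled_sq == pytest.approx(2.0 / n)

    def test_matches_per_gene_least_squares_oracle(self):
        rng = np.random.default_rng(42)
        n1, n2 = 7, 5
        expr = _matrix(rng.normal(size=(50, n1 + n2)))
        groups = self._groups(["AD"] * n1 + ["CON"] * n2)
        fit = dge.fit_linear_models(expr, groups, "AD-CON")
        X = np.column_stack([np.ones(n1 + n2), [1.0] * n1 + [0.0] * n2])
        for g in range(50):
            y = expr.values[g]
            beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert fit.coef[g] == pytest.approx(beta[1], abs=1e-10)
            assert fit.sigma[g] ** 2 == pytest.approx(rss[0] / (n1 + n2 - 2), rel=1e-10)

    def test_small_group_rejected(self):
        expr = _matrix(np.ones((1, 4)))
        groups = self._groups(["MCI", "MCI", "MCI", "CON"])
        with pytest.raises(ValueError, match="2 samples"):
            dge.fit_linear_models(expr, groups, "MCI-CON")


class TestModerate:
    def _random_fit(self, n_genes=100, seed=0):
        rng = np.random.default_rng(seed)
        return dge.GeneFit(
            gene_ids=[f"g{i}" for i in range(n_genes)],
            coef=rng.normal(size=n_genes),
            sigma=np.sqrt(rng.chisquare(6, size=n_genes) / 6),
            df_residual=6.0,
            stdev_unscaled_sq=0.2,
        )

    def test_no_moderation_limit_equals_ordinary_t(self):
        fit = self._random_fit()
        mod = dge.moderate(fit, d0=0.0, s0_sq=1.0)
        ordinary = fit.coef / (fit.sigma * np.sqrt(fit.stdev_unscaled_sq))
        np.testing.assert_allclose(mod.t, ordinary, rtol=1e-12)

    def test_identical_variances_give_infinite_prior_df(self):
        fit = self._random_fit()
        fit.sigma = np.full_like(fit.sigma, 0.7)
        mod = dge.moderate(fit)
        assert mod.d0 >= dge.D0_CAP
        np.testing.assert_allclose(mod.sigma_tilde_sq, 0.49, rtol=1e-6)

    def test_moderated_variance_between_gene_and_prior(self):
        fit = self._random_fit(seed=3)
        mod = dge.moderate(fit)
        lo = np.minimum(fit.sigma**2, mod.s0_sq)
        hi = np.maximum(fit.sigma**2, mod.s0_sq)
        assert ((mod.sigma_tilde_sq >= lo - 1e-12) & (mod.sigma_tilde_sq <= hi + 1e-12)).all()

    def test_moderated_t_between_gene_and_prior_t(self):
        fit = self._random_fit(seed=4)
        mod = dge.moderate(fit)
        sv = np.sqrt(fit.stdev_unscaled_sq)
        t_gene = np.abs(fit.coef / (fit.sigma * sv))
        t_prior = np.abs(fit.coef / (np.sqrt(mod.s0_sq) * sv))
        lo = np.minimum(t_gene, t_prior) - 1e-9
        hi = np.maximum(t_gene, t_prior) + 1e-9
        assert ((np.abs(mod.t) >= lo) & (np.abs(mod.t) <= hi)).all()

    def test_prior_parameter_recovery_within_20_percent(self):
        d0s, s0s = [], []
        for rep in range(10):
            config = SyntheticConfig(
                n_genes=2000, n_regions=1,
                subjects_per_group={"CON": 10, "MCI": 10, "AD": 10},
                deg_per_region=0, prior_df_d0=4.0, prior_var_s0sq=0.25,
                seed=300 + rep,
            )
            expr, samples, _ = generate_cohort(config)
            groups = samples.set_index("sample_id")["group"]
            fit = dge.fit_linear_models(expr, groups, "AD-CON")
            d0, s0_sq = dge.estimate_prior(fit.sigma**2, fit.df_residual)
            d0s.append(d0)
            s0s.append(s0_sq)
        assert abs(np.median(d0s) - 4.0) / 4.0 < 0.2
        assert abs(np.median(s0s) - 0.25) / 0.25 < 0.2

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """limma's lmFit + eBayes is the independent reference implementation."""
        rng = np.random.default_rng(5)
        n1 = n2 = 6
        sigma = np.sqrt(4 * 0.25 / rng.chisquare(4, size=150))
        y = rng.normal(0, 1, size=(150, n1 + n2)) * sigma[:, None]
        y[:20, :n1] += 1.0
        expr = _matrix(y)
        groups = pd.Series(["MCI"] * n1 + ["CON"] * n2, index=expr.columns)
        fit = dge.fit_linear_models(expr, groups, "MCI-CON")
        mod = dge.moderate(fit)

        data_path = tmp_path / "expr.tsv"
        expr.to_csv(data_path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.delim("{data_path}", row.names = 1))
            design <- cbind(CON = 1, MCIvsCON = rep(c(1, 0), c({n1}, {n2})))
            fit <- eBayes(lmFit(y, design))
            out <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2])
            cat(fit$df.prior, fit$s2.prior, "\\n")
            write.table(out, "{tmp_path}/limma.tsv", sep = "\\t", quote = FALSE)
        """)
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        d0_l, s0_l = map(float, proc.stdout.split()[:2])
        limma = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        assert mod.d0 == pytest.approx(d0_l, rel=1e-3)
        assert mod.s0_sq == pytest.approx(s0_l, rel=1e-3)
        np.testing.assert_allclose(mod.t, limma["t"], rtol=1e-4)
        np.testing.assert_allclose(mod.p_value, limma["p"], rtol=1e-4, atol=1e-12)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            dge.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_degenerate_inputs(self):
        assert dge.bh_adjust([0.4])[0] == pytest.approx(0.4)
        np.testing.assert_allclose(dge.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            dge.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            dge.bh_adjust([-0.1])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(dge.bh_adjust(p), expected, rtol=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60), st.randoms())
    def test_permutation_equivariance(self, p, rnd):
        p = np.asarray(p)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        adjusted = dge.bh_adjust(p)
        np.testing.assert_allclose(dge.bh_adjust(p[perm]), adjusted[perm], rtol=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_adjusted_at_least_raw_and_bounded(self, p):
        adjusted = dge.bh_adjust(p)
        assert (adjusted >= np.asarray(p) - 1e-15).all()
        assert ((adjusted >= 0) & (adjusted <= 1)).all()


class TestCallDegs:
    def _mod(self, lfc, adj_p):
        n = len(lfc)
        return dge.ModeratedFit(
            gene_ids=[f"g{i}" for i in range(n)],
            coef=np.asarray(lfc, dtype=float),
            d0=4.0, s0_sq=0.25,
            sigma_tilde_sq=np.full(n, 0.25),
            t=np.ones(n), df_total=10.0,
            p_value=np.asarray(adj_p, dtype=float),
            adj_p_value=np.asarray(adj_p, dtype=float),
        )

    def test_threshold_combinations(self):
        mod = self._mod([0.60, 0.585, 2.0, -0.9], [0.01, 0.001, 0.06, 0.02])
        called = set(dge.call_degs(mod)["gene"])
        assert called == {"g0", "g3"}  # 0.585 exactly and adj p 0.06 excluded

    def test_thresholds_are_strict(self):
        mod = self._mod([0.586, 0.585], [0.05, 0.049])
        called = set(dge.call_degs(mod)["gene"])
        assert called == set()  # adj p 0.05 not < 0.05; lfc 0.585 not > 0.585


class TestDegsPerRegion:
    def test_region_sets_are_unions_over_contrasts(self, small_cohort, small_cohort_degs):
        _, expr, _, _ = small_cohort
        sets = small_cohort_degs.region_sets
        table = sets.deg_table
        for region, genes in sets.region_sets.items():
            assert genes == set(table.loc[table["region"] == region, "gene"])
            assert genes <= set(expr.index)

    def test_universal_list_needs_two_regions(self, small_cohort_degs):
        sets = small_cohort_degs.region_sets
        for gene in sets.universal:
            assert sets.region_frequency[gene] >= 2
        singles = set(sets.region_frequency.index[sets.region_frequency == 1])
        assert singles.isdisjoint(sets.universal)

    def test_planted_cross_region_genes_recovered(self, small_cohort, small_cohort_degs):
        _, _, _, truth = small_cohort
        pool_planted = truth.cross_region_genes() & truth.shared_pool
        recovered = pool_planted & small_cohort_degs.universal
        assert len(recovered) / len(pool_planted) >= 0.8

    def test_planted_deg_recall_above_80_percent(self, small_cohort, small_cohort_degs):
        _, _, _, truth = small_cohort
        table = small_cohort_degs.deg_table
        hits = total = 0
        for region, per_contrast in truth.planted_degs.items():
            for contrast, genes in per_contrast.items():
                called = set(
                    table.loc[
                        (table["region"] == region) & (table["contrast"] == contrast),
                        "gene",
                    ]
                )
                hits += len(genes & called)
                total += len(genes)
        assert hits / total >= 0.8

    def test_contrast_with_missing_group_skipped(self):
        config = SyntheticConfig(
            n_genes=100, n_regions=2,
            subjects_per_group={"CON": 5, "MCI": 5, "AD": 5}, seed=0,
        )
        expr, samples, _ = generate_cohort(config)
        keep = samples["group"] != "AD"
        with pytest.warns(UserWarning, match="skipping contrast"):
            sets = dge.degs_per_region(expr[samples.loc[keep, "sample_id"]], samples[keep])
        assert set(sets.region_sets) == {"R01", "R02"}

    def test_no_valid_contrast_raises(self):
        expr = _matrix(np.random.default_rng(0).normal(size=(10, 2)))
        samples = pd.DataFrame(
            {
                "sample_id": ["s0", "s1"],
                "subject_id": ["a", "b"],
                "region": ["R01", "R01"],
                "diagnosis": ["Normal", "Definite AD"],
                "group": ["CON", "AD"],
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(dge.EmptyResultError):
                dge.degs_per_region(expr, samples)


class TestTypeIControl:
    def test_null_cohort_false_positive_rate(self):
        """On null cohorts the adj p < 0.05 proportion stays within FDR bounds."""
        rates = []
        for rep in range(20):
            config = SyntheticConfig(
                n_genes=200, n_regions=2,
                subjects_per_group={"CON": 8, "MCI": 8, "AD": 8},
                deg_per_region=0, seed=600 + rep,
            )
            expr, samples, _ = generate_cohort(config)
            groups = samples.set_index("sample_id")["group"]
            n_sig = n_tot = 0
            for region, meta in samples.groupby("region"):
                sub = expr[meta["sample_id"]]
                for contrast in ("MCI-CON", "AD-CON", "MCI-AD"):
                    mod = dge.moderate(dge.fit_linear_models(sub, groups, contrast))
                    n_sig += int((mod.adj_p_value < 0.05).sum())
                    n_tot += len(mod.gene_ids)
            rates.append(n_sig / n_tot)
        assert np.mean(rates) <= 0.10


class TestRegionalDGEFacade:
    def test_summary_counts_match_tables(self, small_cohort_degs):
        summary = small_cohort_degs.summary()
        assert set(summary.columns) == {"region", "MCI-CON", "AD-CON", "MCI-AD", "union"}
        sets = small_cohort_degs.region_sets
        for _, row in summary.iterrows():
            assert row["union"] == len(sets.region_sets[row["region"]])
        assert summary.attrs["n_universal"] == len(small_cohort_degs.universal)

    def test_region_sets_json_roundtrip(self, small_cohort_degs):
        sets = small_cohort_degs.region_sets
        back = dge.RegionDEGSets.from_json_dict(sets.to_json_dict())
        assert back.region_sets == sets.region_sets
        assert back.universal == sets.universal
        assert back.min_regions == sets.min_regions
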