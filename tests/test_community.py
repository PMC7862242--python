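import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import slicksurvey as ss
from slicksurvey.community import pcoa_embedding


class TestLogTransform:
    def test_zero_preserving(self):
        M = np.array([[0.0, 0.0], [0.0, 0.0]])
        assert (ss.log_transform(M) == 0).all()

    def test_smallest_positive_maps_to_one(self):
        M = np.array([[0.0, 0.004, 0.008], [0.002, 0.0, 0.016]])
        L = ss.log_transform(M, base=2)
        assert L[1, 0] == pytest.approx(1.0)      # min positive -> 1
        assert L[0, 1] == pytest.approx(2.0)      # doubling adds 1 at base 2
        assert L[0, 2] == pytest.approx(3.0)
        assert L[1, 2] == pytest.approx(4.0)

    def test_integer_counts_not_rescaled(self):
        L = ss.log_transform(np.array([[1.0, 2.0, 8.0]]), base=2)
        np.testing.assert_allclose(L, [[1.0, 2.0, 4.0]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ss.log_transform(np.array([[-1.0]]))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        X = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [0.0, 5.0]], index=["a", "b", "c"]
        )
        D = ss.bray_curtis(X)
        assert D["a", "b"] == 0.0
        Y = pd.DataFrame([[1.0, 0.0], [0.0, 3.0]], index=["a", "b"])
        assert ss.bray_curtis(Y)["a", "b"] == 1.0

    def test_hand_computed_pair(self):
        D = ss.bray_curtis(pd.DataFrame([[1.0, 2.0], [3.0, 0.0]]))
        assert D["0", "1"] == pytest.approx(4 / 6)

    def test_bounded_and_symmetric(self, rng):
        X = rng.poisson(1.0, (10, 6)).astype(float) + 0.01
        D = ss.bray_curtis(X).data
        assert (D >= 0).all() and (D <= 1).all()
        np.testing.assert_allclose(D, D.T)

    def test_invariant_to_all_zero_taxa(self, rng):
        X = rng.poisson(1.0, (8, 5)).astype(float) + 0.01
        D1 = ss.bray_curtis(X).data
        D2 = ss.bray_curtis(np.hstack([X, np.zeros((8, 3))])).data
        np.testing.assert_allclose(D1, D2)

    def test_all_zero_pair_flagged(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            ss.bray_curtis(X)


class TestShannon:
    def test_single_taxon_zero(self):
        assert ss.shannon_index([4.0]) == 0.0

    def test_uniform_maximum(self):
        assert ss.shannon_index([2.0, 2.0, 2.0, 2.0]) == pytest.approx(np.log(4))

    def test_direct_formula(self):
        # counts (2,1,1): H = -sum p ln p = 1.0397
        assert ss.shannon_index([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_rescaling_invariance_and_bound(self, rng):
        x = rng.gamma(1.0, 1.0, 7)
        assert ss.shannon_index(x) == pytest.approx(ss.shannon_index(x * 123.4))
        assert ss.shannon_index(x) <= np.log(7) + 1e-12


class TestDbRda:
    def test_euclidean_toy_matches_classical_rda(self, rng):
        """On Euclidean distances, dbRDA equals RDA by projection algebra."""
        X = rng.normal(size=(6, 3))
        hab = np.array(["slick"] * 3 + ["ambient"] * 3)
        D = squareform(pdist(X))
        res = ss.db_rda(D, hab, n_perm=49, seed=0)
        Xc = X - X.mean(axis=0)
        g = (hab == "slick").astype(float)
        g = g - g.mean()
        fitted = np.outer(g, g) @ Xc / (g @ g)
        ss_model = (fitted**2).sum()
        ss_resid = ((Xc - fitted) ** 2).sum()
        F = ss_model / (ss_resid / (6 - 2))
        assert res.pseudo_F == pytest.approx(F, abs=1e-8)
        assert res.df_model == 1 and res.df_residual == 4

    def test_matches_vegan_capscale(self, tmp_path, rng):
        """Independent oracle: vegan's partial capscale on the same matrix."""
        n, ntaxa = 18, 7
        X = rng.poisson(4.0, (n, ntaxa)).astype(float)
        X[: n // 2] *= rng.uniform(1, 3, ntaxa)
        hab = np.array(["slick"] * (n // 2) + ["ambient"] * (n - n // 2))
        site = np.array([f"s{j % 3}" for j in range(n)])
        D = ss.bray_curtis(ss.log_transform(X))
        res = ss.db_rda(D, hab, condition=site, n_perm=49, seed=0)
        np.savetxt(tmp_path / "D.csv", D.data, delimiter=",")
        pd.DataFrame({"habitat": hab, "site": site}).to_csv(
            tmp_path / "meta.csv", index=False
        )
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            D <- as.matrix(read.csv("D.csv", header=FALSE))
            meta <- read.csv("meta.csv")
            m <- capscale(as.dist(D) ~ habitat + Condition(site), data=meta)
            a <- anova(m, permutations=19)
            cat(sprintf("%.12f %d %d", a$F[1], a$Df[1], a$Df[2]))
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], cwd=tmp_path,
            capture_output=True, text=True, check=True,
        )
        f_vegan, df1, df2 = out.stdout.split()
        assert res.pseudo_F == pytest.approx(float(f_vegan), rel=1e-8)
        assert (res.df_model, res.df_residual) == (int(df1), int(df2))

    def test_p_value_never_zero(self, rng):
        X = rng.poisson(3.0, (12, 5)).astype(float)
        X[:6] *= 10
        hab = np.array(["slick"] * 6 + ["ambient"] * 6)
        res = ss.db_rda(ss.bray_curtis(X + 0.01), hab, n_perm=199, seed=0)
        assert res.p_value >= 1 / 200

    def test_strong_shift_detected(self, sim_survey):
        """A real between-habitat composition shift gives a tiny p-value."""
        survey, _ = sim_survey
        fish = survey.taxa.loc[
            survey.taxa["functional_group"] == "fish", "taxon_id"
        ]
        dm = ss.compute_densities(
            survey, grouping="family",
            subset=survey.counts[survey.counts["taxon_id"].isin(fish)],
        )
        dm, _, _ = ss.filter_common(dm)
        dist = ss.bray_curtis(ss.log_transform(dm))
        order = list(dist.ids)
        res = ss.db_rda(
            dist,
            constraint=survey.habitat.reindex(order).values,
            condition=survey.tows.set_index("tow_id")["site"].reindex(order).values,
            n_perm=2999, seed=0,
        )
        assert res.p_value <= 0.001
        assert res.df_model == 1

    def test_constant_constraint_rejected(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            ss.db_rda(D, ["slick", "slick"], n_perm=9)

    def test_negative_inertia_recorded(self, rng):
        X = rng.poisson(2.0, (10, 4)).astype(float) + 0.01
        res = ss.db_rda(
            ss.bray_curtis(X), ["slick"] * 5 + ["ambient"] * 5, n_perm=9, seed=0
        )
        # Bray-Curtis is generally non-Euclidean: some inertia is discarded
        assert res.negative_inertia >= 0.0

    def test_pcoa_recovers_euclidean_geometry(self, rng):
        X = rng.normal(size=(7, 3))
        D = squareform(pdist(X))
        coords, evals, neg = pcoa_embedding(D)
        np.testing.assert_allclose(
            squareform(pdist(coords)), D, atol=1e-8
        )
        assert neg == pytest.approx(0.0, abs=1e-8)


class TestDiversityContrast:
    def test_group_means_and_probability(self, sim_survey):
        survey, _ = sim_survey
        dm, _, _ = ss.filter_common(ss.compute_densities(survey, grouping="family"))
        res = ss.diversity_contrast(dm, nboot=500, nperm=500, seed=0)
        hs = res.group_means.loc[("shannon_H", "slick"), "mean"]
        ha = res.group_means.loc[("shannon_H", "ambient"), "mean"]
        assert hs > 0 and ha > 0
        assert res.per_tow["richness_S"].ge(0).all()
        # simulated slicks are enriched, so diversity prob should be high
        assert res.prob_H > 0.9

    def test_empty_tow_excluded_with_warning(self):
        data = pd.DataFrame(
            {"t1": [1.0, 2.0], "t2": [0.0, 0.0], "t3": [3.0, 1.0]},
            index=["a", "b"],
        )
        habitat = pd.Series(["slick", "slick", "ambient"],
                            index=["t1", "t2", "t3"])
        dm = ss.DensityMatrix(data=data, habitat=habitat)
        with pytest.warns(UserWarning, match="empty"):
            res = ss.diversity_contrast(dm, nboot=100, nperm=100, seed=0)
        assert np.isnan(res.per_tow.loc["t2", "shannon_H"])


class TestSpearmanOverlap:
    def test_perfect_and_inverted(self):
        idx = [f"t{i}" for i in range(10)]
        fish = pd.Series(np.arange(10, dtype=float), index=idx)
        prey = pd.DataFrame({
            "same": np.arange(10, dtype=float),
            "inverse": np.arange(10, dtype=float)[::-1],
        }, index=idx)
        habitat = pd.Series(["slick"] * 5 + ["ambient"] * 5, index=idx)
        table = ss.spearman_overlap(fish, prey, habitat)
        same = table[table["prey_group"] == "same"]["r"]
        inverse = table[table["prey_group"] == "inverse"]["r"]
        assert np.allclose(same, 1.0)
        assert np.allclose(inverse, -1.0)

    def test_null_significance_rate(self, rng):
        """Independent pairs are 'significant' ~5% of the time at alpha=.05."""
        idx = [f"t{i}" for i in range(40)]
        habitat = pd.Series(["slick"] * 20 + ["ambient"] * 20, index=idx)
        hits, total = 0, 0
        for _ in range(50):
            fish = pd.Series(rng.normal(size=40), index=idx)
            prey = pd.DataFrame(rng.normal(size=(40, 8)), index=idx)
            t = ss.spearman_overlap(fish, prey, habitat, log=False)
            hits += t["significant"].sum()
            total += len(t)
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * se
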