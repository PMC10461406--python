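"""Species-by-time contrast model, BH, alpha-RRA, the final caller,
p53 flagging and variance partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats as sps

from crisprcomp.species_contrast import (AlphaRRAConfig, _rho_min_beta,
                                         adjust_pvalues, alpha_rra,
                                         call_species_specific,
                                         estimate_count_dispersion,
                                         fit_sgrna_contrast,
                                         flag_p53_dependence,
                                         variance_partition)


def reference_bh(p):
    """Textbook step-up oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestAdjustPvalues:
    def test_hand_example(self):
        assert np.allclose(adjust_pvalues([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert (adjust_pvalues([1.0] * 5) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])

    def test_matches_reference_stepup_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            adj = adjust_pvalues(p)
            assert np.allclose(adj, reference_bh(p))
            assert (adj >= p - 1e-12).all()


def contrast_design(n_ind=2, n_rep=1):
    rows = []
    for sp in ("A", "B"):
        for i in range(1, n_ind + 1):
            for r in range(1, n_rep + 1):
                for tp in ("t0", "tfinal"):
                    rows.append({"sample_id": f"{sp}{i}_R{r}_{tp}",
                                 "species": sp, "individual": f"{sp}{i}",
                                 "replicate": f"R{r}", "timepoint": tp})
    return pd.DataFrame(rows)


class TestFitSgrnaContrast:
    def test_constant_counts_give_zero_delta(self):
        design = contrast_design()
        counts = pd.DataFrame(100, index=[f"g{i}" for i in range(5)],
                              columns=design["sample_id"])
        res = fit_sgrna_contrast(counts, design, dispersion=0.0)
        assert np.allclose(res["delta_lfc"], 0.0, atol=1e-6)
        assert (res["p"] > 0.99).all()

    def test_noiseless_halving_in_species_b(self):
        # most guides flat; two guides halve between t0 and tfinal in
        # species B only -> delta log2FC = -1 exactly in the noiseless limit
        design = contrast_design()
        counts = pd.DataFrame(400, index=[f"g{i}" for i in range(12)],
                              columns=design["sample_id"])
        for g in ("g0", "g1"):
            for col in design.loc[(design["species"] == "B")
                                  & (design["timepoint"] == "tfinal"),
                                  "sample_id"]:
                counts.loc[g, col] = 200
        res = fit_sgrna_contrast(counts, design, dispersion=0.0)
        assert res.loc["g0", "delta_lfc"] == pytest.approx(-1.0, abs=0.01)
        assert res.loc["g5", "delta_lfc"] == pytest.approx(0.0, abs=0.01)

    def test_all_zero_guides_skipped(self):
        design = contrast_design()
        counts = pd.DataFrame(50, index=["g0", "dead"],
                              columns=design["sample_id"])
        counts.loc["dead"] = 0
        res = fit_sgrna_contrast(counts, design, dispersion=0.0)
        assert "dead" not in res.index

    def test_matches_statsmodels_glm(self, rng):
        # independent cross-check: statsmodels NB GLM with the same fixed
        # dispersion and design must reproduce coefficients and Wald stats
        import statsmodels.api as sm

        design = contrast_design(n_ind=3, n_rep=2)
        n = len(design)
        mu = rng.uniform(50, 500, size=4)[:, None] * np.ones((1, n))
        counts = pd.DataFrame(rng.poisson(mu),
                              index=[f"g{i}" for i in range(4)],
                              columns=design["sample_id"])
        disp = 0.05
        res = fit_sgrna_contrast(counts, design, dispersion=disp)

        from crisprcomp.species_contrast import _contrast_design
        from crisprcomp.sgrna_stats import median_ratio_normalize
        X, ia, ib, _ = _contrast_design(design, counts.columns)
        sf, _ = median_ratio_normalize(counts)
        offset = np.log(sf.to_numpy())
        for gid in counts.index:
            fit = sm.GLM(counts.loc[gid].to_numpy(), X,
                         family=sm.families.NegativeBinomial(alpha=disp),
                         offset=offset).fit()
            delta = (fit.params[ib] - fit.params[ia]) / np.log(2)
            assert res.loc[gid, "delta_lfc"] == pytest.approx(delta, abs=1e-4)
            c = np.zeros(X.shape[1]); c[ib], c[ia] = 1, -1
            se = np.sqrt(c @ fit.cov_params() @ c) / np.log(2)
            assert res.loc[gid, "se"] == pytest.approx(se, rel=1e-3)

    def test_dispersion_estimated_from_nt_trend(self, rng):
        design = contrast_design(n_ind=2, n_rep=2)
        n = len(design)
        mu = 300.0
        alpha = 0.08
        r = 1 / alpha
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(3000, n)),
            index=[f"nt{i}" for i in range(3000)],
            columns=design["sample_id"])
        nt_mask = pd.Series(True, index=counts.index)
        est = estimate_count_dispersion(counts, design, nt_mask)
        assert 0.5 * alpha <= est <= 2 * alpha


def test_species_different_flag_rule():
    from crisprcomp.species_contrast import species_different_sgrnas
    contrast = pd.DataFrame({
        "adj_p": [0.001, 0.001, 0.5, 0.005],
        "delta_lfc": [-0.9, 0.3, -2.0, 0.5],
        "p": [0.0001, 0.0001, 0.3, 0.001],
    }, index=["hit", "small_effect", "not_sig", "boundary"])
    flagged = species_different_sgrnas(contrast)
    assert set(flagged) == {"hit", "boundary"}


class TestAlphaRRA:
    def test_rho_matches_direct_beta_cdf(self):
        # percentiles (0.001, 0.002, 0.003, 0.9) with alpha=0.05: rho is the
        # minimum of BetaCDF(r_k; k, 4-k+1) over the three sub-alpha ranks
        pct = np.array([[0.001, 0.002, 0.003, 0.9]])
        rho = _rho_min_beta(pct, alpha=0.05)[0]
        oracle = min(special.betainc(k, 4 - k + 1, p)
                     for k, p in [(1, 0.001), (2, 0.002), (3, 0.003)])
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_rho_monotone_in_each_percentile(self, rng):
        base = np.sort(rng.uniform(0, 0.04, size=4))
        rho0 = _rho_min_beta(base[None, :], alpha=0.05)[0]
        for k in range(4):
            worse = base.copy()
            worse[k] = min(worse[k] * 2, 0.049)
            worse = np.sort(worse)
            assert _rho_min_beta(worse[None, :], 0.05)[0] >= rho0 - 1e-15

    def make_pvector(self, n=1000, gene_ranks=(1, 2, 3, 900)):
        # adj p proportional to rank so percentile ranks are exact
        p = pd.Series(np.arange(1, n + 1) / n,
                      index=[f"s{i}" for i in range(n)])
        genes = {f"s{r - 1}": "G" for r in gene_ranks}
        g2g = pd.Series(genes)
        return p, g2g

    def test_integration_rho_with_fixed_alpha(self):
        p, g2g = self.make_pvector()
        res = alpha_rra(p, g2g, AlphaRRAConfig(alpha=0.05, n_perm=200, seed=0))
        oracle = min(special.betainc(k, 4 - k + 1, k / 1000.0)
                     for k in (1, 2, 3))
        assert res.loc["G", "rho"] == pytest.approx(oracle, rel=1e-9)
        assert res.loc["G", "n_below_alpha"] == 3
        assert res.loc["G", "p"] < 0.05

    def test_gene_above_alpha_gets_p_one(self):
        p, _ = self.make_pvector()
        g2g = pd.Series({"s800": "G", "s900": "G"})
        res = alpha_rra(p, g2g, AlphaRRAConfig(alpha=0.05, n_perm=100, seed=0))
        assert res.loc["G", "p"] == 1.0
        assert res.loc["G", "n_below_alpha"] == 0

    def test_alpha_zero_warns_and_returns_ones(self):
        p = pd.Series([0.5, 0.6, 0.7], index=["a", "b", "c"])
        g2g = pd.Series({"a": "G", "b": "G"})
        with pytest.warns(UserWarning, match="alpha"):
            res = alpha_rra(p, g2g, AlphaRRAConfig(adj_threshold=0.01,
                                                   n_perm=50, seed=0))
        assert (res["p"] == 1.0).all()

    def test_permutation_null_pvalues_valid(self, rng):
        # random gene labels on a structured p vector: gene p must be
        # super-uniform (valid) at every level
        n = 3000
        p = pd.Series(np.sort(rng.beta(0.5, 3.0, size=n)),
                      index=[f"s{i}" for i in range(n)])
        labels = rng.permutation(np.repeat(np.arange(600), 5))
        g2g = pd.Series([f"G{k}" for k in labels[:3000]], index=p.index)
        res = alpha_rra(p, g2g, AlphaRRAConfig(alpha=0.1, n_perm=2000, seed=4))
        for q in (0.01, 0.05, 0.1, 0.25):
            frac = (res["p"] <= q).mean()
            se = np.sqrt(q * (1 - q) / len(res))
            assert frac <= q + 3 * se + 1 / 2000


class TestCallSpeciesSpecific:
    def tables(self):
        rra_c = pd.DataFrame({
            "fdr": [0.005, 0.005, 0.2, 0.005, 0.5],
            "n_below_alpha": [4, 2, 1, 3, 0],
        }, index=["hit", "fewguides", "weak", "sharedhit", "null"])
        rra_a = pd.DataFrame({"fdr": [0.001, 0.001, 0.5, 0.10, 1.0]},
                             index=rra_c.index)
        rra_b = pd.DataFrame({"fdr": [0.9, 0.9, 0.5, 0.15, 1.0]},
                             index=rra_c.index)
        lfc_a = pd.Series([-2.0, -2.0, -0.5, -2.0, 0.0], index=rra_c.index)
        lfc_b = pd.Series([-1.1, -1.1, -0.3, -1.2, 0.0], index=rra_c.index)
        return rra_c, rra_a, rra_b, lfc_a, lfc_b

    def test_three_conditions_and_exclusion(self):
        rra_c, rra_a, rra_b, lfc_a, lfc_b = self.tables()
        out = call_species_specific(rra_c, rra_a, rra_b, lfc_a, lfc_b)
        # exclusion threshold = max FDR among genes with >=1 passing guide
        assert out.attrs["exclusion_threshold"] == pytest.approx(0.2)
        assert out.loc["hit", "call"] == "speciesA-specific"
        assert out.loc["fewguides", "call"] == "none"      # < 3 guides
        assert out.loc["weak", "call"] == "none"           # FDR too high
        # significant in both species terms below the threshold -> shared
        assert out.loc["sharedhit", "excluded_shared"]
        assert out.loc["sharedhit", "call"] == "none"
        assert out.loc["null", "call"] == "none"

    def test_lfc_difference_threshold(self):
        rra_c, rra_a, rra_b, lfc_a, lfc_b = self.tables()
        lfc_b["hit"] = -1.5  # |diff| = 0.5 < 0.75
        out = call_species_specific(rra_c, rra_a, rra_b, lfc_a, lfc_b)
        assert out.loc["hit", "call"] == "none"

    def test_invariant_to_gene_order(self):
        rra_c, rra_a, rra_b, lfc_a, lfc_b = self.tables()
        order = ["null", "weak", "hit", "sharedhit", "fewguides"]
        out1 = call_species_specific(rra_c, rra_a, rra_b, lfc_a, lfc_b)
        out2 = call_species_specific(rra_c.loc[order], rra_a.loc[order],
                                     rra_b.loc[order], lfc_a.loc[order],
                                     lfc_b.loc[order])
        assert out1["call"].sort_index().equals(out2["call"].sort_index())


class TestFlagP53:
    def test_equal_group_means_not_flagged(self):
        scores = pd.DataFrame({"u1": [1.0], "u2": [2.0],
                               "r1": [1.0], "r2": [2.0],
                               "r3": [1.0], "r4": [2.0]}, index=["G"])
        out = flag_p53_dependence(scores, ["r1", "r2", "r3", "r4"],
                                  ["u1", "u2"])
        assert out.loc["G", "p"] > 0.9
        assert not out.loc["G", "p53_flagged"]

    def test_separated_groups_flagged(self, rng):
        jitter = rng.normal(0, 1e-3, size=6)
        scores = pd.DataFrame(
            [[-3 + jitter[0], -3 + jitter[1], 0 + jitter[2], 0 + jitter[3],
              0 + jitter[4], 0 + jitter[5]]],
            columns=["u1", "u2", "r1", "r2", "r3", "r4"], index=["G"])
        out = flag_p53_dependence(scores, ["r1", "r2", "r3", "r4"],
                                  ["u1", "u2"])
        assert out.loc["G", "p"] < 0.01
        assert out.loc["G", "p53_flagged"]

    def test_constant_gene_reported_undefined(self):
        scores = pd.DataFrame(0.0, index=["G"],
                              columns=["u1", "u2", "r1", "r2"])
        out = flag_p53_dependence(scores, ["r1", "r2"], ["u1", "u2"])
        assert out.loc["G", "p"] == 1.0
        assert out.loc["G", "undefined"]

    def test_small_group_errors(self):
        scores = pd.DataFrame(0.0, index=["G"], columns=["u1", "r1", "r2"])
        with pytest.raises(ValueError, match="unresponsive"):
            flag_p53_dependence(scores, ["r1", "r2"], ["u1"])


def vp_design(n_ind=3, n_rep=2):
    rows = []
    for sp in ("A", "B"):
        for i in range(1, n_ind + 1):
            for tp in ("t0", "tfinal"):
                for r in range(1, n_rep + 1):
                    rows.append({"sample_id": f"{sp}{i}_{tp}_R{r}",
                                 "species": sp, "individual": f"{sp}{i}",
                                 "replicate": f"R{r}", "timepoint": tp})
    return pd.DataFrame(rows)


class TestVariancePartition:
    def simulate(self, rng, sd_species, sd_indiv, sd_resid, n_sgrna=500,
                 sd_tp=0.0):
        design = vp_design()
        n = len(design)
        sp = design["species"].to_numpy()
        ind = design["individual"].to_numpy()
        tp = design["timepoint"].to_numpy()
        Y = np.zeros((n_sgrna, n))
        for g in range(n_sgrna):
            sp_eff = {s: rng.normal(0, sd_species) for s in np.unique(sp)}
            ind_eff = {i: rng.normal(0, sd_indiv) for i in np.unique(ind)}
            tp_eff = {t: rng.normal(0, sd_tp) for t in np.unique(tp)}
            Y[g] = ([sp_eff[s] for s in sp]
                    + np.array([ind_eff[i] for i in ind])
                    + np.array([tp_eff[t] for t in tp])
                    + rng.normal(0, sd_resid, size=n))
        values = pd.DataFrame(Y, index=[f"g{i}" for i in range(n_sgrna)],
                              columns=design["sample_id"])
        return values, design

    def test_pure_species_shift(self, rng):
        design = vp_design()
        base = rng.normal(0, 1e-4, size=(3, len(design)))
        base[:, (design["species"] == "B").to_numpy()] += 5.0
        values = pd.DataFrame(base, index=["g1", "g2", "g3"],
                              columns=design["sample_id"])
        fracs = variance_partition(values, design)
        assert (fracs["species"] > 0.99).all()

    def test_recovers_simulated_components(self, rng):
        # variances (species, individual, residual) = (1, 1, 2)
        values, design = self.simulate(rng, 1.0, 1.0, np.sqrt(2.0))
        fracs = variance_partition(values, design)
        means = fracs.mean()
        assert means["species"] == pytest.approx(0.25, abs=0.1)
        assert means["individual"] == pytest.approx(0.25, abs=0.1)
        assert means["residual"] == pytest.approx(0.50, abs=0.1)
        assert np.allclose(fracs.sum(axis=1), 1.0)

    def test_permuted_species_labels_lose_species_fraction(self, rng):
        values, design = self.simulate(rng, 1.0, 0.0, 1.0, n_sgrna=200)
        permuted = design.copy()
        permuted["species"] = rng.permutation(design["species"].to_numpy())
        permuted["individual"] = rng.permutation(
            design["individual"].to_numpy())
        real = variance_partition(values, design).mean()
        null = variance_partition(values, permuted).mean()
        assert null["species"] < real["species"] / 2

    def test_gene_level_means(self, rng):
        values, design = self.simulate(rng, 1.0, 1.0, 1.0, n_sgrna=10)
        g2g = pd.Series(["G1"] * 5 + ["G2"] * 5, index=values.index)
        fracs, gene_means = variance_partition(values, design, g2g)
        assert set(gene_means.index) == {"G1", "G2"}
        assert gene_means.loc["G1", "species"] == pytest.approx(
            fracs.iloc[:5]["species"].mean())

    def test_confounded_design_names_aliased_factors(self, rng):
        design = vp_design(n_rep=1)
        # make timepoint perfectly aliased with species
        design["timepoint"] = np.where(design["species"] == "A",
                                       "t0", "tfinal")
        values = pd.DataFrame(rng.normal(size=(3, len(design))),
                              columns=design["sample_id"])
        with pytest.raises(ValueError, match="aliased"):
            variance_partition(values, design)
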