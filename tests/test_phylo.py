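"""Taxonomy trees, Pagel-lambda covariance and OLS/PGLS model ranking."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from katydid_hotspots import phylo


def taxonomy_frame(rows):
    return pd.DataFrame(rows, columns=["species_id", "subfamily", "genus", "subgenus"])


@pytest.fixture()
def small_taxonomy():
    return taxonomy_frame(
        [
            ("a", "SF1", "G1", "S1"),
            ("b", "SF1", "G1", "S1"),
            ("c", "SF1", "G2", "S2"),
            ("d", "SF2", "G3", ""),
        ]
    )


class TestTaxonomyTree:
    def test_cherry_tip_distance_is_two(self, small_taxonomy):
        tree = phylo.taxonomy_to_tree(small_taxonomy)
        C = phylo.brownian_covariance(tree, tip_order=["a", "b", "c", "d"])
        d_ab = C.loc["a", "a"] + C.loc["b", "b"] - 2 * C.loc["a", "b"]
        assert d_ab == 2.0

    def test_congeners_closer_than_cross_genus(self, small_taxonomy):
        tree = phylo.taxonomy_to_tree(small_taxonomy)
        C = phylo.brownian_covariance(tree)

        def dist(i, j):
            return C.loc[i, i] + C.loc[j, j] - 2 * C.loc[i, j]

        assert dist("a", "b") < dist("a", "c") < dist("a", "d")

    def test_species_without_subgenus_attach_at_genus(self, small_taxonomy):
        tree = phylo.taxonomy_to_tree(small_taxonomy)
        depths = {
            leaf.taxon.label: leaf.distance_from_root() for leaf in tree.leaf_node_iter()
        }
        assert depths["a"] == 4.0  # subfamily, genus, subgenus, tip
        assert depths["d"] == 3.0  # no subgenus level

    def test_duplicate_species_rejected(self, small_taxonomy):
        dup = pd.concat([small_taxonomy, small_taxonomy.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            phylo.taxonomy_to_tree(dup)

    def test_structure_on_synthetic_pool(self, sim_dataset):
        traits = sim_dataset.traits
        tree = phylo.taxonomy_to_tree(traits)
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        assert sorted(tips) == sorted(traits["species_id"])
        newick = phylo.tree_to_newick(tree)
        reread = dendropy.Tree.get(data=newick, schema="newick")
        assert len(reread.leaf_nodes()) == len(tips)


class TestLambdaCovariance:
    def test_endpoints(self, small_taxonomy):
        tree = phylo.taxonomy_to_tree(small_taxonomy)
        C = phylo.brownian_covariance(tree)
        v0 = phylo.lambda_covariance(C, 0.0)
        assert np.allclose(v0.to_numpy(), np.diag(np.diag(C.to_numpy())))
        v1 = phylo.lambda_covariance(C, 1.0)
        assert np.allclose(v1.to_numpy(), C.to_numpy())

    def test_half_lambda_on_three_tip_tree(self):
        tax = taxonomy_frame(
            [("a", "SF1", "G1", "S1"), ("b", "SF1", "G1", "S1"), ("c", "SF1", "G2", "S2")]
        )
        C = phylo.brownian_covariance(phylo.taxonomy_to_tree(tax), tip_order=["a", "b", "c"])
        # shared depth of the (a, b) cherry is 3 (subfamily+genus+subgenus)
        v = phylo.lambda_covariance(C, 0.5)
        assert v.loc["a", "b"] == 0.5 * 3.0
        assert v.loc["a", "a"] == C.loc["a", "a"]

    def test_psd_for_lambda_in_unit_interval(self, sim_dataset):
        tree = phylo.taxonomy_to_tree(sim_dataset.traits.head(40))
        C = phylo.brownian_covariance(tree)
        for lam in (0.0, 0.3, 0.7, 1.0):
            eig = np.linalg.eigvalsh(phylo.lambda_covariance(C, lam).to_numpy())
            assert eig.min() > -1e-9

    def test_out_of_range_lambda_rejected(self, small_taxonomy):
        C = phylo.brownian_covariance(phylo.taxonomy_to_tree(small_taxonomy))
        with pytest.raises(ValueError):
            phylo.lambda_covariance(C, 1.5)


@pytest.fixture(scope="module")
def pool():
    rng = np.random.default_rng(99)
    rows = []
    k = 0
    for sf in range(6):
        for g in range(3):
            for sg in range(2):
                for _ in range(2):
                    rows.append((f"t{k:03d}", f"SF{sf}", f"SF{sf}_G{g}", f"SG{sg}"))
                    k += 1
    tax = taxonomy_frame(rows)
    tree = phylo.taxonomy_to_tree(tax)
    C = phylo.brownian_covariance(tree, tip_order=list(tax["species_id"]))
    return tax, tree, C, rng


class TestComparativeFits:

    def test_pgls_at_lambda_zero_equals_ols(self, pool):
        tax, tree, C, rng = pool
        ids = list(tax["species_id"])
        y = pd.Series(rng.normal(size=len(ids)), index=ids, name="y")
        X = pd.DataFrame({"x": rng.normal(size=len(ids))}, index=ids)
        ols = phylo.fit_comparative(y, X, C, mode="OLS")
        pgls0 = phylo.fit_comparative(y, X, C, mode="PGLS", lam=0.0)
        for k in ols.coefficients:
            assert pgls0.coefficients[k] == pytest.approx(ols.coefficients[k], abs=1e-8)

    def test_ml_lambda_beats_endpoints(self, pool):
        tax, tree, C, rng = pool
        ids = list(tax["species_id"])
        L = np.linalg.cholesky(phylo.lambda_covariance(C, 0.6).to_numpy())
        y = pd.Series(L @ rng.standard_normal(len(ids)), index=ids, name="y")
        X = pd.DataFrame({"x": rng.normal(size=len(ids))}, index=ids)
        fit = phylo.fit_comparative(y, X, C, mode="PGLS")
        for lam in (0.0, 1.0):
            pinned = phylo.fit_comparative(y, X, C, mode="PGLS", lam=lam)
            assert fit.loglik >= pinned.loglik - 1e-9

    def test_nested_interaction_model_has_higher_loglik(self, pool):
        tax, tree, C, rng = pool
        ids = list(tax["species_id"])
        scores = pd.DataFrame(
            {
                "T": rng.integers(0, 4, len(ids)),
                "D": rng.integers(0, 4, len(ids)),
                "LH": rng.integers(0, 4, len(ids)),
                "M": rng.integers(0, 3, len(ids)),
                "Tr": rng.integers(0, 4, len(ids)),
            },
            index=pd.Index(ids, name="species_id"),
        ).astype(float)
        y = scores["T"]
        main = phylo.fit_comparative(y, scores[["D", "LH"]], C, mode="OLS")
        inter = phylo.fit_comparative(
            y,
            scores[["D", "LH"]].assign(**{"D:LH": scores["D"] * scores["LH"]}),
            C,
            mode="OLS",
        )
        assert inter.loglik >= main.loglik - 1e-9


class TestRanking:
    def _fit(self, label, loglik, k, ids=("a", "b", "c")):
        return phylo.ComparativeFit(
            model_label=label, mode="OLS", coefficients={},
            loglik=loglik, aic=2 * k - 2 * loglik, lam=None, n=3, k=k, obs_ids=tuple(ids),
        )

    def test_aic_penalty_breaks_loglik_ties(self):
        simple = self._fit("simple", -10.0, 3)
        complex_ = self._fit("complex", -10.0, 4)
        table = phylo.rank_models([complex_, simple])
        assert table.iloc[0]["model"] == "simple"

    def test_rank_order_preserved_under_loglik_shift(self):
        fits = [self._fit(f"m{i}", -10.0 - i, 3) for i in range(4)]
        shifted = [self._fit(f"m{i}", -10.0 - i + 100.0, 3) for i in range(4)]
        t1 = phylo.rank_models(fits)
        t2 = phylo.rank_models(shifted)
        assert list(t1["model"]) == list(t2["model"])
        d1 = np.diff(t1["AIC"])
        d2 = np.diff(t2["AIC"])
        assert np.allclose(d1, d2)

    def test_differing_observations_rejected(self):
        with pytest.raises(ValueError, match="differing"):
            phylo.rank_models([self._fit("a", -1, 3), self._fit("b", -1, 3, ids=("x", "y", "z"))])

    def test_sixteen_model_set_on_synthetic_scores(self, sim_dataset, sim_metrics):
        scores = sim_metrics["scores"]
        traits = sim_dataset.traits
        traits = traits[traits["species_id"].isin(scores["species_id"])]
        tree = phylo.taxonomy_to_tree(traits)
        table = phylo.fit_model_set(scores, tree)
        assert len(table) == 16
        assert (table["AIC"].diff().dropna() >= -1e-9).all()  # sorted ascending
        assert table.loc[table["mode"] == "PGLS", "lambda"].between(0, 1).all()
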