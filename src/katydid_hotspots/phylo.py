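"""Taxonomy-derived trees and OLS/PGLS comparative regression with Pagel's lambda.

Lacking a molecular phylogeny, the tree is the taxonomic hierarchy
subfamily -> genus -> subgenus -> species as nested polytomies with every
branch length equal to one (a deliberately conservative tree: within-rank
relationships are unresolved, between-rank relatedness ordering is preserved).
PGLS fits a Gaussian GLS model whose error covariance is the Brownian
shared-path matrix with off-diagonals multiplied by Pagel's lambda, estimated
by bounded maximum likelihood on [0, 1]; OLS is the lambda-free Gaussian ML
fit.  Models are compared by AIC.

The covariance matrix needs a root; the basal subfamily polytomy serves as
one (an unrooted taxonomy has no defined root-to-tip covariance, so rooting
at the basal polytomy is this module's documented convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "ComparativeFit",
    "taxonomy_to_tree",
    "tree_to_newick",
    "brownian_covariance",
    "lambda_covariance",
    "fit_comparative",
    "rank_models",
    "table2_model_set",
    "fit_model_set",
]


@dataclass
class ComparativeFit:
    model_label: str
    mode: str  # "OLS" | "PGLS"
    coefficients: dict
    loglik: float
    aic: float
    lam: float | None
    n: int
    k: int
    obs_ids: tuple


def taxonomy_to_tree(taxonomy: pd.DataFrame) -> dendropy.Tree:
    """Build the nested-polytomy taxonomy tree with unit branch lengths.

    ``taxonomy`` needs columns species_id, subfamily, genus and optionally
    subgenus (empty/NaN = attach the species at genus level).  Tips are
    labelled by species_id.
    """
    ids = taxonomy["species_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate species ids: {dupes}")
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node.edge.length = 0.0
    sf_nodes, g_nodes, sg_nodes = {}, {}, {}
    has_subgenus = "subgenus" in taxonomy.columns
    for rec in taxonomy.to_dict("records"):
        sf, g = rec["subfamily"], rec["genus"]
        sg = rec.get("subgenus", "") if has_subgenus else ""
        if pd.isna(sg):
            sg = ""
        if sf not in sf_nodes:
            node = tree.seed_node.new_child(edge_length=1.0)
            sf_nodes[sf] = node
        if (sf, g) not in g_nodes:
            node = sf_nodes[sf].new_child(edge_length=1.0)
            g_nodes[(sf, g)] = node
        parent = g_nodes[(sf, g)]
        if sg:
            if (sf, g, sg) not in sg_nodes:
                node = parent.new_child(edge_length=1.0)
                sg_nodes[(sf, g, sg)] = node
            parent = sg_nodes[(sf, g, sg)]
        tip = parent.new_child(edge_length=1.0)
        tip.taxon = taxon_ns.new_taxon(label=rec["species_id"])
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def brownian_covariance(tree: dendropy.Tree, tip_order=None) -> pd.DataFrame:
    """Brownian covariance: C_ij = shared root-to-MRCA path length, C_ii = tip depth."""
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if tip_order is None:
        tip_order = tips
    idx = {lab: i for i, lab in enumerate(tip_order)}
    n = len(tip_order)
    C = np.zeros((n, n))
    # depth of every node from the root
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    # postorder: C_ij = depth of the MRCA, assigned when tips first meet
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            C[i, i] = depth[node]
            below[node] = [i]
        else:
            kids = [below[ch] for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = d
            below[node] = [i for k in kids for i in k]
    return pd.DataFrame(C, index=list(tip_order), columns=list(tip_order))


def lambda_covariance(tree_or_C, lam: float, tip_order=None) -> pd.DataFrame:
    """Pagel's lambda transform: off-diagonals scaled by lam, diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = (
        tree_or_C
        if isinstance(tree_or_C, pd.DataFrame)
        else brownian_covariance(tree_or_C, tip_order)
    )
    V = C.to_numpy() * lam
    np.fill_diagonal(V, np.diag(C.to_numpy()))
    return pd.DataFrame(V, index=C.index, columns=C.columns)


def _gls_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Gaussian ML log-likelihood with the scale profiled out; returns (ll, beta, sigma2)."""
    n = len(y)
    c, low = linalg.cho_factor(V, lower=True)
    yi = linalg.cho_solve((c, low), y)
    xi = linalg.cho_solve((c, low), X)
    beta = linalg.solve(X.T @ xi, X.T @ yi, assume_a="pos")
    r = y - X @ beta
    ri = linalg.cho_solve((c, low), r)
    sigma2 = float(r @ ri) / n
    logdet = 2.0 * np.log(np.diag(c)).sum()
    ll = -0.5 * (n * np.log(2.0 * np.pi) + n * np.log(max(sigma2, 1e-300)) + logdet + n)
    return ll, beta, sigma2


def fit_comparative(
    y: pd.Series,
    X: pd.DataFrame,
    tree: dendropy.Tree | pd.DataFrame,
    mode: str = "PGLS",
    label: str | None = None,
    lam: float | None = None,
    tol: float = 1e-6,
) -> ComparativeFit:
    """Fit one OLS or PGLS model of ``y`` on ``X`` (intercept added here).

    ``y``/``X`` are indexed by species_id and must match the tree's tips.
    PGLS estimates lambda by bounded ML on [0, 1] unless ``lam`` pins it.
    AIC = 2k - 2 logLik with k = #coefficients + 1 (residual scale) + 1 if
    lambda was estimated.
    """
    obs = list(y.index)
    Xd = np.column_stack([np.ones(len(obs)), X.loc[obs].to_numpy(float)])
    names = ["intercept", *X.columns]
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("singular design matrix")
    if len(obs) <= Xd.shape[1]:
        raise ValueError("need more observations than parameters")
    yv = y.to_numpy(float)
    if mode == "OLS":
        ll, beta, _ = _gls_loglik(yv, Xd, np.eye(len(obs)))
        k = Xd.shape[1] + 1
        lam_hat = None
    elif mode == "PGLS":
        C = (
            tree
            if isinstance(tree, pd.DataFrame)
            else brownian_covariance(tree, tip_order=obs)
        )
        missing = set(obs) - set(C.index)
        if missing:
            raise ValueError(f"observations not on tree: {sorted(missing)}")
        C = C.loc[obs, obs]

        def nll(l):
            return -_gls_loglik(yv, Xd, lambda_covariance(C, l).to_numpy())[0]

        if lam is None:
            res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                           options={"xatol": tol})
            candidates = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, float(res.x))]
            _, lam_hat = min(candidates)
            k = Xd.shape[1] + 2
        else:
            lam_hat = float(lam)
            k = Xd.shape[1] + 2
        ll, beta, _ = _gls_loglik(yv, Xd, lambda_covariance(C, lam_hat).to_numpy())
    else:
        raise ValueError(f"mode must be OLS or PGLS, got {mode!r}")
    if label is None:
        label = f"{y.name or 'y'} ~ {' + '.join(X.columns)} ({mode})"
    return ComparativeFit(
        model_label=label,
        mode=mode,
        coefficients=dict(zip(names, map(float, beta))),
        loglik=float(ll),
        aic=float(2 * k - 2 * ll),
        lam=lam_hat,
        n=len(obs),
        k=k,
        obs_ids=tuple(obs),
    )


def rank_models(fits) -> pd.DataFrame:
    """Rank fits by ascending AIC (ties broken by fewer parameters).

    All fits must be on identical observations or the comparison is invalid.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    ids0 = fits[0].obs_ids
    if any(f.obs_ids != ids0 for f in fits[1:]):
        raise ValueError("fits were made on differing observations; AICs not comparable")
    ordered = sorted(fits, key=lambda f: (f.aic, f.k))
    return pd.DataFrame(
        {
            "rank": range(1, len(ordered) + 1),
            "model": [f.model_label for f in ordered],
            "mode": [f.mode for f in ordered],
            "AIC": [f.aic for f in ordered],
            "logLik": [f.loglik for f in ordered],
            "lambda": [f.lam if f.mode == "PGLS" else np.nan for f in ordered],
        }
    )


def table2_model_set():
    """The 16-model comparison set: T on D/LH/M/Tr and their interactions,
    plus D on LH; each as OLS and PGLS."""
    specs = [
        ("D", ("LH",)),
        ("T", ("D", "LH")),
        ("T", ("D", "M")),
        ("T", ("D",)),
        ("T", ("D", "Tr")),
        ("T", ("LH",)),
        ("T", ("M",)),
        ("T", ("Tr",)),
    ]
    return [(dep, ind, mode) for dep, ind in specs for mode in ("OLS", "PGLS")]


def _design(scores: pd.DataFrame, ind) -> pd.DataFrame:
    X = scores[list(ind)].astype(float).copy()
    if len(ind) == 2:  # two-predictor rows include the interaction
        X[f"{ind[0]}:{ind[1]}"] = X[ind[0]] * X[ind[1]]
    return X


def fit_model_set(scores: pd.DataFrame, tree, models=None) -> pd.DataFrame:
    """Fit and rank the comparative model set on a species score table.

    ``scores`` is indexed by (or contains) species_id with columns T, D, M,
    Tr, LH.  Returns the ranked AIC table.
    """
    if "species_id" in scores.columns:
        scores = scores.set_index("species_id")
    C = brownian_covariance(tree, tip_order=list(scores.index))
    fits = []
    for dep, ind, mode in models or table2_model_set():
        y = scores[dep].astype(float)
        y.name = dep
        X = _design(scores, ind)
        label = f"{dep} ~ {' * '.join(ind) if len(ind) > 1 else ind[0]}"
        fits.append(fit_comparative(y, X, C, mode=mode, label=label))
    return rank_models(fits)
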