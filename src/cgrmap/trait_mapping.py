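"""Genotype-phenotype mapping on the pan-genome and phylogenetic signal.

Workflow: call metabolizer strains from a culture screen (ANOVA + Dunnett
many-to-one comparisons against vehicle controls), collapse co-occurring
presence/absence columns into features, rank features by random-forest mean
decrease in Gini impurity, flag features whose presence pattern perfectly
separates the phenotype (with a two-sided Fisher exact p), and test whether
the phenotype tracks the phylogeny with Blomberg's K.

Blomberg's K compares the observed partitioning of trait variance on the
tree to the Brownian-motion expectation:

    K = (MSE0 / MSE) / E[MSE0 / MSE]

with MSE0 the variance around the phylogenetically-corrected mean a^ =
(1'V^-1 x)/(1'V^-1 1), MSE the generalized least-squares error
(x - a^1)'V^-1(x - a^1)/(n-1), and E[MSE0/MSE] =
[tr(V) - n/(1'V^-1 1)]/(n-1). K ~ 1 under Brownian evolution, K ~ 0 when
close relatives resemble each other no more than distant ones. Significance
comes from permuting trait values across tips and comparing MSE (lower MSE
means more signal), with the observed configuration counted among the
permutations so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .pangenome import PangenomeMatrix
from .phylo import tree_vcv

METABOLIZER = "metabolizer"
NON_METABOLIZER = "non-metabolizer"


def percent_conversion(digoxin: float, dihydrodigoxin: float) -> float:
    """Percent conversion of substrate to product: 100*DHD/(DHD+digoxin)."""
    if digoxin < 0 or dihydrodigoxin < 0:
        raise ValueError("concentrations must be non-negative")
    total = digoxin + dihydrodigoxin
    if total == 0:
        raise ValueError("percent conversion undefined: both concentrations zero")
    return 100.0 * dihydrodigoxin / total


def screen_metabolizers(replicates: Mapping[str, Sequence[float]],
                        control: Sequence[float],
                        alpha: float = 0.05) -> tuple[set[str], pd.DataFrame]:
    """Metabolizer calls from replicate product measurements vs vehicle controls.

    One-way ANOVA across all groups, then Dunnett many-to-one comparisons
    against the control; a strain is called a metabolizer when its adjusted
    p is below ``alpha`` and its mean exceeds the control mean. Returns the
    called set and a per-strain table (mean, dunnett_p, metabolizer).
    """
    strains = sorted(replicates)
    groups = [np.asarray(replicates[s], dtype=float) for s in strains]
    ctrl = np.asarray(control, dtype=float)
    if len(ctrl) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 replicates per strain and for the control")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(ctrl) == 0:
        raise ValueError("zero variance in every group")
    stats.f_oneway(ctrl, *groups)  # overall test (reported via Dunnett below)
    res = stats.dunnett(*groups, control=ctrl)
    pvals = np.asarray(res.pvalue)
    called = set()
    rows = []
    for s, g, p in zip(strains, groups, pvals):
        hit = bool(p < alpha and g.mean() > ctrl.mean())
        if hit:
            called.add(s)
        rows.append((s, float(g.mean()), float(p), hit))
    table = pd.DataFrame(rows, columns=["strain_id", "mean", "dunnett_p",
                                        "metabolizer"])
    return called, table


# ---------------------------------------------------------------------------
# Feature collapsing and importance


def collapse_features(matrix: PangenomeMatrix
                      ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Merge presence/absence columns with identical patterns into features.

    The feature keeps the id of its first member column (column order of the
    matrix), so the transform is order-stable; returns the collapsed boolean
    matrix and {feature_id: member cluster ids}.
    """
    presence = matrix.presence
    if presence.empty:
        raise ValueError("empty matrix")
    pattern_to_feature: dict[bytes, str] = {}
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for col in presence.columns:
        key = presence[col].to_numpy().tobytes()
        feat = pattern_to_feature.get(key)
        if feat is None:
            pattern_to_feature[key] = col
            groups[col] = [col]
            order.append(col)
        else:
            groups[feat].append(col)
    collapsed = presence[order].copy()
    return collapsed, groups


def _phenotype_array(collapsed: pd.DataFrame,
                     phenotype: Mapping[str, str]) -> np.ndarray:
    missing = [g for g in collapsed.index if g not in phenotype]
    if missing:
        raise ValueError(f"phenotype missing for genome(s): {missing}")
    y = np.array([phenotype[g] == METABOLIZER for g in collapsed.index])
    if y.all() or not y.any():
        raise ValueError("phenotype has a single class")
    return y


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]
    (hypergeometric enumeration of tables at fixed margins)."""
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])


def exact_discriminators(collapsed: pd.DataFrame,
                         phenotype: Mapping[str, str]) -> pd.DataFrame:
    """Features whose presence pattern equals the phenotype or its complement.

    Absence is as discriminative as presence. Each feature gets a two-sided
    Fisher exact p from its 2x2 presence-by-phenotype table.
    """
    y = _phenotype_array(collapsed, phenotype)
    rows = []
    for col in collapsed.columns:
        x = collapsed[col].to_numpy()
        perfect = bool(np.array_equal(x, y) or np.array_equal(x, ~y))
        a = int((x & y).sum())
        b = int((x & ~y).sum())
        c = int((~x & y).sum())
        d = int((~x & ~y).sum())
        rows.append((col, perfect, fisher_exact_p(a, b, c, d)))
    return pd.DataFrame(rows, columns=["feature", "perfect_discriminator",
                                       "fisher_p"])


def rf_gini_importance(collapsed: pd.DataFrame, phenotype: Mapping[str, str],
                       n_trees: int = 500, mtry: int | None = None,
                       seed: int = 0, top_n: int = 15,
                       group_map: Mapping[str, list[str]] | None = None
                       ) -> pd.DataFrame:
    """Random-forest variable importance (mean decrease Gini) per feature.

    A forest of ``n_trees`` CART trees on bootstrap samples, ``mtry``
    features per split (default floor(sqrt(p))), Gini impurity splits.
    Importance is the mean over trees of the total (sample-weighted)
    impurity decrease attributed to the feature. The returned table is
    sorted by descending importance with rank, a top-``top_n`` flag, the
    perfect-discriminator flag, Fisher exact p, and member cluster ids.
    """
    y = _phenotype_array(collapsed, phenotype)
    X = collapsed.to_numpy(dtype=np.float64)
    p = X.shape[1]
    if mtry is None:
        mtry = max(1, int(np.sqrt(p)))
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features=mtry,
        bootstrap=True, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    # unnormalized per-tree impurity decrease == mean decrease Gini convention
    imp = np.mean(
        [t.tree_.compute_feature_importances(normalize=False)
         for t in forest.estimators_], axis=0)
    table = pd.DataFrame({"feature": collapsed.columns,
                          "mean_decrease_gini": imp})
    exact = exact_discriminators(collapsed, phenotype)
    table = table.merge(exact, on="feature")
    table = table.sort_values(["mean_decrease_gini", "feature"],
                              ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    table["top"] = table["rank"] <= top_n
    if group_map is not None:
        table["member_clusters"] = table["feature"].map(
            lambda f: ",".join(group_map.get(f, [f])))
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Blomberg's K


@dataclass
class KResult:
    K: float
    MSE0: float
    MSE: float
    expected_ratio: float
    p_perm: float
    n_perm: int
    seed: int


def _k_components(V: np.ndarray, x: np.ndarray):
    n = len(x)
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    denom = ones @ Vinv @ ones
    a_hat = (ones @ Vinv @ x) / denom
    resid = x - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ Vinv @ resid) / (n - 1)
    expected = (np.trace(V) - n / denom) / (n - 1)
    return mse0, mse, float(expected), Vinv, denom


def blomberg_k(tree: dendropy.Tree, trait: Mapping[str, float],
               n_perm: int = 1000, seed: int = 0,
               permute_on: str = "mse") -> KResult:
    """Blomberg's K phylogenetic-signal statistic with a permutation p-value.

    ``trait`` maps tip labels to values; its key set must equal the tree's
    tips and n must be at least 4. The p-value is the fraction of ``n_perm``
    tip-label permutations (the observed configuration included) with MSE at
    most the observed MSE (``permute_on="mse"``; ``"k"`` compares on K >=
    observed instead).
    """
    labels, V = tree_vcv(tree)
    if set(labels) != set(trait):
        raise ValueError("trait keys must equal the tree's tip labels")
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 tips")
    x = np.array([trait[t] for t in labels], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("phylogenetic covariance matrix is singular")

    mse0, mse, expected, Vinv, denom = _k_components(V, x)
    k_obs = (mse0 / mse) / expected

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm - 1)])
    if len(perms):
        ones = np.ones(n)
        a_hats = (perms @ Vinv @ ones) / denom
        resid = perms - a_hats[:, None]
        mse_perm = np.einsum("bi,ij,bj->b", resid, Vinv, resid) / (n - 1)
        if permute_on == "mse":
            more_signal = mse_perm <= mse
        elif permute_on == "k":
            mse0_perm = np.einsum("bi,bi->b", resid, resid) / (n - 1)
            k_perm = (mse0_perm / mse_perm) / expected
            more_signal = k_perm >= k_obs
        else:
            raise ValueError("permute_on must be 'mse' or 'k'")
        p = (1 + int(more_signal.sum())) / n_perm
    else:
        p = 1.0
    return KResult(K=float(k_obs), MSE0=mse0, MSE=mse, expected_ratio=expected,
                   p_perm=float(p), n_perm=n_perm, seed=seed)
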