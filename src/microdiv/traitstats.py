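"""Statistical layer: community, trait and phylogenetic comparative tests.

Implemented from first principles on top of scipy/statsmodels primitives:

* Bray-Curtis dissimilarity, d(i,j) = sum|x-y| / sum(x+y).
* Two-factor PERMANOVA with type-III (partial) sums of squares and
  permutation of residuals under the reduced model (Freedman-Lane), the
  McArdle-Anderson trace formulation on the Gower-centered matrix.
* Mantel/RELATE: Spearman rank correlation between two distance matrices
  with joint row+column permutation.
* One-way ANOVA with Tukey's HSD (studentized-range distribution).
* Phylogenetic independent contrasts (Felsenstein pruning) with regression
  through the origin.
* Backward-selection ANCOVA: full factorial least squares, iteratively
  dropping the most non-significant interaction while respecting
  marginality.

Permutation p-values use the (b+1)/(P+1) estimator except in exhaustive
mode, where the exact proportion over all permutations (identity included)
is returned.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import phylo
from .util import rng_for


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(abundances: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bray-Curtis dissimilarity between samples (rows).

    Returns (dissimilarity, similarity = 1 - d) as labelled DataFrames.
    """
    X = abundances.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    if (X.sum(axis=1) <= 0).any():
        bad = abundances.index[X.sum(axis=1) <= 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    D = num / den
    np.fill_diagonal(D, 0.0)
    dist = pd.DataFrame(D, index=abundances.index, columns=abundances.index)
    return dist, 1.0 - dist


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: terms + Residual + Total; cols df, SS, pseudo_F, p, pct_of_total
    n_permutations: int
    degenerate: bool = False


def _effect_code(series: pd.Series) -> np.ndarray:
    """Sum-to-zero (deviation) coding: levels-1 columns."""
    levels = sorted(series.unique())
    if len(levels) < 2:
        return np.zeros((len(series), 0))
    X = np.zeros((len(series), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        X[:, j] = np.where(series == lev, 1.0, np.where(series == levels[-1], -1.0, 0.0))
    return X


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _gower(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def permanova(dist: pd.DataFrame, design: pd.DataFrame,
              factors: tuple[str, ...] = ("treatment", "date"),
              n_perm: int = 999, seed: int = 0,
              include_interaction: bool = False,
              method: str = "freedman_lane",
              exhaustive: bool = False) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Type-III partial sums of squares per term (each adjusted for all
    others); pseudo-F per the McArdle-Anderson trace formulation; p-values
    by Freedman-Lane permutation of reduced-model residuals (or raw
    permutation with ``method='raw'``).  ``exhaustive=True`` enumerates all
    n! sample permutations (n <= 8) and returns exact proportions.
    """
    labels = list(dist.index)
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    missing = [l for l in labels if l not in design.index]
    if missing:
        raise ValueError(f"design rows missing for samples: {missing[:5]}")
    design = design.loc[labels]
    D = dist.to_numpy(dtype=float)
    if np.max(np.abs(D - D.T)) > 1e-12 * max(1.0, np.abs(D).max()):
        raise ValueError("distance matrix is not symmetric")
    n = D.shape[0]
    G = _gower(D)
    total_ss = float(np.trace(G))

    terms: list[tuple[str, np.ndarray]] = []
    for f in factors:
        terms.append((f, _effect_code(design[f].astype(str))))
    if include_interaction and len(factors) == 2:
        Xa, Xb = terms[0][1], terms[1][1]
        inter = np.einsum("ni,nj->nij", Xa, Xb).reshape(n, -1)
        terms.append((f"{factors[0]}:{factors[1]}", inter))
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept] + [X for _, X in terms])
    expected_rank = 1 + sum(X.shape[1] for _, X in terms)
    if np.linalg.matrix_rank(X_full) < expected_rank:
        raise ValueError(f"confounded design: aliased terms among {[t for t, _ in terms]}")
    H_full = _hat(X_full)
    df_terms = {t: X.shape[1] for t, X in terms}
    df_res = n - expected_rank

    if total_ss <= 1e-12:
        rows = []
        for t, _ in terms:
            rows.append({"term": t, "df": df_terms[t], "SS": 0.0, "pseudo_F": np.nan,
                         "p": 1.0, "pct_of_total": np.nan})
        rows.append({"term": "Residual", "df": df_res, "SS": 0.0, "pseudo_F": np.nan,
                     "p": np.nan, "pct_of_total": np.nan})
        rows.append({"term": "Total", "df": n - 1, "SS": 0.0, "pseudo_F": np.nan,
                     "p": np.nan, "pct_of_total": np.nan})
        return PermanovaResult(pd.DataFrame(rows).set_index("term"), 0, degenerate=True)

    def ss_terms(Gm: np.ndarray, H_f: np.ndarray, H_r: np.ndarray) -> float:
        # tr(H G H) = tr(G H) for symmetric idempotent H
        return float((Gm * H_f).sum() - (Gm * H_r).sum())

    results = {}
    rng = rng_for(seed, "permanova")
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        perms = [rng.permutation(n) for _ in range(n_perm)]

    for t, _X in terms:
        X_red = np.hstack([intercept] + [X for u, X in terms if u != t])
        H_red = _hat(X_red)
        ss_t = ss_terms(G, H_full, H_red)
        ss_res = total_ss - float((G * H_full).sum())
        F_obs = (ss_t / df_terms[t]) / (ss_res / df_res) if df_res > 0 else np.nan
        if method == "freedman_lane":
            I_red = np.eye(n) - H_red
            R = I_red @ G @ I_red
        elif method == "raw":
            R = G
        else:
            raise ValueError(f"unknown permutation method {method!r}")
        count = 0
        for perm in perms:
            Rp = R[np.ix_(perm, perm)]
            ss_tp = ss_terms(Rp, H_full, H_red)
            ss_resp = float(np.trace(Rp)) - float((Rp * H_full).sum())
            if ss_resp <= 0:
                Fp = np.inf
            else:
                Fp = (ss_tp / df_terms[t]) / (ss_resp / df_res)
            if Fp >= F_obs - 1e-12:
                count += 1
        if exhaustive:
            p = count / len(perms)
        else:
            p = (count + 1) / (len(perms) + 1)
        results[t] = (ss_t, F_obs, p)

    ss_res = total_ss - float((G * H_full).sum())
    rows = []
    for t, _ in terms:
        ss_t, F_obs, p = results[t]
        rows.append({"term": t, "df": df_terms[t], "SS": ss_t, "pseudo_F": F_obs,
                     "p": p, "pct_of_total": 100.0 * ss_t / total_ss})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res, "pseudo_F": np.nan,
                 "p": np.nan, "pct_of_total": 100.0 * ss_res / total_ss})
    rows.append({"term": "Total", "df": n - 1, "SS": total_ss, "pseudo_F": np.nan,
                 "p": np.nan, "pct_of_total": 100.0})
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), len(perms))


# ---------------------------------------------------------------------------
# Mantel / RELATE
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    rho: float
    p: float
    n_permutations: int
    defined: bool = True


def mantel_relate(dist_a: pd.DataFrame, dist_b: pd.DataFrame, n_perm: int = 999,
                  seed: int = 0, exhaustive: bool = False) -> MantelResult:
    """Spearman rank correlation between two distance matrices (RELATE test).

    p is one-sided (greater), by permuting rows+columns of the second matrix
    jointly.
    """
    if list(dist_a.index) != list(dist_b.index):
        dist_b = dist_b.loc[dist_a.index, dist_a.index]
    A = dist_a.to_numpy(dtype=float)
    B = dist_b.to_numpy(dtype=float)
    n = A.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    iu = np.triu_indices(n, k=1)
    a, b = A[iu], B[iu]
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return MantelResult(np.nan, np.nan, 0, defined=False)
    rho_obs = float(stats.spearmanr(a, b).statistic)
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        rng = rng_for(seed, "mantel")
        perms = [rng.permutation(n) for _ in range(n_perm)]
    count = 0
    for perm in perms:
        bp = B[np.ix_(perm, perm)][iu]
        rho_p = float(stats.spearmanr(a, bp).statistic)
        if rho_p >= rho_obs - 1e-12:
            count += 1
    p = count / len(perms) if exhaustive else (count + 1) / (len(perms) + 1)
    return MantelResult(rho_obs, p, len(perms))


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    tukey: pd.DataFrame  # group_a, group_b, diff, q, p_adj


def anova_tukey(values, groups) -> AnovaResult:
    """One-way ANOVA with Tukey's honestly-significant-difference test."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: values[groups == g] for g in levels}
    sizes = {g: len(v) for g, v in data.items()}
    if min(sizes.values()) == 0:
        raise ValueError("a group has 0 observations")
    N = len(values)
    k = len(levels)
    if N - k < 1:
        raise ValueError("need at least 1 residual degree of freedom")
    grand = values.mean()
    ss_between = sum(sizes[g] * (data[g].mean() - grand) ** 2 for g in levels)
    ss_within = sum(((data[g] - data[g].mean()) ** 2).sum() for g in levels)
    df_b, df_w = k - 1, N - k
    msw = ss_within / df_w
    if msw <= 0:
        F = 0.0 if ss_between <= 1e-300 else np.inf
        p = 1.0 if F == 0.0 else 0.0
    else:
        F = (ss_between / df_b) / msw
        p = float(stats.f.sf(F, df_b, df_w))
    rows = []
    for ga, gb in itertools.combinations(levels, 2):
        diff = data[gb].mean() - data[ga].mean()
        se = math.sqrt(msw / 2.0 * (1.0 / sizes[ga] + 1.0 / sizes[gb])) if msw > 0 else 0.0
        q = abs(diff) / se if se > 0 else (0.0 if abs(diff) < 1e-300 else np.inf)
        p_adj = float(stats.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else (1.0 if q == 0 else 0.0)
        rows.append({"group_a": ga, "group_b": gb, "diff": diff, "q": q, "p_adj": p_adj})
    return AnovaResult(float(F), (df_b, df_w), p, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# phylogenetic independent contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastSet:
    contrasts: np.ndarray   # n_leaves - 1 standardized contrasts
    variances: np.ndarray   # expected variances (branch-length sums)
    nodes: list[str]        # internal-node identifiers (postorder)


def pic(tree: phylo.Node, trait: dict[str, float]) -> ContrastSet:
    """Felsenstein's phylogenetic independent contrasts.

    Requires a fully bifurcating rooted tree with positive branch lengths
    and a trait value for every leaf.  At each internal node the contrast is
    (x_left - x_right)/sqrt(v_left + v_right); the ancestral value is the
    variance-weighted average and the parent branch is extended by
    v_l*v_r/(v_l+v_r).
    """
    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in trait]
    if missing:
        raise ValueError(f"trait missing for leaves: {missing[:5]}")
    contrasts, variances, nodes = [], [], []

    def prune(node: phylo.Node) -> tuple[float, float]:
        if node.is_leaf:
            if node.parent is not None and node.length <= 0:
                raise ValueError(f"non-positive branch length at leaf {node.name}")
            return float(trait[node.name]), float(node.length)
        if len(node.children) != 2:
            raise ValueError(
                "tree contains a polytomy; resolve it with zero-length branches first"
            )
        (x1, v1), (x2, v2) = (prune(c) for c in node.children)
        if v1 <= 0 or v2 <= 0:
            raise ValueError("non-positive branch length at an internal node")
        contrasts.append((x1 - x2) / math.sqrt(v1 + v2))
        variances.append(v1 + v2)
        nodes.append(node.name or f"node{len(nodes)}")
        x = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        v = node.length + v1 * v2 / (v1 + v2)
        return x, v

    prune(tree)
    return ContrastSet(np.array(contrasts), np.array(variances), nodes)


def pic_regression(cx: np.ndarray, cy: np.ndarray) -> tuple[float, float, float]:
    """Regression of contrasts cy on cx THROUGH THE ORIGIN.

    Returns (slope, F, p) with 1 and n-1 degrees of freedom (n contrasts).
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    if len(cx) != len(cy) or len(cx) < 2:
        raise ValueError("need >= 2 paired contrasts")
    sxx = float(np.sum(cx ** 2))
    if sxx <= 0:
        raise ValueError("degenerate contrasts (all zero)")
    slope = float(np.sum(cx * cy)) / sxx
    ss_reg = slope ** 2 * sxx
    ss_res = float(np.sum(cy ** 2)) - ss_reg
    df_res = len(cx) - 1
    if ss_res <= 0:
        return slope, np.inf, 0.0
    F = ss_reg / (ss_res / df_res)
    return slope, float(F), float(stats.f.sf(F, 1, df_res))


# ---------------------------------------------------------------------------
# backward-selection ANCOVA
# ---------------------------------------------------------------------------

def ancova_backward(data: pd.DataFrame, response: str = "area",
                    factors: tuple[str, ...] = ("temperature", "clade", "substrate"),
                    alpha: float = 0.05) -> pd.DataFrame:
    """Full-factorial least squares with backward elimination of interactions.

    Starts from the full factorial model; while any interaction term not
    contained in a retained higher-order interaction has p > alpha, the one
    with the highest p is dropped and the model refit.  Main effects are
    never dropped.  Returns the final ANOVA table (term, df, sum_sq, F, p).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = data.copy()
    for f in factors:
        data[f] = data[f].astype(str)
    all_terms = []
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            all_terms.append(frozenset(combo))

    def term_str(t: frozenset) -> str:
        return ":".join(f"C({f})" for f in sorted(t, key=list(factors).index))

    terms = list(all_terms)

    def fit(terms_list):
        formula = f"{response} ~ " + " + ".join(term_str(t) for t in terms_list)
        model = smf.ols(formula, data=data).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = anova_lm(model, typ=2)
        return model, table

    model, table = fit(terms)
    while model.df_resid <= 0:
        order = max(len(t) for t in terms)
        candidates = [t for t in terms if len(t) == order]
        drop = sorted(candidates, key=term_str)[-1]
        warnings.warn(f"saturated model: dropping {term_str(drop)} a priori")
        terms.remove(drop)
        model, table = fit(terms)

    while True:
        removable = []
        for t in terms:
            if len(t) < 2:
                continue
            if any(len(s) > len(t) and t < s for s in terms):
                continue  # marginality: contained in a retained higher-order term
            p = float(table.loc[term_str(t), "PR(>F)"])
            if p > alpha or not np.isfinite(p):
                removable.append((p if np.isfinite(p) else np.inf, term_str(t), t))
        if not removable:
            break
        removable.sort()
        _, _, worst = removable[-1]
        terms.remove(worst)
        model, table = fit(terms)

    table = table.rename(columns={"PR(>F)": "p"})
    return table
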