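"""Phylogeny-aware algorithms.

Patristic distances and the Brownian-motion covariance (shared root-to-MRCA
path length) feed four procedures: matched-control selection of a
phylogenetically comparable background subset, phylogenetic PCA on GLS-
centred traits, a phylogenetic logistic regression (estimating-equation
construction with a fitted signal weight), and the max-contrasting-pairs
test with its label-permutation wrapper used by the stringent pan-GWAS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import DataValidationError
from .stats import TestResult, binomial_sign_test


# ----------------------------------------------------------- distances

def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix (sum of branch lengths on path)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = _leaf_labels(tree)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def phylo_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion trait covariance: C[i, j] = root-to-MRCA(i, j) depth."""
    if tree.is_rooted is False:
        raise DataValidationError("phylo_vcv requires a rooted tree")
    labels = _leaf_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    # root depth per node
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    leaves_below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            leaves_below[node] = [i]
            C[i, i] = depth[node]
        else:
            children = [leaves_below[ch] for ch in node.child_nodes()]
            merged: list[int] = []
            for k, left in enumerate(children):
                for right in children[k + 1:]:
                    for i in left:
                        for j in right:
                            C[i, j] = C[j, i] = depth[node]
                merged.extend(left)
            leaves_below[node] = merged
    return pd.DataFrame(C, index=labels, columns=labels)


# ------------------------------------------------- matched-control subset

def matched_control_selection(
    D: pd.DataFrame,
    pma_ids: list[str],
    npma_ids: list[str],
    size: int,
    repeats: int = 100,
    seed: int | None = None,
) -> dict:
    """Select a background subset phylogenetically comparable to the focal group.

    Draws ``repeats`` uniform subsets of ``npma_ids`` of the given size,
    computes each subset's mean focal-to-subset patristic distance, and
    returns the subset whose mean deviates least from the across-repeats
    average (earliest repeat wins ties).
    """
    if size > len(npma_ids):
        raise ValueError(f"size {size} exceeds pool of {len(npma_ids)}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    block = D.loc[list(pma_ids), list(npma_ids)].to_numpy()
    pool = np.asarray(npma_ids, dtype=object)
    draws = [np.sort(rng.choice(len(pool), size=size, replace=False)) for _ in range(repeats)]
    means = np.array([block[:, idx].mean() for idx in draws])
    target = means.mean()
    best = int(np.argmin(np.abs(means - target)))
    return {
        "selected_ids": [str(g) for g in pool[draws[best]]],
        "subset_mean": float(means[best]),
        "target_mean": float(target),
        "repeat_index": best,
    }


# ------------------------------------------------------------- phylo-PCA

def phylo_pca(X: pd.DataFrame, tree: dendropy.Tree, ridge: float = 1e-8) -> dict:
    """Phylogenetic PCA of a tips x traits matrix.

    Traits are centred at the phylogenetic GLS mean
    a = (1' C^-1 1)^-1 1' C^-1 X and the evolutionary covariance
    S = (X - 1a)' C^-1 (X - 1a) / (n - 1) is eigendecomposed; scores are the
    centred data projected on the eigenvectors (eigenvalues non-increasing).
    """
    if X.shape[0] < 3:
        raise ValueError("phylo_pca requires at least 3 tips")
    if X.shape[1] < 2:
        raise ValueError("phylo_pca requires at least 2 traits")
    C_full = phylo_vcv(tree)
    missing = [t for t in X.index if t not in C_full.index]
    if missing:
        raise DataValidationError(f"tips absent from tree: {missing}")
    C = C_full.loc[X.index, X.index].to_numpy()
    n = X.shape[0]
    Xv = X.to_numpy(dtype=float)
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        Ci = np.linalg.inv(C + ridge * np.eye(n))
    ones = np.ones((n, 1))
    denom = float((ones.T @ Ci @ ones).item())
    a = (ones.T @ Ci @ Xv) / denom
    Xc = Xv - ones @ a
    S = Xc.T @ Ci @ Xc / (n - 1)
    S = (S + S.T) / 2.0
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    scores = Xc @ eigvec
    pc_names = [f"PC{i + 1}" for i in range(len(eigval))]
    return {
        "eigenvalues": eigval,
        "loadings": pd.DataFrame(eigvec, index=X.columns, columns=pc_names),
        "scores": pd.DataFrame(scores, index=X.index, columns=pc_names),
        "phylo_means": pd.Series(a.ravel(), index=X.columns),
    }


# --------------------------------------------- phylogenetic logistic test

def _corr_from_vcv(C: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(C))
    d[d == 0] = 1.0
    return C / np.outer(d, d)


_ALPHA_GRID = np.linspace(0.0, 1.0, 21)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


def phyloglm_test(
    y,
    x,
    tree: dendropy.Tree | None = None,
    C: pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
    ridge: float = 1e-6,
) -> dict:
    """Phylogenetic logistic regression of a binary habitat label on a covariate.

    Quasi-likelihood estimating equations with working covariance
    V = A^(1/2) R(alpha) A^(1/2). The working correlation is the
    observed-scale correlation a latent threshold (probit-like) model
    implies for binary tips whose latent trait is Brownian on the tree:
    R(alpha) = (2/pi) arcsin(alpha * R0), with R0 the phylogenetic
    correlation and alpha in [0, 1] a signal weight chosen by Gaussian
    pseudo-likelihood on the Pearson residuals. The covariate is
    standardized internally; estimate > 0 means larger values associate
    with the focal (y = 1) group. On a star phylogeny R0 has zero
    off-diagonals, so R(alpha) = I for every alpha and the fit reduces
    exactly to ordinary logistic regression. Wald p from the model-based
    covariance; falls back to ordinary logistic with converged=False when
    the phylogeny-weighted solve fails.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary (0/1)")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if C is None:
        if tree is None:
            raise ValueError("provide a tree or a phylogenetic covariance")
        C = phylo_vcv(tree)
    Cm = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C, dtype=float)
    if Cm.shape[0] != len(y):
        raise ValueError("covariance size does not match trait length")
    R0 = _corr_from_vcv(Cm)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("constant covariate")
    xs = (x - x.mean()) / sd
    n = len(y)
    X = np.column_stack([np.ones(n), xs])
    eye = np.eye(n)

    def working_R(alpha: float) -> np.ndarray:
        R = (2.0 / np.pi) * np.arcsin(np.clip(alpha * R0, -1.0, 1.0))
        np.fill_diagonal(R, 1.0)
        return R

    def irls(Rinv: np.ndarray, beta: np.ndarray):
        info = None
        for _ in range(max_iter):
            mu = _sigmoid(X @ beta)
            v = np.clip(mu * (1.0 - mu), 1e-10, None)
            sqrt_v = np.sqrt(v)
            Xt = X * sqrt_v[:, None]           # A^(1/2) X
            info = Xt.T @ Rinv @ Xt
            score = Xt.T @ Rinv @ ((y - mu) / sqrt_v)
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                return beta, None, False
            beta = beta + step
            if np.abs(beta).max() > 50:
                return beta, info, False
            if np.abs(step).max() < tol:
                return beta, info, True
        return beta, info, False

    beta = np.zeros(2)
    alpha = 0.0
    ok = False
    info = None
    for _ in range(4):
        Rinv = np.linalg.inv(working_R(alpha) + ridge * eye)
        beta, info, ok = irls(Rinv, beta)
        if info is None:
            break
        mu = _sigmoid(X @ beta)
        e = (y - mu) / np.sqrt(np.clip(mu * (1.0 - mu), 1e-10, None))
        best_ll, best_alpha = -np.inf, alpha
        for a in _ALPHA_GRID:
            Ra = working_R(a) + ridge * eye
            _, logdet = np.linalg.slogdet(Ra)
            ll = -0.5 * logdet - 0.5 * float(e @ np.linalg.solve(Ra, e))
            if ll > best_ll + 1e-12:
                best_ll, best_alpha = ll, a
        if abs(best_alpha - alpha) < 1e-9:
            break
        alpha = best_alpha
    if info is not None:
        # refit at the settled signal weight
        Rinv = np.linalg.inv(working_R(alpha) + ridge * eye)
        beta, info, ok = irls(Rinv, beta)
    converged = bool(ok)
    if info is None or not ok:
        # ordinary-logistic fallback
        beta = np.zeros(2)
        beta, info, _ = irls(np.linalg.inv(eye), beta)
        if info is None:
            return {"estimate": float("nan"), "intercept": float("nan"),
                    "se": float("nan"), "p": 1.0, "alpha": 0.0, "converged": False}
        converged = False
        alpha = 0.0
    cov = np.linalg.inv(info)
    se = math.sqrt(max(cov[1, 1], 0.0))
    z = beta[1] / se if se > 0 else 0.0
    p = float(2.0 * sps.norm.sf(abs(z)))
    return {
        "estimate": float(beta[1]),
        "intercept": float(beta[0]),
        "se": float(se),
        "p": min(p, 1.0),
        "alpha": float(alpha),
        "converged": bool(converged),
    }


# -------------------------------------------- max contrasting pairs (DP)

@dataclass(frozen=True)
class PairwiseComparisonResult:
    max_pairs: int
    best_supporting: int
    worst_supporting: int
    p_best: float
    p_worst: float


class TreeIndex:
    """Postorder array representation of a tree for fast repeated traversal."""

    def __init__(self, tree: dendropy.Tree):
        self.labels = _leaf_labels(tree)
        index = {lab: i for i, lab in enumerate(self.labels)}
        nodes = list(tree.postorder_node_iter())
        node_pos = {id(nd): k for k, nd in enumerate(nodes)}
        self.postorder: list[tuple[int | None, list[int]]] = []
        for nd in nodes:
            if nd.is_leaf():
                self.postorder.append((index[nd.taxon.label], []))
            else:
                self.postorder.append((None, [node_pos[id(ch)] for ch in nd.child_nodes()]))


_NONE = 4  # carry state: no unmatched tip passes above this node

# contrasting pairs: states encode (genotype, phenotype) as 2*g + p
_PAIRABLE = {(0, 3): 1, (3, 0): 1, (1, 2): 0, (2, 1): 0}  # -> supporting flag

_INF = np.iinfo(np.int64).max // 4


def _acc(out: dict, carry: int, mn: np.ndarray, mx: np.ndarray) -> None:
    cur = out.get(carry)
    if cur is None:
        out[carry] = (mn.copy(), mx.copy())
        return
    cmn, cmx = cur
    if len(cmn) < len(mn):
        pad = len(mn) - len(cmn)
        cmn = np.concatenate([cmn, np.full(pad, _INF, dtype=np.int64)])
        cmx = np.concatenate([cmx, np.full(pad, -_INF, dtype=np.int64)])
    elif len(mn) < len(cmn):
        pad = len(cmn) - len(mn)
        mn = np.concatenate([mn, np.full(pad, _INF, dtype=np.int64)])
        mx = np.concatenate([mx, np.full(pad, -_INF, dtype=np.int64)])
    out[carry] = (np.minimum(cmn, mn), np.maximum(cmx, mx))


def _combine(left: dict, right: dict) -> dict:
    """Min/max-plus convolution over pair counts for each carry-state pair.

    Each state maps carry -> (minS, maxS) arrays indexed by pair count,
    with +/-INF marking unreachable counts.
    """
    out: dict = {}
    for cL, (mnL, mxL) in left.items():
        for cR, (mnR, mxR) in right.items():
            if len(mnL) <= len(mnR):  # iterate over the shorter side
                a_mn, a_mx, b_mn, b_mx = mnL, mxL, mnR, mxR
            else:
                a_mn, a_mx, b_mn, b_mx = mnR, mxR, mnL, mxL
            nA, nB = len(a_mn), len(b_mn)
            mnv = np.full(nA + nB - 1, _INF, dtype=np.int64)
            mxv = np.full(nA + nB - 1, -_INF, dtype=np.int64)
            for i in range(nA):
                if a_mn[i] >= _INF:
                    continue
                seg = mnv[i:i + nB]
                np.minimum(seg, a_mn[i] + b_mn, out=seg)
                seg = mxv[i:i + nB]
                np.maximum(seg, a_mx[i] + b_mx, out=seg)
            _acc(out, cL, mnv, mxv)
            if cR != cL:
                _acc(out, cR, mnv, mxv)
            sup = _PAIRABLE.get((cL, cR))
            if sup is not None:
                pmn = np.concatenate([[_INF], np.where(mnv < _INF, mnv + sup, _INF)])
                pmx = np.concatenate([[-_INF], np.where(mxv > -_INF, mxv + sup, -_INF)])
                _acc(out, _NONE, pmn, pmx)
    return out


def max_contrasting_pairs(
    tree: dendropy.Tree | TreeIndex,
    genotype,
    phenotype,
) -> PairwiseComparisonResult:
    """Maximum edge-disjoint tip pairs contrasting in both genotype and phenotype.

    A contrasting pair joins tips differing in both traits; it is
    "supporting" when the genotype-positive tip is also phenotype-positive.
    Among all maximum pairings a postorder dynamic program finds the best
    (max) and worst (min) numbers of supporting pairs. Both are scored
    against a fair coin: p_best is the one-sided binomial p of the most
    favorable achievable pairing (min of the upper tail at ``best`` and the
    lower tail at ``worst``); p_worst is the p of the least favorable
    pairing per direction (upper tail at ``worst``, lower tail at ``best``,
    minimum of the two directions). p_worst is the stringent statistic used
    downstream: it is small only when every maximum pairing shows a
    directional excess.
    """
    tix = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    g = _trait_array(genotype, tix.labels, "genotype")
    ph = _trait_array(phenotype, tix.labels, "phenotype")
    zero_mn = np.zeros(1, dtype=np.int64)
    zero_mx = np.zeros(1, dtype=np.int64)
    states: list[dict] = []
    for leaf_index, children in tix.postorder:
        if leaf_index is not None:
            carry = int(2 * g[leaf_index] + ph[leaf_index])
            states.append({carry: (zero_mn, zero_mx)})
        else:
            acc = states[children[0]]
            for ch in children[1:]:
                acc = _combine(acc, states[ch])
            states.append(acc)
    root = states[-1]
    max_pairs, worst, best = 0, 0, 0
    for mn, mx in root.values():
        reachable = np.nonzero(mn < _INF)[0]
        if len(reachable) == 0:
            continue
        top = int(reachable.max())
        if top > max_pairs:
            max_pairs, worst, best = top, int(mn[top]), int(mx[top])
        elif top == max_pairs and top > 0:
            worst = min(worst, int(mn[top]))
            best = max(best, int(mx[top]))
    if max_pairs == 0:
        return PairwiseComparisonResult(0, 0, 0, 1.0, 1.0)
    p_best = min(_pairing_tail_p(max_pairs, worst, best, True),
                 _pairing_tail_p(max_pairs, worst, best, False))
    p_worst = min(_worst_directional_p(max_pairs, worst, best, True),
                  _worst_directional_p(max_pairs, worst, best, False))
    return PairwiseComparisonResult(max_pairs, best, worst, p_best, p_worst)


def _pairing_tail_p(max_pairs: int, worst: int, best: int, positive: bool) -> float:
    """One-sided binomial p of the most favorable pairing for a direction."""
    if positive:
        return float(sps.binom.sf(best - 1, max_pairs, 0.5))
    return float(sps.binom.cdf(worst, max_pairs, 0.5))


def _worst_directional_p(max_pairs: int, worst: int, best: int, positive: bool) -> float:
    """One-sided binomial p of the least favorable pairing for a direction."""
    if max_pairs == 0:
        return 1.0
    if positive:
        return float(sps.binom.sf(worst - 1, max_pairs, 0.5))
    return float(sps.binom.cdf(best, max_pairs, 0.5))


def _trait_array(trait, labels: list[str], name: str) -> np.ndarray:
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if isinstance(trait, dict):
        missing = [lab for lab in labels if lab not in trait]
        if missing:
            raise DataValidationError(f"{name} missing for tip(s): {missing}")
        arr = np.array([trait[lab] for lab in labels])
    else:
        arr = np.asarray(trait)
        if arr.shape[0] != len(labels):
            raise DataValidationError(f"{name} length {arr.shape[0]} != {len(labels)} tips")
    arr = arr.astype(int)
    if set(np.unique(arr)) - {0, 1}:
        raise DataValidationError(f"{name} must be binary (0/1)")
    return arr


def label_permutation_test(
    tree: dendropy.Tree | TreeIndex,
    genotype,
    phenotype,
    n_perm: int = 1000,
    seed: int | None = None,
    early_stop: float | None = None,
) -> float:
    """Empirical p for the worst-case pairwise statistic under label shuffles.

    Permutes the phenotype labels uniformly across tips; the statistic is
    the worst-case directional pairwise p from max_contrasting_pairs,
    evaluated in the direction the observed data favor (so anti-directional
    extremes among permutations do not count against the observed signal);
    empirical p uses the +1 correction. When ``early_stop`` is given, the
    loop ends as soon as the empirical p can no longer fall below it; the
    returned (conservative) estimate then still decides "significant at
    early_stop" correctly.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    tix = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    g = _trait_array(genotype, tix.labels, "genotype")
    ph = _trait_array(phenotype, tix.labels, "phenotype")
    obs = max_contrasting_pairs(tix, g, ph)
    positive = (
        _worst_directional_p(obs.max_pairs, obs.worst_supporting, obs.best_supporting, True)
        <= _worst_directional_p(obs.max_pairs, obs.worst_supporting, obs.best_supporting, False)
    ) if obs.max_pairs > 0 else True
    observed = _worst_directional_p(
        obs.max_pairs, obs.worst_supporting, obs.best_supporting, positive
    ) if obs.max_pairs > 0 else 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    for _ in range(n_perm):
        perm = rng.permutation(ph)
        done += 1
        r = max_contrasting_pairs(tix, g, perm)
        stat = _worst_directional_p(
            r.max_pairs, r.worst_supporting, r.best_supporting, positive
        ) if r.max_pairs > 0 else 1.0
        if stat <= observed:
            hits += 1
            if early_stop is not None and (1 + hits) >= early_stop * (1 + n_perm):
                return (1 + hits) / (1 + done)
    return (1 + hits) / (1 + n_perm)
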