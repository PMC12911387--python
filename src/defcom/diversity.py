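"""Functional diversity on orthogroup CPM profiles.

Alpha diversity (richness, Shannon H in natural log), Bray-Curtis beta
diversity, non-metric multidimensional scaling (Kruskal stress-1, SMACOF
updates alternated with isotonic regression of disparities), and a
sequential (type-I) PERMANOVA partitioning distance-matrix variance among
design factors with a free-permutation null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(cpm: pd.DataFrame, base: float = np.e) -> pd.DataFrame:
    """Per-sample orthogroup richness and Shannon diversity.

    Expects CPM columns (each summing to 1e6); proportions are CPM/1e6
    restricted to nonzero features.
    """
    vals = cpm.to_numpy(dtype=float)
    rich = (vals > 0).sum(axis=0)
    p = vals / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    H = -plogp.sum(axis=0) / np.log(base)
    return pd.DataFrame({"richness": rich, "shannon": H}, index=cpm.columns)


def compare_alpha(values: pd.Series, groups: pd.Series) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum and one-way ANOVA p-values across groups.

    The rank-sum test is exact for combined n <= 20 without ties, otherwise
    the tie-corrected normal approximation; it requires exactly 2 groups
    (ANOVA accepts any number >= 2).
    """
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    parts = [values[groups == g].to_numpy(dtype=float) for g in levels]
    if any(len(p) < 2 for p in parts):
        raise ValueError("each group needs at least 2 values")
    out: dict[str, float] = {}
    anova = stats.f_oneway(*parts)
    out["anova_p"] = float(anova.pvalue)
    out["anova_F"] = float(anova.statistic)
    if len(levels) == 2:
        a, b = parts
        combined = np.concatenate([a, b])
        no_ties = np.unique(combined).size == combined.size
        method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
        mw = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        out["wilcoxon_p"] = float(mw.pvalue)
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(cpm: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample columns."""
    vals = cpm.to_numpy(dtype=float).T
    if (vals < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = vals.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(vals, metric="braycurtis"))
    return pd.DataFrame(d, index=cpm.columns, columns=cpm.columns)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NMDSResult:
    coords: pd.DataFrame
    stress: float
    stress_trace: list[float]
    converged: bool


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    return float(np.sqrt(((dist - disp) ** 2).sum() / (dist**2).sum()))


def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)[None, :]


def nmds(
    d: pd.DataFrame,
    dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMDSResult:
    """Kruskal non-metric MDS by SMACOF updates with monotone disparities.

    The first start is a classical-scaling (principal coordinates)
    configuration; the rest are random. Within a start the recorded stress-1
    trace is non-increasing (an iteration that would raise stress stops the
    start). Returns the best configuration over starts; ``converged`` is
    False when no start reached the tolerance before ``max_iter``.
    """
    D = d.to_numpy(dtype=float)
    n = D.shape[0]
    if n < dims + 2:
        raise ValueError("need at least dims + 2 samples")
    iu = np.triu_indices(n, k=1)
    diss = D[iu]
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    iso = IsotonicRegression()

    best = None
    any_converged = False
    for start in range(n_starts):
        if start == 0:
            X = _classical_mds(D, dims)
        else:
            X = rng.normal(size=(n, dims)) * diss.mean()
        trace: list[float] = []
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            dist = squareform(pdist(X))
            dv = dist[iu]
            disp = np.empty_like(dv)
            disp[order] = iso.fit_transform(np.arange(order.size), dv[order])
            s = _stress1(dv, disp)
            if s > prev:
                break
            trace.append(s)
            if prev - s < tol:
                converged = True
                break
            prev = s
            Xprev = X
            # Guttman transform with disparities
            W = squareform(disp)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, W / dist, 0.0)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = (B @ X) / n
        else:
            Xprev = X
        if s > prev:
            X = Xprev  # revert the rejected update
        final = trace[-1] if trace else s
        if best is None or final < best[0]:
            best = (final, X, trace, converged)
        any_converged = any_converged or converged
    stress, X, trace, _ = best
    coords = pd.DataFrame(
        X, index=d.index, columns=[f"NMDS{i + 1}" for i in range(dims)]
    )
    return NMDSResult(coords=coords, stress=stress, stress_trace=trace, converged=any_converged)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, SS, R2, F, p
    n_permutations: int
    seed: int | None = None


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _term_matrices(design: pd.DataFrame, terms: list[str]) -> list[np.ndarray]:
    mats = []
    for t in terms:
        col = design[t]
        if col.dtype.kind in "OUSb" or col.nunique() < 8:
            dm = pd.get_dummies(col.astype("category"), drop_first=True).to_numpy(float)
        else:
            dm = col.to_numpy(float)[:, None]
        mats.append(dm)
    return mats


def permanova(
    d: pd.DataFrame,
    design: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (type-I) PERMANOVA with free permutation of sample labels.

    Terms are added in the given order; R2(term) = SS(term)/SS(total); the
    permutation p-value is (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    ``n_perm="exact"`` enumerates all label permutations (small n only).
    """
    if list(design.index) != list(d.index):
        raise ValueError("design rows must match distance-matrix samples")
    D = d.to_numpy(dtype=float)
    n = D.shape[0]
    G = _gower_center(D)
    ss_total = float(np.trace(G))

    mats = _term_matrices(design, terms)
    ones = np.ones((n, 1))
    hats = [_hat(ones)]
    X = ones
    dfs = []
    for dm in mats:
        X = np.hstack([X, dm])
        H = _hat(X)
        dfs.append(int(round(np.trace(H - hats[-1]))))
        hats.append(H)
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("confounded terms: zero residual degrees of freedom")
    proj = [hats[i + 1] - hats[i] for i in range(len(mats))]
    resid_proj = np.eye(n) - hats[-1]

    def stats_for(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.sum(P * Gm)) for P in proj])  # tr(P G)
        ss_res = float(np.sum(resid_proj * Gm))
        F = (ss_terms / np.maximum(dfs, 1)) / (ss_res / df_res)
        return F, ss_res

    F_obs, ss_res = stats_for(G)
    ss_terms = np.array([float(np.sum(P * G)) for P in proj])

    if n_perm == "exact":
        perms = list(itertools.permutations(range(n)))[1:]
        count = np.zeros(len(terms))
        for pm in perms:
            idx = np.array(pm)
            Fp, _ = stats_for(G[np.ix_(idx, idx)])
            count += Fp >= F_obs - 1e-12
        pvals = (1.0 + count) / (len(perms) + 1.0)
        n_used = len(perms)
    else:
        if n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            Fp, _ = stats_for(G[np.ix_(idx, idx)])
            count += Fp >= F_obs - 1e-12
        pvals = (1.0 + count) / (n_perm + 1.0)
        n_used = n_perm

    rows = []
    for t, dfi, ssi, Fi, pi in zip(terms, dfs, ss_terms, F_obs, pvals):
        rows.append((t, dfi, ssi, ssi / ss_total, Fi, pi))
    rows.append(("residual", df_res, ss_res, ss_res / ss_total, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "R2", "F", "p"]).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_used, seed=None if n_perm == "exact" else seed)
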