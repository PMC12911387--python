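"""Three-method consensus differential abundance on orthogroup counts.

The three procedures are deliberately lightweight reimplementations of the
three standard count-model families used for microbiome differential
abundance — a negative-binomial Wald GLM with median-of-ratios size factors,
the voom + moderated-t pipeline, and cumulative-sum-scaling (CSS)
normalization with zero-inflation weights — sharing a common result schema.
Exact numerical agreement with any particular external package is not the
contract; calibrated error control and the conservative all-three consensus
are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linmodel import bh_adjust, build_design, contrast_vector, moderated_fit, voom_transform
from .quant import CountMatrix, cpm_normalize, tmm_factors


@dataclass
class DAResult:
    method: str
    table: pd.DataFrame  # log2fc, p, q, significant
    params: dict = field(default_factory=dict)

    def significant_set(self, alpha: float = 0.05, direction: int = 0) -> set[str]:
        t = self.table
        m = t["q"] < alpha
        if direction > 0:
            m &= t["log2fc"] > 0
        elif direction < 0:
            m &= t["log2fc"] < 0
        return set(t.index[m])


# ---------------------------------------------------------------------------
# negative-binomial Wald
# ---------------------------------------------------------------------------

def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference;
    features containing any zero are excluded from the median."""
    y = counts.to_numpy(dtype=float)
    allpos = (y > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no feature is positive in every sample")
    logy = np.log(y[allpos])
    ref = logy.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logy - ref, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_irls(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, disp: np.ndarray, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-feature NB2 IRLS with log link and known dispersions.

    Returns (beta (F, p), covariances (F, p, p))."""
    F, n = y.shape
    p = X.shape[1]
    beta = np.zeros((F, p))
    base = np.log(np.maximum(y.mean(axis=1) / np.exp(offset).mean(), 1e-8))
    beta[:, 0] = base
    for _ in range(max_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + disp[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        A = np.einsum("fn,np,nq->fpq", W, X, X)
        b = np.einsum("fn,np,fn->fp", W, X, z)
        A += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < 1e-8:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30, 30)
    mu = np.exp(eta)
    W = mu / (1.0 + disp[:, None] * mu)
    A = np.einsum("fn,np,nq->fpq", W, X, X) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(A)
    return beta, cov


def estimate_dispersions(
    counts: pd.DataFrame, sf: pd.Series, shrink_weight: float = 0.5
) -> np.ndarray:
    """Method-of-moments gene-wise dispersions shrunk toward a fitted
    a0 + a1/mean trend (weighted average with weight ``shrink_weight`` on
    the trend)."""
    q = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - m) / m**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.clip(raw, 1e-8, 10.0)
    ok = m > 0
    if ok.sum() >= 10:
        Xt = np.column_stack([np.ones(ok.sum()), 1.0 / m[ok]])
        coef, *_ = np.linalg.lstsq(Xt, raw[ok], rcond=None)
        a0, a1 = coef
        trend = np.clip(a0 + a1 / np.maximum(m, 1e-8), 1e-8, 10.0)
    else:
        trend = np.full_like(raw, np.median(raw))
    return np.clip(shrink_weight * trend + (1 - shrink_weight) * raw, 1e-8, 10.0)


def nb_wald_da(
    cm: CountMatrix,
    alpha: float = 0.05,
    host: bool | None = None,
    shrink_weight: float = 0.5,
    df_correction: bool = False,
) -> DAResult:
    """Negative-binomial Wald test on the compartment contrast.

    Raw integer counts only. The asymptotic normal reference for the Wald
    statistic is well calibrated here (trend-shrunken moment dispersions are
    slightly conservative); ``df_correction`` switches to a t reference with
    the residual degrees of freedom for users who want extra conservatism.
    """
    counts = cm.counts
    y = counts.to_numpy(dtype=float)
    if not np.allclose(y, np.round(y)):
        raise ValueError("nb_wald_da requires integer counts")
    design = cm.design
    if host is None:
        host = design["host"].nunique() > 1
    X = build_design(design, compartment=True, host=host)
    c = contrast_vector(X, "compartment")
    sf = size_factors_median_of_ratios(counts)
    offset = np.log(sf.to_numpy())
    allzero = y.sum(axis=1) == 0
    disp = estimate_dispersions(counts, sf, shrink_weight)
    beta, cov = _nb_irls(y + 0.0, X.to_numpy(), offset, disp)
    coef = beta @ c
    se = np.sqrt(np.einsum("p,fpq,q->f", c, cov, c))
    z = coef / np.maximum(se, 1e-12)
    dfres = len(design) - X.shape[1]
    if df_correction:
        p = 2.0 * stats.t.sf(np.abs(z), dfres)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = coef / np.log(2.0)
    p = np.where(allzero, 1.0, p)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": bh_adjust(p)}, index=counts.index
    )
    table["significant"] = table["q"] < alpha
    table["all_zero"] = allzero
    return DAResult(
        method="nb_wald",
        table=table,
        params={"shrink_weight": shrink_weight, "df_correction": df_correction},
    )


# ---------------------------------------------------------------------------
# voom route (reuses the strain-enrichment machinery)
# ---------------------------------------------------------------------------

def voom_da(
    cm: CountMatrix,
    alpha: float = 0.05,
    host: bool | None = None,
    factors: pd.Series | None = None,
) -> DAResult:
    """TMM + voom + moderated t on the compartment contrast.

    Fractional (per-copy) counts are rounded to pseudo-counts first; the
    rounding is recorded in the result params.
    """
    counts = cm.counts
    rounded = False
    y = counts.to_numpy(dtype=float)
    if not np.allclose(y, np.round(y)):
        counts = counts.round()
        rounded = True
    design = cm.design
    if host is None:
        host = design["host"].nunique() > 1
    X = build_design(design, compartment=True, host=host)
    if factors is None:
        factors = tmm_factors(counts)
    logcpm, weights = voom_transform(counts, factors, X)
    res = moderated_fit(logcpm, weights, X, contrast_vector(X, "compartment"))
    table = res.table[["log2fc", "p", "q"]].copy()
    table["significant"] = table["q"] < alpha
    return DAResult(
        method="voom_mod_t",
        table=table,
        params={"rounded_pseudo_counts": rounded, "d0": res.d0},
    )


# ---------------------------------------------------------------------------
# CSS + zero-inflation route
# ---------------------------------------------------------------------------

def css_scales(counts: pd.DataFrame, css_quantile: float = 0.5) -> pd.Series:
    """Cumulative-sum-scaling factor per sample: the sum of counts at or
    below the sample's ``css_quantile`` quantile of its nonzero counts."""
    scales = {}
    for s in counts.columns:
        col = counts[s].to_numpy(dtype=float)
        nz = col[col > 0]
        if nz.size < 10:
            raise ValueError(f"sample {s!r} has fewer than 10 nonzero features; CSS unstable")
        v = np.quantile(nz, css_quantile)
        scales[s] = float(col[(col > 0) & (col <= v)].sum())
    return pd.Series(scales, name="css_scale")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def zig_weights(
    norm: pd.DataFrame,
    libsize: pd.Series,
    is_zero: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, dict]:
    """Posterior probability that each zero is structural (two-component EM).

    Mixture per entry: a point mass at zero (structural absence, prior
    probability logistic in log library size) vs a Gaussian with
    feature-specific mean and a pooled variance. Returns observation weights
    1 - P(structural) (nonzero entries get weight 1) and EM diagnostics.
    Falls back to all-ones weights if the EM fails to converge.
    """
    y = norm.to_numpy(dtype=float)
    F, n = y.shape
    x = np.log(libsize.to_numpy(dtype=float))
    x = (x - x.mean()) / (x.std() + 1e-12)
    b = np.array([-1.0, 0.0])  # logistic intercept, slope
    r = np.where(is_zero, 0.5, 0.0)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        wts = 1.0 - r
        mu = (wts * y).sum(axis=1) / np.maximum(wts.sum(axis=1), 1e-9)
        var = (wts * (y - mu[:, None]) ** 2).sum() / np.maximum(wts.sum(), 1e-9)
        var = max(var, 1e-6)
        # weighted logistic regression of structural indicator on x
        for _ in range(20):
            pi = _sigmoid(b[0] + b[1] * x)[None, :] * np.ones((F, 1))
            g0 = (r - pi).sum()
            g1 = ((r - pi) * x[None, :]).sum()
            w2 = pi * (1 - pi)
            h00 = w2.sum()
            h01 = (w2 * x[None, :]).sum()
            h11 = (w2 * x[None, :] ** 2).sum()
            H = np.array([[h00, h01], [h01, h11]]) + 1e-9 * np.eye(2)
            step = np.linalg.solve(H, np.array([g0, g1]))
            b = b + step
            if np.max(np.abs(step)) < 1e-9:
                break
        pi = _sigmoid(b[0] + b[1] * x)[None, :] * np.ones((F, 1))
        dens = stats.norm.pdf(y, loc=mu[:, None], scale=np.sqrt(var))
        num = pi
        den = pi + (1 - pi) * np.maximum(dens, 1e-300)
        r = np.where(is_zero, num / den, 0.0)
        ll = float(
            np.where(
                is_zero,
                np.log(np.maximum(pi + (1 - pi) * dens, 1e-300)),
                np.log(np.maximum((1 - pi) * dens, 1e-300)),
            ).sum()
        )
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            converged = True
            break
        prev_ll = ll
    if not converged:
        return (
            pd.DataFrame(np.ones_like(y), index=norm.index, columns=norm.columns),
            {"converged": False, "warning": "EM did not converge; weights set to 1"},
        )
    weights = pd.DataFrame(1.0 - r, index=norm.index, columns=norm.columns)
    return weights, {"converged": True, "logistic_coef": b.tolist(), "sigma2": var}


def css_zig_da(
    cm: CountMatrix,
    alpha: float = 0.05,
    host: bool | None = None,
    css_quantile: float = 0.5,
) -> DAResult:
    """CSS normalization + zero-inflation weights + moderated t."""
    counts = cm.counts
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    design = cm.design
    if host is None:
        host = design["host"].nunique() > 1
    scales = css_scales(counts, css_quantile)
    norm = np.log2(counts.div(scales, axis=1) * 1000.0 + 1.0)
    is_zero = counts.to_numpy() == 0
    if is_zero.any():
        weights, diag = zig_weights(norm, counts.sum(axis=0), is_zero)
    else:
        weights = pd.DataFrame(
            np.ones(counts.shape), index=counts.index, columns=counts.columns
        )
        diag = {"converged": True, "note": "no zeros; degenerate EM"}
    # guard: keep at least a little weight so the WLS stays full rank
    weights = weights.clip(lower=1e-4)
    X = build_design(design, compartment=True, host=host)
    res = moderated_fit(norm, weights, X, contrast_vector(X, "compartment"))
    table = res.table[["log2fc", "p", "q"]].copy()
    table["significant"] = table["q"] < alpha
    return DAResult(
        method="css_zig",
        table=table,
        params={"css_quantile": css_quantile, "em": diag},
    )


# ---------------------------------------------------------------------------
# consensus and intersections
# ---------------------------------------------------------------------------

def consensus(
    results: list[DAResult],
    alpha: float = 0.05,
    direction: int = 1,
    require_direction: bool = True,
) -> set[str]:
    """Features significant in every method at alpha, with consistent sign.

    ``direction`` +1 keeps endosphere-enriched (positive log2fc), -1
    rhizosphere-enriched, 0 either (sign must still agree across methods
    when ``require_direction``).
    """
    universes = [set(r.table.index) for r in results]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("feature universes differ across methods")
    sig = set.intersection(*(r.significant_set(alpha) for r in results))
    out = set()
    for f in sig:
        signs = {int(np.sign(r.table.loc[f, "log2fc"])) for r in results}
        if require_direction and len(signs) > 1:
            continue
        s = signs.pop() if len(signs) == 1 else 0
        if direction and s != direction:
            continue
        out.add(f)
    return out


def run_three_methods(cm: CountMatrix, alpha: float = 0.05, host: bool | None = None) -> list[DAResult]:
    raw = cm
    if not np.allclose(cm.counts.to_numpy(), np.round(cm.counts.to_numpy())):
        raw = cm.with_counts(cm.counts.round())
    return [
        nb_wald_da(raw, alpha=alpha, host=host),
        voom_da(cm, alpha=alpha, host=host),
        css_zig_da(raw, alpha=alpha, host=host),
    ]


def per_host_enrichment(
    cm: CountMatrix,
    alpha: float = 0.05,
    min_detect: int = 1,
) -> dict:
    """Separate endosphere-vs-rhizosphere voom analyses per host species.

    Returns per-host significant (endosphere-enriched) sets, their
    intersection, UpSet-style disjoint intersection cardinalities, and
    presence/absence detection sets per host x compartment (detected =
    CPM > 0 in at least ``min_detect`` samples of the cell).
    """
    design = cm.design
    hosts = sorted(design["host"].unique())
    if len(hosts) != 2:
        raise ValueError("per-host analysis requires exactly 2 hosts")
    per_host_sets: dict[str, set[str]] = {}
    per_host_tables: dict[str, pd.DataFrame] = {}
    for h in hosts:
        sub = design[design["host"] == h]
        cells = sub.groupby("compartment").size()
        if set(cells.index) != {"endosphere", "rhizosphere"} or (cells < 2).any():
            raise ValueError(f"host {h!r} lacks >= 2 replicates in each compartment")
        sub_cm = CountMatrix(cm.counts[list(sub.index)], level=cm.level, design=sub)
        res = voom_da(sub_cm, alpha=alpha, host=False)
        per_host_sets[h] = res.significant_set(alpha, direction=1)
        per_host_tables[h] = res.table
    a, b = hosts
    both = per_host_sets[a] & per_host_sets[b]
    upset = {
        f"{a}_only": len(per_host_sets[a] - per_host_sets[b]),
        f"{b}_only": len(per_host_sets[b] - per_host_sets[a]),
        "shared": len(both),
    }
    cpm = cpm_normalize(cm)
    detection: dict[str, set[str]] = {}
    for h in hosts:
        for comp in ("endosphere", "rhizosphere"):
            cols = design.index[(design["host"] == h) & (design["compartment"] == comp)]
            det = (cpm[list(cols)] > 0).sum(axis=1) >= min_detect
            detection[f"{h}:{comp}"] = set(cpm.index[det])
    return {
        "hosts": hosts,
        "significant": per_host_sets,
        "tables": per_host_tables,
        "shared": both,
        "upset": upset,
        "detection": detection,
    }


def intersect_frameworks(
    consensus_ogs: set[str],
    og_to_ko: dict[str, set[str]] | pd.DataFrame,
    lineage_kos: set[str],
) -> set[str]:
    """KOs annotating at least one consensus orthogroup that are also in the
    lineage-level enriched KO set."""
    if isinstance(og_to_ko, pd.DataFrame):
        ann = og_to_ko.dropna(subset=["ko"])
        mapping: dict[str, set[str]] = {}
        for og, grp in ann.groupby("orthogroup"):
            mapping[og] = set(grp["ko"])
        og_to_ko = mapping
    kos_of_consensus: set[str] = set()
    for og in consensus_ogs:
        kos_of_consensus |= og_to_ko.get(og, set())
    return kos_of_consensus & set(lineage_kos)
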