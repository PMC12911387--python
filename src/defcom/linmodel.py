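"""Weighted linear modeling of count matrices: voom-style precision weights
and empirical-Bayes moderated t statistics, with Benjamini-Hochberg FDR.

The voom transform maps counts to log2-CPM, estimates the mean-variance
trend by lowess on per-feature residual standard deviations, and converts
the predicted sqrt(sd) into inverse-fourth-power observation weights. The
moderated fit then runs per-feature weighted least squares and shrinks the
residual variances toward a common prior estimated by moment matching on the
log variances (the classic limma squeeze), giving t statistics with
augmented degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def build_design(
    design: pd.DataFrame,
    compartment: bool = True,
    host: bool = False,
    interaction: bool = False,
) -> pd.DataFrame:
    """Design matrix with intercept and 0/1 indicator columns.

    ``compartment`` codes endosphere as 1 (so its coefficient is the
    endosphere-minus-rhizosphere log2 fold change); ``host`` codes the
    lexicographically larger host species as 1.
    """
    cols = {"intercept": np.ones(len(design))}
    if compartment:
        cols["compartment"] = (design["compartment"] == "endosphere").astype(float).to_numpy()
    if host:
        hosts = sorted(design["host"].unique())
        if len(hosts) != 2:
            raise ValueError("host term requires exactly 2 host levels")
        cols["host"] = (design["host"] == hosts[1]).astype(float).to_numpy()
    if interaction:
        if not (compartment and host):
            raise ValueError("interaction requires compartment and host terms")
        cols["compartment:host"] = cols["compartment"] * cols["host"]
    X = pd.DataFrame(cols, index=design.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    return X


def contrast_vector(X: pd.DataFrame, column: str = "compartment") -> np.ndarray:
    c = np.zeros(X.shape[1])
    c[list(X.columns).index(column)] = 1.0
    return c


def voom_transform(
    counts: pd.DataFrame,
    factors: pd.Series | None,
    X: pd.DataFrame,
    span: float = 0.5,
    robust_iters: int = 2,
    sd_floor: float = 1e-4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2-CPM and observation-level precision weights.

    logCPM = log2((count + 0.5) / (lib * factor + 1) * 1e6). Per-feature
    residual sd comes from OLS on the design; sqrt(sd) is smoothed by lowess
    against mean log2 count and the trend value at each fitted observation is
    raised to the -4th power, clipped to [1e-6, 1e6].
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    Xm = X.to_numpy()
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    f = factors.loc[counts.columns].to_numpy() if factors is not None else np.ones(lib.size)
    eff = lib * f + 1.0
    y = np.log2((counts.to_numpy(dtype=float) + 0.5) / eff[None, :] * 1e6)

    beta, *_ = np.linalg.lstsq(Xm, y.T, rcond=None)
    fitted = (Xm @ beta).T
    dof = y.shape[1] - Xm.shape[1]
    resid_sd = np.sqrt(((y - fitted) ** 2).sum(axis=1) / max(dof, 1))
    resid_sd = np.maximum(resid_sd, sd_floor)

    # mean log2 count scale for the trend x-axis
    mean_logcount = y.mean(axis=1) + np.mean(np.log2(eff)) - np.log2(1e6)
    if np.ptp(mean_logcount) < 1e-9:  # degenerate: flat trend
        xs = np.array([mean_logcount.min() - 1, mean_logcount.max() + 1])
        ys = np.full(2, np.sqrt(resid_sd).mean())
    else:
        order = np.argsort(mean_logcount)
        fit = lowess(
            np.sqrt(resid_sd)[order],
            mean_logcount[order],
            frac=span,
            it=robust_iters,
            return_sorted=True,
        )
        xs, ys = fit[:, 0], fit[:, 1]
    fitted_logcount = fitted + np.log2(eff)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_logcount, xs, ys)
    w = np.clip(pred**-4.0, 1e-6, 1e6)
    logcpm = pd.DataFrame(y, index=counts.index, columns=counts.columns)
    weights = pd.DataFrame(w, index=counts.index, columns=counts.columns)
    return logcpm, weights


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    observed log sample variances; d0 may be inf when variances are
    underdispersed relative to chi-square sampling noise."""
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) if e.size > 1 else 0.0
    evar_adj = evar - special.polygamma(1, df / 2.0)
    if evar_adj > 0:
        d0 = 2.0 * _trigamma_inverse(evar_adj)
        s20 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s20 = float(np.exp(emean))
    return d0, s20


@dataclass
class ModeratedFitResult:
    table: pd.DataFrame  # feature, log2fc, mean_logcpm, t, p, q
    d0: float
    s0_sq: float
    df_residual: float


def moderated_fit(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame | None,
    X: pd.DataFrame,
    contrast: np.ndarray,
    d0_override: float | None = None,
) -> ModeratedFitResult:
    """Per-feature weighted least squares with empirical-Bayes moderation.

    ``d0_override`` pins the prior degrees of freedom (0 recovers the
    ordinary t, inf the residual-pooled z) — mainly for verification.
    """
    Xm = X.to_numpy()
    n, p = Xm.shape
    contrast = np.asarray(contrast, dtype=float)
    if contrast.size != p:
        raise ValueError("contrast length must equal number of design columns")
    df = n - p
    if df < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    y = logcpm.to_numpy(dtype=float)
    w = weights.to_numpy(dtype=float) if weights is not None else np.ones_like(y)

    # per-feature WLS with a shared design: stack the normal equations
    A = np.einsum("fn,np,nq->fpq", w, Xm, Xm)
    b = np.einsum("fn,np,fn->fp", w, Xm, y)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    fitted = beta @ Xm.T
    rss = (w * (y - fitted) ** 2).sum(axis=1)
    s2 = rss / df
    cvec = np.linalg.solve(A, np.broadcast_to(contrast, (y.shape[0], p))[..., None])[..., 0]
    cvar = np.einsum("fp,p->f", cvec, contrast)  # c' (X'WX)^-1 c
    cvar = np.maximum(cvar, 1e-300)

    if d0_override is not None:
        d0 = d0_override
        s20 = float(np.mean(s2)) if not np.isfinite(d0) else 0.0
        if np.isinf(d0):
            s2_post = np.full_like(s2, np.mean(s2))
        elif d0 == 0:
            s2_post = s2
        else:
            s2_post = (d0 * s20 + df * s2) / (d0 + df)
    else:
        d0, s20 = squeeze_variances(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s20)
        else:
            s2_post = (d0 * s20 + df * s2) / (d0 + df)

    coef = np.einsum("fp,p->f", beta, contrast)
    t = coef / np.sqrt(s2_post * cvar)
    df_total = d0 + df
    if np.isfinite(df_total):
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    table = pd.DataFrame(
        {
            "log2fc": coef,
            "mean_logcpm": y.mean(axis=1),
            "t": t,
            "p": pvals,
            "q": bh_adjust(pvals),
        },
        index=logcpm.index,
    )
    return ModeratedFitResult(table=table, d0=d0, s0_sq=(s20 if d0_override is None or np.isfinite(d0) else float(np.mean(s2))), df_residual=df)
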