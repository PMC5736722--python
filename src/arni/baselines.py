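"""Model-free baseline scores: correlations, partial correlations, transfer entropy.

All three return a dense (N, N) score matrix at unit level (multi-component
units pooled by the maximum absolute statistic over component pairs), with the
diagonal set to zero. Scores are threshold-free: they are evaluated by ranking
(ROC AUC), not by a fixed cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np

from .simulate import TimeSeriesSet

__all__ = ["corr_baseline", "pcorr_baseline", "te_baseline"]


def _pool_units(C: np.ndarray, layout) -> np.ndarray:
    """Max-|.| pooling of a component-level matrix to unit level."""
    N = len(layout)
    out = np.zeros((N, N))
    for i, ci in enumerate(layout):
        for j, cj in enumerate(layout):
            if i == j:
                continue
            out[i, j] = np.max(np.abs(C[np.ix_(ci, cj)]))
    return out


def corr_baseline(ts: TimeSeriesSet) -> np.ndarray:
    """|Pearson correlation| between unit series (symmetric, zero diagonal)."""
    X, _ = ts.stacked()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = X.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance component(s); scores set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(X.T)
    C = np.nan_to_num(C, nan=0.0)
    return _pool_units(C, ts.unit_layout)


def pcorr_baseline(ts: TimeSeriesSet, ridge: float = 0.0) -> np.ndarray:
    """|partial correlation| from the (optionally ridge-regularized) precision.

    rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj) with Omega the inverse
    covariance; ``ridge`` adds ridge * mean(diag(cov)) * I before inversion
    (needed when M_eff < N or the covariance is ill-conditioned).
    """
    X, _ = ts.stacked()
    cov = np.cov(X.T)
    cov = np.atleast_2d(cov)
    if ridge > 0:
        cov = cov + ridge * float(np.mean(np.diag(cov))) * np.eye(cov.shape[0])
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        if ridge == 0:
            raise np.linalg.LinAlgError(
                "covariance is singular or ill-conditioned; pass ridge > 0"
            )
        warnings.warn("covariance still ill-conditioned after ridge")
    om = np.linalg.pinv(cov) if ridge > 0 else np.linalg.inv(cov)
    d = np.sqrt(np.abs(np.diag(om)))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = -om / np.outer(d, d)
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 0.0)
    return _pool_units(rho, ts.unit_layout)


def _equal_freq_codes(v: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(v, np.arange(1, bins) / bins)
    return np.searchsorted(edges, v, side="right")


def te_baseline(ts: TimeSeriesSet, bins: int = 4, lag: int = 1) -> np.ndarray:
    """Plug-in transfer entropy TE_{j->i} in bits, equal-frequency binning.

    TE_{j->i} = sum p(x_i^{t+lag}, x_i^t, x_j^t)
                log2[ p(x_i^{t+lag} | x_i^t, x_j^t) / p(x_i^{t+lag} | x_i^t) ],
    estimated from all within-segment (t, t+lag) pairs; empty bins follow the
    plug-in convention 0 log 0 = 0 and numerical negatives are clipped at 0.
    """
    if bins < 2 or lag < 1:
        raise ValueError("need bins >= 2 and lag >= 1")
    X, _ = ts.stacked()
    D = X.shape[1]
    codes = np.column_stack([_equal_freq_codes(X[:, c], bins) for c in range(D)])

    # within-segment (past, future) row index pairs
    past, fut = [], []
    offset = 0
    for seg in ts.segments:
        n = seg.shape[0]
        if n > lag:
            idx = np.arange(n - lag)
            past.append(offset + idx)
            fut.append(offset + idx + lag)
        offset += n
    if not past:
        raise ValueError("no segment longer than the lag")
    past = np.concatenate(past)
    fut = np.concatenate(fut)
    M = len(past)

    def te_pair(ci: int, cj: int) -> float:
        a = codes[fut, ci]          # future of target
        b = codes[past, ci]         # past of target
        c = codes[past, cj]         # past of source
        n_abc = np.bincount((a * bins + b) * bins + c, minlength=bins**3).astype(float)
        n_abc = n_abc.reshape(bins, bins, bins)
        n_bc = n_abc.sum(axis=0)
        n_ab = n_abc.sum(axis=2)
        n_b = n_abc.sum(axis=(0, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (n_abc * n_b[None, :, None]) / (n_bc[None, :, :] * n_ab[:, :, None])
            term = n_abc * np.log2(ratio)
        te = np.nansum(term[n_abc > 0]) / M
        return max(te, 0.0)

    layout = ts.unit_layout
    N = len(layout)
    out = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            out[i, j] = max(te_pair(ci, cj) for ci in layout[i] for cj in layout[j])
    return out
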