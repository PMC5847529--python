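"""Interactability filtering of captured fragments.

A captured fragment's total trans-ligation count N_T measures its generic
propensity to form ligations. Across a capture design N_T is bimodal: a
low-count component from failed baits (stochastic noise) and a high-count
component from working baits. We fit a left-truncated negative binomial to
the upper component — the likelihood of an observation x >= t is
P(X = x) / P(X >= t) under the untruncated NB(mu, size) — and take the 5%
quantile of the corresponding *untruncated* fit as the per-replicate
threshold. Fragments below threshold in any replicate of a cell line are
treated as failed and removed from all downstream peak calling.

Parameterisation: mean ``mu`` and dispersion ``size`` (r), with
variance = mu + mu^2/size; scipy's nbinom(n, p) has n = size and
p = size / (size + mu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

__all__ = [
    "TruncNBFit",
    "select_truncation_point",
    "fit_truncated_nb",
    "interactability_threshold",
    "filter_fragments",
    "fit_interactability_filters",
]


class TruncatedNBError(RuntimeError):
    """Raised when the truncated-NB likelihood cannot be maximised."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class TruncNBFit:
    """Maximum-likelihood fit of a left-truncated negative binomial."""

    mu: float
    size: float
    truncation_point: int
    loglik: float
    threshold: int
    n_fitted: int
    converged: bool = True

    def cdf(self, x) -> np.ndarray:
        return stats.nbinom.cdf(x, self.size, self.size / (self.size + self.mu))


def _nb_p(mu: float, size: float) -> float:
    return size / (size + mu)


def _trunc_nb_negll(params: np.ndarray, values: np.ndarray, weights: np.ndarray, t: int) -> float:
    log_mu, log_size = params
    mu, size = np.exp(log_mu), np.exp(log_size)
    if not np.isfinite(mu) or not np.isfinite(size):
        return np.inf
    p = _nb_p(mu, size)
    ll = np.sum(weights * stats.nbinom.logpmf(values, size, p))
    if t > 0:
        # P(X >= t) renormalisation for the left truncation
        tail = stats.nbinom.sf(t - 1, size, p)
        if tail <= 0:
            return np.inf
        ll -= weights.sum() * np.log(tail)
    return -ll if np.isfinite(ll) else np.inf


def fit_truncated_nb(n_trans: np.ndarray, t: int = 0) -> TruncNBFit:
    """Fit NB(mu, size) to counts left-truncated at ``t`` by maximum likelihood.

    Only observations >= t enter the likelihood; each contributes
    P(X = x) / P(X >= t). With t = 0 this reduces to the ordinary NB MLE
    (in particular mu_hat equals the sample mean). Optimisation is over
    (log mu, log size) with three starts: method-of-moments, and the MoM mu
    doubled and halved.

    Raises
    ------
    TruncatedNBError
        on degenerate data (all values equal), too few observations (< 30),
        or failure of all optimiser starts.
    """
    x = np.asarray(n_trans)
    x = x[x >= t].astype(np.int64)
    if len(x) < 30:
        raise TruncatedNBError(f"need >= 30 observations >= t={t}, got {len(x)}")
    if x.min() == x.max():
        raise TruncatedNBError("degenerate data: all observations equal")
    values, weights = np.unique(x, return_counts=True)
    weights = weights.astype(float)

    m, v = x.mean(), x.var()
    mu0 = max(m, 1e-3)
    size0 = mu0**2 / max(v - mu0, mu0 * 1e-2)
    size0 = float(np.clip(size0, 1e-2, 1e4))
    starts = [(mu0, size0), (2 * mu0, size0), (0.5 * mu0, size0)]

    best = None
    last = None
    for mu_s, size_s in starts:
        res = optimize.minimize(
            _trunc_nb_negll,
            x0=np.log([mu_s, size_s]),
            args=(values, weights, t),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
        last = res
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise TruncatedNBError("truncated NB fit failed to converge", last_iterate=last)
    mu_hat, size_hat = np.exp(best.x)
    fit = TruncNBFit(
        mu=float(mu_hat),
        size=float(size_hat),
        truncation_point=int(t),
        loglik=float(-best.fun),
        threshold=0,
        n_fitted=int(len(x)),
        converged=bool(best.success),
    )
    q = interactability_threshold(fit)
    return TruncNBFit(
        fit.mu, fit.size, fit.truncation_point, fit.loglik, q, fit.n_fitted, fit.converged
    )


def interactability_threshold(fit: TruncNBFit, quantile: float = 0.05) -> int:
    """Smallest integer q with untruncated CDF(q) >= ``quantile``."""
    p = _nb_p(fit.mu, fit.size)
    q = int(stats.nbinom.ppf(quantile, fit.size, p))
    # guard against ppf edge rounding; enforce CDF(q-1) < quantile <= CDF(q)
    while stats.nbinom.cdf(q, fit.size, p) < quantile:
        q += 1
    while q > 0 and stats.nbinom.cdf(q - 1, fit.size, p) >= quantile:
        q -= 1
    return q


def select_truncation_point(
    n_trans: np.ndarray,
    method: str = "valley",
    manual_t: int | None = None,
    smooth_window: int = 5,
    n_bins: int = 50,
) -> int:
    """Choose the left-truncation point for the upper (signal) component.

    ``valley``: histogram the counts on a log(1+x) axis with ``n_bins``
    equal-width bins, smooth with a centred moving average of
    ``smooth_window`` bins, locate the two tallest modes and return the
    count value at the minimum of the smoothed histogram between them. A
    unimodal histogram yields t = 0 with a warning. ``manual`` returns
    ``manual_t`` unchanged.
    """
    if method == "manual":
        if manual_t is None:
            raise ValueError("manual method requires manual_t")
        return int(manual_t)
    if method != "valley":
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(n_trans, dtype=float)
    if len(x) < 50:
        raise ValueError("valley method needs >= 50 fragments")
    z = np.log1p(x)
    hist, edges = np.histogram(z, bins=n_bins)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(hist, kernel, mode="same")
    # require genuine modes: prominence above histogram noise level
    peaks, props = signal.find_peaks(smoothed, prominence=0.1 * smoothed.max())
    props["peak_heights"] = smoothed[peaks]
    if len(peaks) < 2:
        warnings.warn("unimodal trans-count histogram; no truncation (t = 0)", stacklevel=2)
        return 0
    top2 = peaks[np.argsort(props["peak_heights"])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        warnings.warn("modes not separated; no truncation (t = 0)", stacklevel=2)
        return 0
    valley = lo + 1 + int(np.argmin(smoothed[lo + 1 : hi]))
    centre = 0.5 * (edges[valley] + edges[valley + 1])
    return int(round(np.expm1(centre)))


def filter_fragments(
    trans_counts: pd.DataFrame,
    fits: dict[object, TruncNBFit],
) -> pd.DataFrame:
    """Apply per-replicate thresholds; keep a fragment only if it passes all.

    ``trans_counts`` is the long table (frag_id, replicate_id, n_trans);
    ``fits`` maps replicate_id -> TruncNBFit for one cell line. A fragment
    missing a replicate's N_T is treated as N_T = 0 (and so fails unless the
    threshold is 0). Returns a table with per-replicate N_T and threshold
    columns plus a boolean ``kept``.
    """
    reps = list(fits)
    wide = (
        trans_counts.pivot_table(
            index="frag_id", columns="replicate_id", values="n_trans", fill_value=0
        )
        .reindex(columns=reps, fill_value=0)
        .astype(int)
    )
    kept = pd.Series(True, index=wide.index)
    for rep in reps:
        kept &= wide[rep] >= fits[rep].threshold
    out = wide.copy()
    out.columns = [f"n_trans_{r}" for r in reps]
    for rep in reps:
        out[f"threshold_{rep}"] = fits[rep].threshold
    out["kept"] = kept
    return out.reset_index()


def fit_interactability_filters(
    trans_counts: pd.DataFrame,
    method: str = "valley",
    manual_t: dict[object, int] | None = None,
    quantile: float = 0.05,
) -> dict[object, TruncNBFit]:
    """Per-replicate truncation selection + truncated-NB fit for one cell line."""
    fits: dict[object, TruncNBFit] = {}
    for rep, sub in trans_counts.groupby("replicate_id"):
        x = sub["n_trans"].to_numpy()
        if manual_t is not None and rep in manual_t:
            t = int(manual_t[rep])
        else:
            t = select_truncation_point(x, method=method)
        fit = fit_truncated_nb(x, t)
        if quantile != 0.05:
            q = interactability_threshold(fit, quantile)
            fit = TruncNBFit(fit.mu, fit.size, fit.truncation_point, fit.loglik, q, fit.n_fitted, fit.converged)
        fits[rep] = fit
    return fits
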