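"""Molecular-mobility analysis: jump distances, squared-displacement (SQD)
mixture fitting, MSD curves, and dwell-time decomposition.

Under Brownian motion with diffusion coefficient ``D`` and frame interval
``dt``, the squared frame-to-frame displacement ``r²`` is exponentially
distributed with mean ``4 D dt`` (the jump distance itself is Rayleigh).  A
``k``-population mixture therefore has the cumulative distribution

    F(x) = 1 - sum_i f_i * exp(-x / (4 D_i dt)),      sum_i f_i = 1,

which is fitted here to the empirical CDF of all pooled squared
displacements by nonlinear least squares (the convention of established SPT
analysis suites), with an optional maximum-likelihood route.  Components are
reported sorted by ``D`` ascending — confined, slow-mobile, fast-mobile.

Dwell times (durations a molecule stays within a small radius) are fitted
with left-truncated one- or two-component exponential models by maximum
likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "JumpData",
    "DiffusionMixtureFit",
    "MSDCurve",
    "DwellFit",
    "FitError",
    "JumpDistanceMixture",
    "DwellTimeFit",
    "compute_jump_distances",
    "fit_sqd_mixture",
    "select_mixture_order",
    "compute_msd",
    "extract_dwell_events",
    "fit_dwell_times",
]

DEFAULT_DT = 0.013  # s, effective frame interval (10 ms exposure + transfer)


class FitError(RuntimeError):
    """The mixture fit failed to converge from every start."""


@dataclass
class JumpData:
    """Pooled squared frame-to-frame displacements at a fixed lag."""

    r2: np.ndarray  # µm²
    dt: float  # s (time corresponding to the lag)
    track_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        if np.any(self.r2 < 0):
            raise ValueError("squared displacements must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_jumps(self) -> int:
        return len(self.r2)


@dataclass
class DiffusionMixtureFit:
    """Result of a k-component SQD mixture fit (components sorted by D)."""

    k: int
    D: np.ndarray  # µm²/s, ascending
    f: np.ndarray  # fractions, sum to 1
    D_se: np.ndarray
    f_se: np.ndarray
    rss: float
    n_jumps: int
    dt: float

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        assert abs(self.f.sum() - 1.0) < 1e-6
        assert np.all(np.diff(self.D) >= 0)


@dataclass
class MSDCurve:
    lags_s: np.ndarray
    msd: np.ndarray  # µm²
    sem: np.ndarray
    D: float  # µm²/s from the linear fit MSD = 4 D tau + b
    intercept: float
    n_per_lag: np.ndarray


@dataclass
class DwellFit:
    """Truncated-exponential dwell-time fit (order 1 or 2)."""

    order: int
    tau: tuple[float, ...]  # s, ascending for order 2
    percentages: tuple[float, ...]  # sum to 100
    loglik: float
    n: int
    t_min: float


# ---------------------------------------------------------------------------
# jump distances
# ---------------------------------------------------------------------------

def compute_jump_distances(tracks: pd.DataFrame, lag: int = 1, dt: float = DEFAULT_DT) -> JumpData:
    """Pool squared displacements ``r²_t = (x_{t+lag}-x_t)² + (y_{t+lag}-y_t)²``
    over all tracks; tracks shorter than ``lag + 1`` contribute nothing."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    r2_all = []
    ids = []
    for tid, grp in tracks.groupby("track_id"):
        g = grp.sort_values("frame")
        x = g["x_um"].to_numpy()
        y = g["y_um"].to_numpy()
        if len(x) <= lag:
            continue
        r2 = (x[lag:] - x[:-lag]) ** 2 + (y[lag:] - y[:-lag]) ** 2
        r2_all.append(r2)
        ids.append(np.full(len(r2), tid))
    if r2_all:
        r2_arr = np.concatenate(r2_all)
        id_arr = np.concatenate(ids)
    else:
        r2_arr = np.empty(0)
        id_arr = np.empty(0)
    return JumpData(r2=r2_arr, dt=lag * dt, track_ids=id_arr)


# ---------------------------------------------------------------------------
# SQD mixture fitting
# ---------------------------------------------------------------------------

def _mixture_cdf(x, D, f, dt, loc_var=0.0):
    scales = 4.0 * D * dt + 4.0 * loc_var
    scales = np.maximum(scales, 1e-30)
    return 1.0 - np.exp(-x[:, None] / scales[None, :]) @ f


class JumpDistanceMixture(BaseEstimator):
    """Rayleigh/exponential mixture of squared displacements, fitted on the
    empirical CDF by least squares.

    Parameters
    ----------
    k : number of diffusive populations (1-3).
    dt : frame interval in s.
    n_starts : multi-start count; starting D values are spread over the
        quantiles of the single-jump estimates ``r² / (4 dt)`` with seeded
        jitter, so fits are reproducible.
    loc_error : localization-error SD in µm. ``None`` (default) fits the
        uncorrected model — reported D are apparent coefficients, matching
        the convention of the emulated analysis lineage; a float fits
        ``x / (4 D dt + 4 sigma²)`` instead.
    fix_D : optional sequence of k diffusion coefficients to hold fixed so
        that only the fractions are fitted.  Fixing shared D values (e.g.
        from a pooled fit across experimental conditions) removes the
        confined/slow trade-off and greatly stabilizes fraction estimates
        when comparing conditions.
    random_state : seed for the multi-start jitter.

    Attributes (after ``fit``)
    --------------------------
    D_, f_ : coefficients (µm²/s, ascending) and fractions (sum to 1).
    D_se_, f_se_ : standard errors (delta method for the fractions).
    rss_ : residual sum of squares on the empirical CDF.
    n_jumps_ : number of squared displacements used.
    """

    def __init__(
        self,
        k: int = 3,
        dt: float = DEFAULT_DT,
        n_starts: int = 10,
        loc_error: float | None = None,
        fix_D=None,
        random_state: int = 0,
    ):
        self.k = k
        self.dt = dt
        self.n_starts = n_starts
        self.loc_error = loc_error
        self.fix_D = fix_D
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _initial_D(self, r2: np.ndarray, rng: np.random.Generator, jitter: bool):
        # spread quantiles of the single-jump D estimates across components
        qs = np.linspace(0.25, 0.95, self.k)
        if jitter:
            qs = np.clip(qs + rng.uniform(-0.15, 0.15, self.k), 0.02, 0.98)
        qs = np.sort(qs)
        d1 = r2 / (4.0 * self.dt)
        # quantile of an Exp(mean=D) at q is -D ln(1-q); invert per component
        vals = np.quantile(d1, qs) / -np.log1p(-qs)
        return np.maximum(np.sort(vals), 1e-8)

    def fit(self, X, y=None):
        r2 = np.asarray(X, dtype=float).ravel()
        if np.any(r2 < 0):
            raise ValueError("squared displacements must be >= 0")
        if not 1 <= self.k <= 3:
            raise ValueError("k must be 1, 2 or 3")
        n = len(r2)
        if n < 50 * self.k:
            raise ValueError(f"need at least {50 * self.k} jumps for k={self.k}")
        x = np.sort(r2)
        ecdf = (np.arange(1, n + 1) - 0.5) / n
        loc_var = 0.0 if self.loc_error is None else float(self.loc_error) ** 2
        k = self.k
        dt = self.dt

        def residual(params):
            D = np.array([params[f"D{i}"].value for i in range(k)])
            p = np.array([params[f"p{i}"].value for i in range(k)])
            f = p / p.sum()
            return _mixture_cdf(x, D, f, dt, loc_var) - ecdf

        fix_D = None if self.fix_D is None else np.asarray(self.fix_D, dtype=float)
        if fix_D is not None and len(fix_D) != k:
            raise ValueError("fix_D must have length k")
        rng = np.random.default_rng(self.random_state)
        best = None
        for start in range(self.n_starts):
            D0 = fix_D if fix_D is not None else self._initial_D(x, rng, jitter=start > 0)
            params = lmfit.Parameters()
            for i in range(k):
                params.add(f"D{i}", value=float(D0[i]), min=0.0,
                           vary=fix_D is None)
            params.add("p0", value=1.0, vary=False)
            for i in range(1, k):
                params.add(f"p{i}", value=float(rng.uniform(0.5, 1.5)) if start else 1.0,
                           min=1e-12)
            try:
                res = lmfit.minimize(residual, params, method="leastsq")
            except Exception:
                continue
            rss = float(np.sum(res.residual**2))
            if best is None or rss < best[0]:
                best = (rss, res)
        if best is None:
            raise FitError(f"SQD mixture fit (k={k}) failed from all starts")

        rss, res = best
        D = np.array([res.params[f"D{i}"].value for i in range(k)])
        p = np.array([res.params[f"p{i}"].value for i in range(k)])
        f = p / p.sum()
        D_se = np.array(
            [res.params[f"D{i}"].stderr or np.nan for i in range(k)], dtype=float
        )
        f_se = self._fraction_se(res, p, k)

        order = np.argsort(D)
        self.D_ = D[order]
        self.f_ = f[order]
        self.D_se_ = D_se[order]
        self.f_se_ = f_se[order]
        self.rss_ = rss
        self.n_jumps_ = n
        return self

    @staticmethod
    def _fraction_se(res, p: np.ndarray, k: int) -> np.ndarray:
        """Delta-method SEs for f_i = p_i / sum(p) (p0 is fixed at 1)."""
        if k == 1:
            return np.array([0.0])
        if getattr(res, "covar", None) is None:
            return np.full(k, np.nan)
        var_names = list(res.var_names)
        C = res.covar
        S = p.sum()
        se = np.empty(k)
        for i in range(k):
            g = np.zeros(len(var_names))
            for j in range(1, k):  # p0 fixed
                name = f"p{j}"
                if name not in var_names:
                    continue
                gj = ((1.0 if i == j else 0.0) * S - p[i]) / S**2
                g[var_names.index(name)] = gj
            se[i] = np.sqrt(max(g @ C @ g, 0.0))
        return se

    def cdf(self, x):
        """Fitted mixture CDF of squared displacements."""
        x = np.asarray(x, dtype=float)
        loc_var = 0.0 if self.loc_error is None else float(self.loc_error) ** 2
        return _mixture_cdf(x.ravel(), self.D_, self.f_, self.dt, loc_var).reshape(x.shape)


def fit_sqd_mixture(
    jumps: JumpData,
    k: int = 3,
    n_starts: int = 10,
    loc_error: float | None = None,
    fix_D=None,
    random_state: int = 0,
) -> DiffusionMixtureFit:
    """Fit a k-component SQD mixture to pooled squared displacements."""
    est = JumpDistanceMixture(
        k=k, dt=jumps.dt, n_starts=n_starts, loc_error=loc_error,
        fix_D=fix_D, random_state=random_state,
    ).fit(jumps.r2)
    return DiffusionMixtureFit(
        k=k, D=est.D_, f=est.f_, D_se=est.D_se_, f_se=est.f_se_,
        rss=est.rss_, n_jumps=est.n_jumps_, dt=jumps.dt,
    )


def select_mixture_order(
    jumps: JumpData,
    k_max: int = 3,
    rel_improvement: float = 0.05,
    **fit_kwargs,
) -> tuple[int, dict[int, DiffusionMixtureFit]]:
    """Pick the smallest adequate number of diffusive populations.

    k components suffice when either (i) the fit residual RMSE is already at
    the empirical-CDF sampling-noise floor ``sqrt(mean(F(1-F))/n)`` — beyond
    which extra components only chase ECDF noise — or (ii) adding a
    component improves the RSS by no more than ``rel_improvement``
    (default 5%).

    Returns ``(k, fits)`` with every attempted fit for inspection.
    """
    n = jumps.n_jumps
    ecdf = (np.arange(1, n + 1) - 0.5) / n
    noise_floor = float(np.sqrt(np.mean(ecdf * (1.0 - ecdf)) / n))
    fits: dict[int, DiffusionMixtureFit] = {}
    for k in range(1, k_max + 1):
        fits[k] = fit_sqd_mixture(jumps, k=k, **fit_kwargs)
    for k in range(1, k_max):
        if np.sqrt(fits[k].rss / n) <= noise_floor:
            return k, fits
        gain = (fits[k].rss - fits[k + 1].rss) / fits[k].rss
        if gain <= rel_improvement:
            return k, fits
    return k_max, fits


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def compute_msd(
    tracks: pd.DataFrame,
    max_lag: int,
    dt: float = DEFAULT_DT,
    fit_lags: int = 4,
) -> MSDCurve:
    """Time-and-ensemble averaged MSD with a linear fit MSD = 4 D tau + b
    over the first ``fit_lags`` lags (the offset absorbs localization error).

    Lags with no contributing track pair are omitted from the curve.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    lags, msd, sem, counts = [], [], [], []
    groups = [
        (g.sort_values("frame")[["x_um", "y_um"]].to_numpy())
        for _, g in tracks.groupby("track_id")
    ]
    for lag in range(1, max_lag + 1):
        vals = []
        for xy in groups:
            if len(xy) <= lag:
                continue
            d = xy[lag:] - xy[:-lag]
            vals.append(d[:, 0] ** 2 + d[:, 1] ** 2)
        if not vals:
            continue
        v = np.concatenate(vals)
        lags.append(lag * dt)
        msd.append(v.mean())
        sem.append(v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
        counts.append(len(v))
    lags = np.asarray(lags)
    msd = np.asarray(msd)
    n_fit = min(fit_lags, len(lags))
    if n_fit >= 2:
        slope, intercept = np.polyfit(lags[:n_fit], msd[:n_fit], 1)
    elif n_fit == 1:
        slope, intercept = msd[0] / lags[0], 0.0
    else:
        slope, intercept = np.nan, np.nan
    return MSDCurve(
        lags_s=lags, msd=msd, sem=np.asarray(sem),
        D=float(slope) / 4.0, intercept=float(intercept),
        n_per_lag=np.asarray(counts),
    )


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

def extract_dwell_events(
    tracks: pd.DataFrame, r_dwell: float = 0.1, dt: float = DEFAULT_DT
) -> np.ndarray:
    """Dwell-event durations (s) from tracks.

    A dwell event is a maximal run of consecutive frames whose positions all
    lie within ``r_dwell`` (µm) of the run's first position; runs shorter
    than 2 frames are discarded; duration = (n_frames - 1) * dt.
    """
    if r_dwell <= 0:
        raise ValueError("r_dwell must be positive")
    durations = []
    for _, grp in tracks.groupby("track_id"):
        xy = grp.sort_values("frame")[["x_um", "y_um"]].to_numpy()
        i = 0
        n = len(xy)
        while i < n:
            anchor = xy[i]
            j = i + 1
            while j < n and np.hypot(*(xy[j] - anchor)) <= r_dwell:
                j += 1
            if j - i >= 2:
                durations.append((j - i - 1) * dt)
            i = j
    return np.asarray(durations)


class DwellTimeFit(BaseEstimator):
    """Maximum-likelihood left-truncated exponential dwell-time model.

    ``order=1`` fits a single exponential with the closed-form MLE
    ``tau = mean(d) - t_min``; ``order=2`` fits a two-component exponential
    mixture on the shifted durations by EM (multi-start, seeded).  Degenerate
    data (all durations equal) fall back to order 1 with a warning.

    Attributes: ``tau_`` (ascending), ``percentages_`` (sum to 100),
    ``loglik_``, ``order_``, ``n_``.
    """

    def __init__(
        self,
        order: int = 2,
        t_min: float = 0.0,
        n_starts: int = 5,
        max_iter: int = 2000,
        tol: float = 1e-10,
        random_state: int = 0,
    ):
        self.order = order
        self.t_min = t_min
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        d = np.asarray(X, dtype=float).ravel()
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        d = d[d >= self.t_min]
        if len(d) < 20:
            raise ValueError("need at least 20 durations >= t_min")
        y_ = d - self.t_min
        self.n_ = len(y_)

        order = self.order
        if order == 2 and np.ptp(y_) == 0:
            warnings.warn("degenerate durations (all equal); falling back to order 1")
            order = 1

        if order == 1:
            tau = float(np.mean(y_))
            self.tau_ = (tau,)
            self.percentages_ = (100.0,)
            self.loglik_ = float(np.sum(-np.log(tau) - y_ / tau))
            self.order_ = 1
            return self

        rng = np.random.default_rng(self.random_state)
        best = None
        for start in range(self.n_starts):
            if start == 0:
                split = np.median(y_)
            else:
                split = np.quantile(y_, rng.uniform(0.2, 0.8))
            lo = y_[y_ <= split]
            hi = y_[y_ > split]
            tau1 = max(np.mean(lo), 1e-6) if len(lo) else np.mean(y_) / 2
            tau2 = max(np.mean(hi), tau1 * 1.5) if len(hi) else np.mean(y_) * 2
            pi1 = np.clip(len(lo) / len(y_), 0.05, 0.95)
            fit = self._em(y_, np.array([tau1, tau2]), np.array([pi1, 1 - pi1]))
            if fit is not None and (best is None or fit[2] > best[2]):
                best = fit
        if best is None:
            warnings.warn("two-component dwell fit degenerate; falling back to order 1")
            self.order = 1
            return self.fit(X)
        tau, pi, ll = best
        order_idx = np.argsort(tau)
        self.tau_ = tuple(float(t) for t in tau[order_idx])
        self.percentages_ = tuple(float(100 * p) for p in pi[order_idx])
        self.loglik_ = float(ll)
        self.order_ = 2
        return self

    def _em(self, y, tau, pi):
        ll_prev = -np.inf
        for _ in range(self.max_iter):
            with np.errstate(over="ignore", under="ignore"):
                dens = pi[None, :] / tau[None, :] * np.exp(-y[:, None] / tau[None, :])
            tot = dens.sum(axis=1)
            if np.any(tot <= 0) or np.any(~np.isfinite(tot)):
                return None
            ll = float(np.sum(np.log(tot)))
            resp = dens / tot[:, None]
            w = resp.sum(axis=0)
            if np.any(w < 1e-12):
                return None
            pi = w / len(y)
            tau = (resp * y[:, None]).sum(axis=0) / w
            tau = np.maximum(tau, 1e-9)
            if abs(ll - ll_prev) < self.tol * (1 + abs(ll)):
                break
            ll_prev = ll
        return tau, pi, ll


def fit_dwell_times(
    durations: np.ndarray,
    order: int = 2,
    t_min: float = 0.0,
    **kwargs,
) -> DwellFit:
    """Fit a left-truncated exponential (order 1) or exponential mixture
    (order 2) to dwell durations; see :class:`DwellTimeFit`."""
    est = DwellTimeFit(order=order, t_min=t_min, **kwargs).fit(durations)
    return DwellFit(
        order=est.order_, tau=est.tau_, percentages=est.percentages_,
        loglik=est.loglik_, n=est.n_, t_min=t_min,
    )
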