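"""Maximum-likelihood fitting of dwell-time, run-length and velocity distributions.

Dwell times of transiently binding myosin II filaments follow mixtures of
exponentials; because events shorter than the detection limit ``t_min`` are
unobservable and events longer than the recording window are discarded, the
mixture density is renormalized on the observation window [t_min, t_max] and
fitted by maximum likelihood on the *unbinned* data (histogram binning is
for display only).  Confidence intervals come from nonparametric bootstrap
resampling; model order is selected by BIC, with likelihood-ratio p-values
reported for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates
from scipy.special import logsumexp

from .stack import ImageStack

__all__ = [
    "ExpMixtureFit", "GaussMixFit", "RunLengthFit",
    "fit_exp_mixture", "bootstrap_ci", "select_model",
    "fit_run_lengths", "fit_velocities",
    "correlate_run_dwell", "ks_compare", "kymograph",
]


@dataclass
class ExpMixtureFit:
    """Truncated multi-exponential dwell-time model.

    ``fractions`` sum to one; ``taus`` (seconds) are strictly ascending.
    The density is f(t) = sum_i a_i exp(-t/tau_i)/tau_i renormalized on
    [t_min, t_max].  ``ci95`` maps parameter names ('tau0', 'frac0', ...)
    to bootstrap percentile intervals once ``bootstrap_ci`` has run.
    """

    k: int
    fractions: np.ndarray
    taus: np.ndarray
    t_min_s: float
    t_max_s: float
    loglik: float
    n: int
    ci95: dict = field(default_factory=dict)
    collapsed: bool = False

    def density(self, t):
        t = np.asarray(t, dtype=float)
        num = np.zeros_like(t)
        norm = 0.0
        for a, tau in zip(self.fractions, self.taus):
            num += a * np.exp(-t / tau) / tau
            norm += a * (np.exp(-self.t_min_s / tau)
                         - (0.0 if np.isinf(self.t_max_s)
                            else np.exp(-self.t_max_s / tau)))
        return num / norm


@dataclass
class GaussMixFit:
    """Gaussian mixture of speeds (um/s)."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n: int
    degenerate: bool = False


@dataclass
class RunLengthFit:
    """Left-truncated exponential run-length model."""

    lambda_um: float
    ci95: tuple[float, float]
    min_run_um: float
    n: int


# --------------------------------------------------------------------------
# Truncated exponential mixtures
# --------------------------------------------------------------------------

def _component_norm(tau: np.ndarray, t_min: float, t_max: float) -> np.ndarray:
    """Probability mass of each exponential component on [t_min, t_max]."""
    return np.exp(-t_min / tau) - (0.0 if np.isinf(t_max)
                                   else np.exp(-t_max / tau))


def _mixture_loglik(t: np.ndarray, fractions: np.ndarray, tau: np.ndarray,
                    t_min: float, t_max: float) -> float:
    """Log-likelihood of the renormalized mixture density on [t_min, t_max]."""
    log_terms = (np.log(fractions)[None, :] - t[:, None] / tau[None, :]
                 - np.log(tau)[None, :])
    ll = logsumexp(log_terms, axis=1).sum()
    norm = float(np.dot(fractions, _component_norm(tau, t_min, t_max)))
    if norm <= 0:
        return -np.inf
    return float(ll - t.size * np.log(norm))


def _solve_truncated_tau(mean_t: float, t_min: float, t_max: float,
                         tau0: float) -> float:
    """tau matching a weighted mean under two-sided truncation (scalar solve).

    Under truncation to [t_min, t_max] the expected duration is
    t_min + tau - D*exp(-D/tau)/(1 - exp(-D/tau)) with D = t_max - t_min;
    for one-sided truncation (t_max = inf) this reduces to t_min + tau.
    """
    if np.isinf(t_max):
        return max(mean_t - t_min, 1e-8)
    D = t_max - t_min

    def expected(tau):
        x = D / tau
        if x > 500:
            return t_min + tau
        return t_min + tau - D * np.exp(-x) / (1.0 - np.exp(-x))

    lo, hi = 1e-6, max(10.0 * tau0, 10.0 * D)
    if expected(lo) >= mean_t:
        return lo
    if expected(hi) <= mean_t:
        return hi
    from scipy.optimize import brentq
    return float(brentq(lambda x: expected(x) - mean_t, lo, hi, xtol=1e-12))


def _em_fit(t: np.ndarray, b: np.ndarray, tau: np.ndarray, t_min: float,
            t_max: float, max_iter: int = 3000, tol: float = 1e-8):
    """EM in the truncated-component parametrization.

    ``b`` are the weights of the *truncated-normalized* components; the
    M-step for tau is a responsibility-weighted mean of (t - t_min) when
    t_max is infinite, otherwise a scalar root-find per component.
    Returns (b, tau, loglik in that parametrization).
    """
    n = t.size
    ll_old = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        Z = np.maximum(_component_norm(tau, t_min, t_max), 1e-300)
        logp = (np.log(b)[None, :] - t[:, None] / tau[None, :]
                - np.log(tau)[None, :] - np.log(Z)[None, :])
        lse = logsumexp(logp, axis=1)
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        b = nk / n
        means = (resp * t[:, None]).sum(axis=0) / nk
        tau = np.array([_solve_truncated_tau(m, t_min, t_max, tk)
                        for m, tk in zip(means, tau)])
        if abs(ll - ll_old) < tol:
            break
        # components that have already collapsed will be refit with k-1;
        # no point polishing a non-identifiable optimum
        if tau.size > 1 and tau.max() / tau.min() < 1.01:
            break
        ll_old = ll
    return b, tau, ll


def _b_to_fractions(b: np.ndarray, tau: np.ndarray, t_min: float,
                    t_max: float) -> np.ndarray:
    """Convert truncated-component weights to untruncated mixture fractions."""
    Z = np.maximum(_component_norm(tau, t_min, t_max), 1e-300)
    a = b / Z
    return a / a.sum()


def fit_exp_mixture(durations, k: int, t_min_s: float = 0.0,
                    t_max_s: float = np.inf, seed: int = 0,
                    n_starts: int = 5) -> ExpMixtureFit:
    """Fit a k-component exponential mixture truncated to [t_min, t_max].

    Maximizes the likelihood of the renormalized mixture density on the
    unbinned durations by expectation-maximization with deterministic
    quantile-spread starting points plus seeded jitter (the reported fit is
    the best of all starts, so repeated calls with the same data and seed
    are identical).  The reported ``fractions`` are the weights of the
    *untruncated* mixture — the fraction of all binding events, observed or
    not, belonging to each component.  For k=1 the MLE is closed-form
    (sample mean, shifted by ``t_min`` for one-sided truncation).  If two
    time constants collapse within 1% the model is declared
    non-identifiable and refitted with k-1 components (``collapsed`` flag).
    """
    t = np.asarray(durations, dtype=float)
    if t.size < 10 * k:
        raise ValueError(f"need at least {10 * k} durations for k={k}")
    if np.any(t < t_min_s) or np.any(t > t_max_s):
        raise ValueError("durations must lie within [t_min, t_max]")
    if not t_min_s < t_max_s:
        raise ValueError("t_min must be < t_max")

    if k == 1:
        tau = _solve_truncated_tau(float(t.mean()), t_min_s, t_max_s,
                                   max(float(t.mean() - t_min_s), 1e-6))
        a = np.array([1.0])
        ll = _mixture_loglik(t, a, np.array([tau]), t_min_s, t_max_s)
        return ExpMixtureFit(k=1, fractions=a, taus=np.array([tau]),
                             t_min_s=t_min_s, t_max_s=t_max_s, loglik=ll,
                             n=t.size)

    rng = np.random.default_rng(seed)
    qs = np.quantile(t - t_min_s, np.linspace(0.2, 0.9, k))
    qs = np.maximum(qs, 1e-3)
    starts = [(np.full(k, 1.0 / k), qs)]
    for _ in range(n_starts - 1):
        starts.append((np.full(k, 1.0 / k),
                       qs * np.exp(rng.normal(0, 0.7, k))))
    best = None
    for b0, tau0 in starts:
        b, tau, ll = _em_fit(t, b0.copy(), tau0.copy(), t_min_s, t_max_s)
        if best is None or ll > best[2]:
            best = (b, tau, ll)
    b, tau, _ = best
    order = np.argsort(tau)
    b, tau = b[order], tau[order]
    a = _b_to_fractions(b, tau, t_min_s, t_max_s)
    if np.any(tau[1:] / tau[:-1] < 1.01):
        warnings.warn(f"time constants collapsed (k={k}); refitting with k={k - 1}")
        sub = fit_exp_mixture(t, k - 1, t_min_s, t_max_s, seed=seed,
                              n_starts=n_starts)
        sub.collapsed = True
        return sub
    ll = _mixture_loglik(t, a, tau, t_min_s, t_max_s)
    return ExpMixtureFit(k=k, fractions=a, taus=tau, t_min_s=t_min_s,
                         t_max_s=t_max_s, loglik=ll, n=t.size)


def _refit_from(fit: ExpMixtureFit, t: np.ndarray) -> ExpMixtureFit | None:
    """Refit a bootstrap replicate starting from the point estimate."""
    k = fit.k
    if k == 1:
        tau = _solve_truncated_tau(float(t.mean()), fit.t_min_s, fit.t_max_s,
                                   float(fit.taus[0]))
        if tau <= 0:
            return None
        return ExpMixtureFit(k=1, fractions=np.array([1.0]), taus=np.array([tau]),
                             t_min_s=fit.t_min_s, t_max_s=fit.t_max_s,
                             loglik=np.nan, n=t.size)
    Z = _component_norm(fit.taus, fit.t_min_s, fit.t_max_s)
    b0 = fit.fractions * Z
    b0 /= b0.sum()
    b, tau, ll = _em_fit(t, b0, fit.taus.copy(), fit.t_min_s, fit.t_max_s,
                         max_iter=1500, tol=1e-8)
    if not np.isfinite(ll):
        return None
    order = np.argsort(tau)
    b, tau = b[order], tau[order]
    a = _b_to_fractions(b, tau, fit.t_min_s, fit.t_max_s)
    return ExpMixtureFit(k=k, fractions=a, taus=tau,
                         t_min_s=fit.t_min_s, t_max_s=fit.t_max_s,
                         loglik=ll, n=t.size)


def bootstrap_ci(durations, fit: ExpMixtureFit, B: int = 500,
                 seed: int = 0) -> dict:
    """Nonparametric bootstrap 95% percentile intervals for every parameter.

    Resamples the durations with replacement, refits each replicate from
    the point estimate, and takes the 2.5/97.5 percentiles.  More than 10%
    replicate failures aborts with the failure count.
    """
    if B < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    t = np.asarray(durations, dtype=float)
    rng = np.random.default_rng(seed)
    taus = []
    fracs = []
    failures = 0
    for _ in range(B):
        sample = rng.choice(t, size=t.size, replace=True)
        rep = _refit_from(fit, sample)
        if rep is None or rep.k != fit.k:
            failures += 1
            continue
        taus.append(rep.taus)
        fracs.append(rep.fractions)
    if failures > 0.1 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicate fits failed")
    taus = np.array(taus)
    fracs = np.array(fracs)
    ci: dict = {}
    for i in range(fit.k):
        ci[f"tau{i}"] = tuple(np.percentile(taus[:, i], [2.5, 97.5]))
        ci[f"frac{i}"] = tuple(np.percentile(fracs[:, i], [2.5, 97.5]))
    fit.ci95 = ci
    return ci


def select_model(durations, k_max: int = 3, t_min_s: float = 0.0,
                 t_max_s: float = np.inf, seed: int = 0) -> dict:
    """Fit k = 1..k_max mixtures and select the model order by BIC.

    Returns ``{'k_best', 'fits', 'bic', 'logliks', 'lrt_p'}`` where
    ``lrt_p[k]`` is the (approximate, chi-square with 2 df) likelihood-ratio
    p-value of the k+1 model against the k model, reported for comparison
    with likelihood-ratio-based selection.
    """
    if k_max > 4:
        raise ValueError("k_max must be <= 4")
    t = np.asarray(durations, dtype=float)
    fits = {}
    bic = {}
    for k in range(1, k_max + 1):
        f = fit_exp_mixture(t, k, t_min_s, t_max_s, seed=seed)
        fits[k] = f
        n_params = 2 * f.k - 1
        bic[k] = n_params * np.log(t.size) - 2.0 * f.loglik
    k_best = min(bic, key=bic.get)
    lrt_p = {}
    for k in range(1, k_max):
        if k in fits and (k + 1) in fits:
            lr = 2.0 * (fits[k + 1].loglik - fits[k].loglik)
            lrt_p[k] = float(stats.chi2.sf(max(lr, 0.0), df=2))
    return {"k_best": k_best, "fits": fits, "bic": bic,
            "logliks": {k: f.loglik for k, f in fits.items()}, "lrt_p": lrt_p}


# --------------------------------------------------------------------------
# Run lengths and velocities
# --------------------------------------------------------------------------

def fit_run_lengths(runs_um, min_run_um: float = 0.0, B: int = 500,
                    seed: int = 0) -> RunLengthFit:
    """Exponential MLE of run lengths with left truncation.

    For an exponential left-truncated at ``min_run_um`` (the shortest
    resolvable run, typically one pixel step) the MLE is the sample mean
    minus the truncation point.  The 95% CI is a nonparametric bootstrap
    percentile interval.
    """
    r = np.asarray(runs_um, dtype=float)
    if r.size < 10:
        raise ValueError("need at least 10 run lengths")
    if np.any(r <= 0):
        raise ValueError("run lengths must be positive")
    if np.any(r < min_run_um):
        raise ValueError("runs below the truncation point")
    lam = float(r.mean() - min_run_um)
    rng = np.random.default_rng(seed)
    boot = rng.choice(r, size=(B, r.size), replace=True).mean(axis=1) - min_run_um
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return RunLengthFit(lambda_um=lam, ci95=(float(lo), float(hi)),
                        min_run_um=min_run_um, n=r.size)


def fit_velocities(speeds_um_s, k: int = 1, max_iter: int = 500,
                   tol: float = 1e-10) -> GaussMixFit:
    """Gaussian (k=1) or two-component Gaussian mixture (k=2) MLE of speeds.

    The two-component fit uses EM with a deterministic initialization by
    median split, so repeated fits of the same data are identical.  A
    degenerate component (vanishing weight or spread) falls back to the
    single Gaussian with the ``degenerate`` flag set.
    """
    v = np.asarray(speeds_um_s, dtype=float)
    if v.size < 20:
        raise ValueError("need at least 20 speeds")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    if k == 1:
        mu, sd = float(v.mean()), float(v.std())
        if sd <= 1e-12 * max(abs(mu), 1.0):
            sd = 0.0
        if sd == 0:
            warnings.warn("all speeds equal; sd = 0")
            ll = np.inf
        else:
            ll = float(stats.norm.logpdf(v, mu, sd).sum())
        return GaussMixFit(k=1, weights=np.array([1.0]), means=np.array([mu]),
                           sds=np.array([max(sd, 0.0)]), loglik=ll, n=v.size,
                           degenerate=sd == 0)
    med = np.median(v)
    lo, hi = v[v <= med], v[v > med]
    if hi.size == 0:
        return fit_velocities(v, k=1)
    w = np.array([lo.size, hi.size], dtype=float)
    w /= w.sum()
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.array([max(lo.std(), 1e-4), max(hi.std(), 1e-4)])
    ll_old = -np.inf
    for _ in range(max_iter):
        logp = (np.log(w)[None, :]
                + stats.norm.logpdf(v[:, None], mu[None, :], sd[None, :]))
        ll = float(logsumexp(logp, axis=1).sum())
        resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        nk = resp.sum(axis=0)
        if np.any(nk < 2) or np.any(sd < 1e-6):
            warnings.warn("degenerate mixture component; falling back to k=1")
            out = fit_velocities(v, k=1)
            out.degenerate = True
            return out
        w = nk / v.size
        mu = (resp * v[:, None]).sum(axis=0) / nk
        sd = np.sqrt((resp * (v[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk)
        sd = np.maximum(sd, 1e-8)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    order = np.argsort(mu)
    return GaussMixFit(k=2, weights=w[order], means=mu[order], sds=sd[order],
                       loglik=ll, n=v.size)


# --------------------------------------------------------------------------
# Correlation and distribution comparison
# --------------------------------------------------------------------------

def correlate_run_dwell(runs_um, dwells_s, split_s: float = 3.0) -> dict:
    """Pearson correlation of run length vs dwell time, split at ``split_s``.

    Returns ``{'short': (r, p, n), 'long': (r, p, n)}`` for dwell times
    <= split and > split; a regime with fewer than 3 pairs is omitted.
    """
    runs = np.asarray(runs_um, dtype=float)
    dwells = np.asarray(dwells_s, dtype=float)
    if runs.shape != dwells.shape:
        raise ValueError("runs and dwells must be paired")
    out: dict = {}
    for name, sel in (("short", dwells <= split_s), ("long", dwells > split_s)):
        if sel.sum() < 3:
            out[name] = None
            continue
        r, p = stats.pearsonr(runs[sel], dwells[sel])
        out[name] = (float(r), float(p), int(sel.sum()))
    return out


def ks_compare(sample_a, sample_b, min_t_s: float = 0.0) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on values above ``min_t_s``."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[a > min_t_s]
    b = b[b > min_t_s]
    if a.size == 0 or b.size == 0:
        raise ValueError("a sample is empty after filtering")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# Kymograph
# --------------------------------------------------------------------------

def kymograph(stack: ImageStack, polyline, line_width_px: int = 3) -> np.ndarray:
    """Contrast sampled along a polyline over time -> (position, time) array.

    The polyline (list of (x, y) pixel coordinates) is resampled at 1-px arc
    spacing; at each sample the contrast is averaged over ``line_width_px``
    perpendicular offsets (bilinear interpolation), reproducing a line-scan
    kymograph of the given width.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    H, W = stack.frame_shape
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > W - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > H - 1):
        raise ValueError("polyline exits the frame")
    # arc-length resampling at 1-px spacing
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    s_grid = np.arange(0.0, arclen[-1] + 1e-9, 1.0)
    xs = np.interp(s_grid, arclen, pts[:, 0])
    ys = np.interp(s_grid, arclen, pts[:, 1])
    # unit tangents -> normals for perpendicular averaging
    tx = np.gradient(xs)
    ty = np.gradient(ys)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx, ny = -ty / norm, tx / norm
    offsets = np.arange(line_width_px) - (line_width_px - 1) / 2.0
    out = np.zeros((s_grid.size, stack.n_frames))
    for f in range(stack.n_frames):
        acc = np.zeros(s_grid.size)
        for o in offsets:
            coords = np.vstack([ys + o * ny, xs + o * nx])
            acc += map_coordinates(stack.frames[f].astype(float), coords,
                                   order=1, mode="nearest")
        out[:, f] = acc / offsets.size
    return out
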