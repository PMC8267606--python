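"""Bifactor graded-response calibration, latent-trait scoring and item information.

Model
-----
Each ordinal item loads on one primary dimension and exactly one group
(subdomain) factor, all factors independent standard normal.  With slopes
``a0`` (primary) and ``ag`` (group) and ordered thresholds ``c_1 < ... <
c_{K-1}``, the cumulative probability of responding in category ``k`` or
above is logistic:

    P(Y >= k | th0, thg) = expit(a0*th0 + ag*thg - c_k)

Calibration maximizes the marginal likelihood by EM.  The bifactor
restriction reduces the integral to a sum of two-dimensional quadratures,
one per subdomain, regardless of the number of subdomains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from catcad.bank import (
    MISSING,
    Bank,
    ItemParams,
    ItemSpec,
    ResponseMatrix,
    collapse_sparse_categories,
)

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12


def gauss_hermite(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights rescaled to integrate against N(0, 1)."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def category_probs(
    a0: float,
    ag: float,
    thresholds: Sequence[float],
    theta0: np.ndarray | float,
    thetag: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Category probabilities of a graded item at latent values.

    ``theta0`` and ``thetag`` broadcast together; the returned array has one
    trailing axis of length ``n_categories``.
    """
    thr = np.asarray(thresholds, dtype=float)
    z = (
        a0 * np.asarray(theta0, dtype=float)[..., None]
        + ag * np.asarray(thetag, dtype=float)[..., None]
        - thr
    )
    s = expit(z)
    shape = s.shape[:-1]
    upper = np.concatenate([np.ones(shape + (1,)), s], axis=-1)
    lower = np.concatenate([s, np.zeros(shape + (1,))], axis=-1)
    return upper - lower


@dataclass(frozen=True)
class LatentState:
    """EAP estimate of the primary trait with its posterior SD."""

    theta: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"posterior SD must be positive, got {self.se}")


@dataclass(frozen=True)
class EstimationOptions:
    """Knobs for marginal-maximum-likelihood EM calibration."""

    quadrature_points: int = 21
    tol: float = 1e-5
    max_iter: int = 500
    m_step_maxiter: int = 50

    def __post_init__(self) -> None:
        if self.quadrature_points < 3:
            raise ValueError("quadrature_points must be >= 3")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


@dataclass
class CalibrationResult:
    """Fitted parameters plus the bookkeeping needed for model comparison."""

    bank: Bank
    model: str  # "bifactor" | "unidimensional"
    loglik: float
    n_iterations: int
    converged: bool
    loglik_trace: list[float]
    n_group_slopes: int
    data_fingerprint: str
    loadings: pd.DataFrame
    collapsed_categories: dict[str, list[int]] = field(default_factory=dict)

    def params(self, item_id: str) -> ItemParams:
        return self.bank.params[item_id]


class LrTestResult(NamedTuple):
    chi2: float
    df: int
    p: float


def standardized_loadings(params: ItemParams) -> tuple[float, float]:
    """Convert logistic slopes to standardized factor loadings.

    Uses the normal-metric convention ``lambda = a / sqrt(1 + a0^2 + ag^2)``
    so loadings are bounded by 1 in absolute value and a 0.3 discrimination
    cut is well defined.
    """
    denom = np.sqrt(1.0 + params.a0**2 + params.ag**2)
    return params.a0 / denom, params.ag / denom


# ---------------------------------------------------------------------------
# M-step: per-item expected complete-data likelihood
# ---------------------------------------------------------------------------


def _pack_item(params: ItemParams, free_ag: bool) -> np.ndarray:
    c = np.asarray(params.thresholds)
    gaps = np.clip(np.diff(c), 1.5e-3, 30.0)
    head = [params.a0, params.ag] if free_ag else [params.a0]
    return np.concatenate([head, [c[0]], np.log(gaps)])


def _unpack_item(x: np.ndarray, free_ag: bool) -> ItemParams:
    if free_ag:
        a0, ag, off = x[0], x[1], 2
    else:
        a0, ag, off = x[0], 0.0, 1
    d = np.exp(x[off + 1 :])
    c = x[off] + np.concatenate([[0.0], np.cumsum(d)])
    return ItemParams(float(a0), float(ag), tuple(c))


def _item_objective(
    x: np.ndarray,
    r: np.ndarray,
    t0: np.ndarray,
    tg: np.ndarray,
    free_ag: bool,
) -> tuple[float, np.ndarray]:
    """Negative expected complete-data log-likelihood and its gradient.

    ``r`` holds expected response counts per quadrature point, shape
    ``(Q, K)``; ``t0``/``tg`` are the flattened grid coordinates.
    """
    if free_ag:
        a0, ag, off = x[0], x[1], 2
    else:
        a0, ag, off = x[0], 0.0, 1
    d = np.exp(x[off + 1 :])
    c = x[off] + np.concatenate([[0.0], np.cumsum(d)])  # (K-1,)

    z = a0 * t0[:, None] + ag * tg[:, None] - c[None, :]
    s = expit(z)  # (Q, K-1)
    sp = s * (1.0 - s)
    q = t0.shape[0]
    upper = np.concatenate([np.ones((q, 1)), s], axis=1)
    lower = np.concatenate([s, np.zeros((q, 1))], axis=1)
    p = np.clip(upper - lower, _PROB_FLOOR, None)  # (Q, K)

    f = -float(np.sum(r * np.log(p)))

    g = r / p  # (Q, K)
    e = g[:, 1:] - g[:, :-1]  # (Q, K-1): dF/ds_m pre-factor (negated)
    v = e * sp
    vrow = v.sum(axis=1)
    da0 = -float(np.sum(vrow * t0))
    dc = v.sum(axis=0)  # (K-1,): dF/dc_m
    dc1 = float(dc.sum())
    # c_k = c_1 + sum_{i<k} d_i  ->  dF/dd_i = sum_{k >= i+1} dc_k
    if d.size:
        tail = np.cumsum(dc[::-1])[::-1]  # tail[i] = sum_{k >= i} dc_k
        du = d * tail[1:]
    else:
        du = np.empty(0)
    if free_ag:
        dag = -float(np.sum(vrow * tg))
        grad = np.concatenate([[da0, dag, dc1], du])
    else:
        grad = np.concatenate([[da0, dc1], du])
    return f, grad


def _optimize_item(
    r: np.ndarray,
    t0: np.ndarray,
    tg: np.ndarray,
    current: ItemParams,
    free_ag: bool,
    maxiter: int,
) -> ItemParams:
    x0 = _pack_item(current, free_ag)
    n_head = 2 if free_ag else 1
    bounds = (
        [(-12.0, 12.0)] * n_head
        + [(-25.0, 25.0)]
        + [(np.log(1e-3), 3.5)] * (len(current.thresholds) - 1)
    )
    f0, _ = _item_objective(x0, r, t0, tg, free_ag)
    res = minimize(
        _item_objective,
        x0,
        args=(r, t0, tg, free_ag),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter},
    )
    if np.isfinite(res.fun) and res.fun <= f0:
        return _unpack_item(res.x, free_ag)
    return current  # never move uphill: keeps the EM trace monotone


# ---------------------------------------------------------------------------
# E-step machinery
# ---------------------------------------------------------------------------


class _Calibrator:
    """Holds the data layout and quadrature for one calibration run."""

    def __init__(
        self,
        responses: ResponseMatrix,
        bank: Bank,
        options: EstimationOptions,
        model: str,
    ) -> None:
        responses.validate_against(bank)
        missing_items = set(bank.item_ids) - set(responses.item_ids)
        if missing_items:
            raise ValueError(
                f"bank items without response columns: {sorted(missing_items)[:5]}"
            )
        if len(bank) < 2:
            raise ValueError("need at least 2 items to calibrate")
        self.fingerprint = responses.fingerprint()
        responses, bank, self.collapsed = collapse_sparse_categories(responses, bank)
        if self.collapsed:
            logger.warning(
                "collapsed unobserved categories for %d item(s): %s",
                len(self.collapsed),
                dict(list(self.collapsed.items())[:5]),
            )
        self.model = model
        self.bank = bank.subset(responses.item_ids)
        self.specs = [self.bank.item(i) for i in responses.item_ids]
        self.item_ids = list(responses.item_ids)
        self.y = responses.codes.astype(np.int64)
        self.n_persons = responses.n_persons

        subdomains = self.bank.used_subdomains()
        sizes = {
            g: sum(1 for s in self.specs if s.subdomain == g) for g in subdomains
        }
        if model == "bifactor" and len(subdomains) >= 2:
            # a single-item subdomain cannot identify its group slope
            self.free_ag = {
                s.item_id: sizes[s.subdomain] >= 2 for s in self.specs
            }
        else:
            self.free_ag = {s.item_id: False for s in self.specs}
        self.any_free = any(self.free_ag.values())

        self.t0, self.w0 = gauss_hermite(options.quadrature_points)
        if self.any_free:
            self.tg, self.wg = gauss_hermite(options.quadrature_points)
        else:
            self.tg, self.wg = np.zeros(1), np.ones(1)
        self.logw0 = np.log(self.w0)
        self.logwg = np.log(self.wg)
        # flattened (theta0, thetag) grid used by the M-step
        self.t0f = np.repeat(self.t0, self.tg.size)
        self.tgf = np.tile(self.tg, self.t0.size)

        if self.any_free:
            self.groups = {
                g: [j for j, s in enumerate(self.specs) if s.subdomain == g]
                for g in subdomains
            }
        else:
            self.groups = {"_all": list(range(len(self.specs)))}
        self.options = options

    # -- likelihood pieces --------------------------------------------------

    def _item_logprobs(self, params: dict[str, ItemParams]) -> list[np.ndarray]:
        """Per item: log category probabilities on the flattened grid (Q, K)."""
        out = []
        for spec in self.specs:
            p = params[spec.item_id]
            ag = p.ag if self.free_ag[spec.item_id] else 0.0
            probs = category_probs(p.a0, ag, p.thresholds, self.t0f, self.tgf)
            out.append(np.log(np.clip(probs, _PROB_FLOOR, None)))
        return out

    def e_step(self, params: dict[str, ItemParams]):
        """Marginal log-likelihood and the pieces needed for posteriors."""
        lp = self._item_logprobs(params)
        n, q0, qg = self.n_persons, self.t0.size, self.tg.size
        group_a: dict[str, np.ndarray] = {}
        group_logf: dict[str, np.ndarray] = {}
        for g, idx in self.groups.items():
            acc = np.zeros((n, q0 * qg))
            for j in idx:
                col = self.y[:, j]
                obs = col != MISSING
                acc[obs] += lp[j].T[col[obs]]
            group_a[g] = acc
            group_logf[g] = logsumexp(
                acc.reshape(n, q0, qg) + self.logwg[None, None, :], axis=2
            )
        total = sum(group_logf.values())  # (n, q0)
        ll_n = logsumexp(total + self.logw0[None, :], axis=1)
        return float(ll_n.sum()), (group_a, group_logf, total, ll_n)

    def m_step(
        self, params: dict[str, ItemParams], estep
    ) -> dict[str, ItemParams]:
        group_a, group_logf, total, ll_n = estep
        n, q0, qg = self.n_persons, self.t0.size, self.tg.size
        new = dict(params)
        for g, idx in self.groups.items():
            log_w = (
                (total - group_logf[g] + self.logw0[None, :] - ll_n[:, None])[
                    :, :, None
                ]
                + self.logwg[None, None, :]
                + group_a[g].reshape(n, q0, qg)
            )
            w = np.exp(log_w).reshape(n, q0 * qg)
            for j in idx:
                spec = self.specs[j]
                col = self.y[:, j]
                k = spec.n_categories
                r = np.empty((q0 * qg, k))
                for c in range(k):
                    r[:, c] = w[col == c].sum(axis=0)
                new[spec.item_id] = _optimize_item(
                    r,
                    self.t0f,
                    self.tgf,
                    params[spec.item_id],
                    self.free_ag[spec.item_id],
                    self.options.m_step_maxiter,
                )
        return new

    # -- initial values -----------------------------------------------------

    def initial_params(self) -> dict[str, ItemParams]:
        params = {}
        for j, spec in enumerate(self.specs):
            col = self.y[:, j]
            vals = col[col != MISSING]
            k = spec.n_categories
            props_ge = np.array([(vals >= c).mean() for c in range(1, k)])
            c = -np.log(
                np.clip(props_ge, 1e-3, 1 - 1e-3)
                / (1 - np.clip(props_ge, 1e-3, 1 - 1e-3))
            )
            # enforce strict increase
            for i in range(1, c.size):
                c[i] = max(c[i], c[i - 1] + 0.05)
            ag = 0.5 if self.free_ag[spec.item_id] else 0.0
            params[spec.item_id] = ItemParams(1.0, ag, tuple(c))
        return params


def _reflect_signs(
    params: dict[str, ItemParams], specs: list[ItemSpec]
) -> dict[str, ItemParams]:
    """Apply the global sign convention (reflection invariance).

    Flipping the primary axis negates every ``a0``; flipping one group axis
    negates the ``ag`` of that subdomain. Neither changes the likelihood.
    """
    out = dict(params)
    if sum(out[s.item_id].a0 for s in specs) < 0:
        out = {
            k: ItemParams(-p.a0, p.ag, p.thresholds) for k, p in out.items()
        }
    for g in {s.subdomain for s in specs}:
        ids = [s.item_id for s in specs if s.subdomain == g]
        if sum(out[i].ag for i in ids) < 0:
            for i in ids:
                p = out[i]
                out[i] = ItemParams(p.a0, -p.ag, p.thresholds)
    return out


def _fit(
    responses: ResponseMatrix,
    bank: Bank,
    options: EstimationOptions,
    model: str,
) -> CalibrationResult:
    cal = _Calibrator(responses, bank, options, model)
    params = cal.initial_params()
    trace: list[float] = []
    converged = False
    n_iter = 0
    prev = -np.inf
    for n_iter in range(1, options.max_iter + 1):
        ll, estep = cal.e_step(params)
        slack = 1e-6 * (1.0 + abs(ll))
        if trace and ll < trace[-1] - slack:
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {n_iter}: "
                f"{trace[-1]:.6f} -> {ll:.6f}"
            )
        trace.append(ll)
        if n_iter > 1 and abs(ll - prev) < options.tol * abs(prev):
            converged = True
            break
        prev = ll
        params = cal.m_step(params, estep)
    else:
        ll, _ = cal.e_step(params)
        trace.append(ll)
    if not converged:
        warnings.warn(
            f"{model} calibration did not converge within "
            f"{options.max_iter} EM iterations",
            RuntimeWarning,
            stacklevel=3,
        )

    params = _reflect_signs(params, cal.specs)
    rows = []
    for spec in cal.specs:
        p = params[spec.item_id]
        l0, lg = standardized_loadings(p)
        rows.append(
            {
                "item_id": spec.item_id,
                "subdomain": spec.subdomain,
                "a0": p.a0,
                "ag": p.ag,
                "lambda0": l0,
                "lambdag": lg,
            }
        )
    loadings = pd.DataFrame(rows).set_index("item_id")
    return CalibrationResult(
        bank=cal.bank.with_params(params),
        model=model,
        loglik=trace[-1],
        n_iterations=n_iter,
        converged=converged,
        loglik_trace=trace,
        n_group_slopes=sum(cal.free_ag.values()),
        data_fingerprint=cal.fingerprint,
        loadings=loadings,
        collapsed_categories=cal.collapsed,
    )


def fit_bifactor(
    responses: ResponseMatrix,
    bank: Bank,
    options: EstimationOptions | None = None,
) -> CalibrationResult:
    """Calibrate the bank under the bifactor graded-response model.

    Group slopes are freed only where identifiable (at least two items in
    the subdomain and at least two subdomains in the bank); otherwise they
    are pinned at zero.
    """
    return _fit(responses, bank, options or EstimationOptions(), "bifactor")


def fit_unidimensional(
    responses: ResponseMatrix,
    bank: Bank,
    options: EstimationOptions | None = None,
) -> CalibrationResult:
    """Calibrate with every group slope fixed at zero (nested null model)."""
    return _fit(responses, bank, options or EstimationOptions(), "unidimensional")


def marginal_loglik(
    responses: ResponseMatrix,
    bank: Bank,
    quadrature_points: int = 21,
    model: str = "bifactor",
) -> float:
    """Marginal log-likelihood of calibrated parameters on a data set."""
    if not bank.is_calibrated:
        raise ValueError("bank must carry parameters")
    opts = EstimationOptions(quadrature_points=quadrature_points)
    cal = _Calibrator(responses, bank, opts, model)
    params = {i: bank.params[i] for i in cal.item_ids}
    ll, _ = cal.e_step(params)
    return ll


def lr_test(full: CalibrationResult, reduced: CalibrationResult) -> LrTestResult:
    """Likelihood-ratio test of nested calibrations on the same data.

    Degrees of freedom equal the number of group slopes freed in the full
    model but fixed in the reduced one (one per item for bifactor vs
    unidimensional).
    """
    from scipy.stats import chi2 as chi2_dist

    if full.data_fingerprint != reduced.data_fingerprint:
        raise ValueError("calibrations were fitted to different data")
    df = full.n_group_slopes - reduced.n_group_slopes
    if df < 0:
        raise ValueError("'full' model has fewer free group slopes than 'reduced'")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < 0:
        if chi2 < -1e-6 * (1 + abs(full.loglik)):
            warnings.warn(
                f"reduced model fit better than full (chi2 = {chi2:.3g}); "
                "check convergence",
                RuntimeWarning,
                stacklevel=2,
            )
        chi2 = 0.0
    if df == 0:
        p = 1.0 if chi2 <= 1e-8 else 0.0
    else:
        p = float(chi2_dist.sf(chi2, df))
    return LrTestResult(float(chi2), int(df), p)


class EmptyBankError(ValueError):
    """Raised when a filter removes every item."""


def filter_items(
    calib: CalibrationResult, min_loading: float = 0.3
) -> tuple[Bank, pd.DataFrame]:
    """Drop items whose primary standardized loading falls below a cut.

    Returns the retained (still calibrated) bank and a report of the
    removed items with their loadings.
    """
    lam = calib.loadings["lambda0"]
    removed = lam.index[lam < min_loading].tolist()
    retained = lam.index[lam >= min_loading].tolist()
    if not retained:
        raise EmptyBankError(
            f"loading cut {min_loading} removes all {len(lam)} items"
        )
    report = calib.loadings.loc[removed, ["subdomain", "lambda0", "lambdag"]].copy()
    report["min_loading"] = min_loading
    return calib.bank.subset(retained), report


# ---------------------------------------------------------------------------
# Scoring: EAP on the primary dimension with group factors marginalized
# ---------------------------------------------------------------------------


class PosteriorTracker:
    """Incrementally accumulated posterior of the primary trait.

    Keeps one (theta0-grid x thetag-grid) log-likelihood accumulator per
    subdomain so adaptive testing can re-score in O(grid) per response.
    The theta0 grid is a uniform trapezoid grid (spectrally accurate for
    these smooth, normally-damped integrands); the group factors use
    Gauss-Hermite quadrature.
    """

    def __init__(
        self,
        bank: Bank,
        n_points: int = 321,
        theta_range: tuple[float, float] = (-8.0, 8.0),
        inner_points: int = 21,
        marginalize_groups: bool = True,
    ) -> None:
        if not bank.is_calibrated:
            raise ValueError("bank must carry parameters for scoring")
        self.bank = bank
        self.t0 = np.linspace(theta_range[0], theta_range[1], n_points)
        self.logw0 = -0.5 * self.t0**2  # prior kernel; normalization cancels
        if marginalize_groups:
            self.tg, wg = gauss_hermite(inner_points)
            self.logwg = np.log(wg)
        else:
            self.tg, self.logwg = np.zeros(1), np.zeros(1)
        self._acc: dict[str, np.ndarray] = {}
        self.answered: dict[str, int] = {}

    def add_response(self, item_id: str, code: int) -> None:
        spec = self.bank.item(item_id)
        if not 0 <= code < spec.n_categories:
            raise ValueError(
                f"item {item_id!r}: code {code} out of range "
                f"(0..{spec.n_categories - 1})"
            )
        p = self.bank.params[item_id]
        probs = category_probs(
            p.a0, p.ag, p.thresholds, self.t0[:, None], self.tg[None, :]
        )[..., code]
        acc = self._acc.setdefault(
            spec.subdomain, np.zeros((self.t0.size, self.tg.size))
        )
        acc += np.log(np.clip(probs, _PROB_FLOOR, None))
        self.answered[item_id] = code

    def log_posterior(self) -> np.ndarray:
        lp = self.logw0.copy()
        for acc in self._acc.values():
            lp += logsumexp(acc + self.logwg[None, :], axis=1)
        return lp

    def state(self) -> LatentState:
        lp = self.log_posterior()
        w = np.exp(lp - lp.max())
        w /= w.sum()
        mean = float(np.sum(w * self.t0))
        var = float(np.sum(w * (self.t0 - mean) ** 2))
        return LatentState(theta=mean, se=float(np.sqrt(max(var, 1e-12))))


def eap_score(
    responses: Mapping[str, int],
    bank: Bank,
    n_points: int = 321,
    theta_range: tuple[float, float] = (-8.0, 8.0),
    inner_points: int = 21,
    marginalize_groups: bool = True,
) -> LatentState:
    """EAP estimate (and posterior SD) of the primary trait.

    ``responses`` maps answered item ids to ordinal codes. With no
    responses the standard-normal prior is returned: theta 0, SD 1.
    """
    tracker = PosteriorTracker(
        bank,
        n_points=n_points,
        theta_range=theta_range,
        inner_points=inner_points,
        marginalize_groups=marginalize_groups,
    )
    for item_id, code in responses.items():
        tracker.add_response(item_id, code)
    return tracker.state()


# ---------------------------------------------------------------------------
# Item information
# ---------------------------------------------------------------------------


def _graded_info_terms(
    a0: np.ndarray,
    ag: np.ndarray,
    thr: np.ndarray,
    theta: np.ndarray,
    tg: np.ndarray,
    wg: np.ndarray,
) -> np.ndarray:
    """Fisher information about theta0 for stacked items of equal K.

    Shapes: a0/ag (J,), thr (J, K-1), theta (T,). Returns (J, T).
    Group factors are integrated out at their prior, i.e. the information
    of the marginal category-response curves.
    """
    # z: (J, T, Qg, K-1)
    z = (
        a0[:, None, None, None] * theta[None, :, None, None]
        + ag[:, None, None, None] * tg[None, None, :, None]
        - thr[:, None, None, :]
    )
    s = expit(z)
    sp = s * (1.0 - s)
    w = wg[None, None, :, None]
    s_bar = np.sum(s * w, axis=2)  # (J, T, K-1)
    sp_bar = np.sum(sp * w, axis=2)
    j, t = s_bar.shape[0], s_bar.shape[1]
    upper = np.concatenate([np.ones((j, t, 1)), s_bar], axis=2)
    lower = np.concatenate([s_bar, np.zeros((j, t, 1))], axis=2)
    p_bar = np.clip(upper - lower, _PROB_FLOOR, None)  # (J, T, K)
    dsp = np.concatenate([np.zeros((j, t, 1)), sp_bar], axis=2) - np.concatenate(
        [sp_bar, np.zeros((j, t, 1))], axis=2
    )
    dp = a0[:, None, None] * dsp  # (J, T, K)
    return np.sum(dp**2 / p_bar, axis=2)


def item_information(
    params: ItemParams,
    theta: float | np.ndarray,
    inner_points: int = 21,
    mode: str = "marginal",
) -> float | np.ndarray:
    """Fisher information about the primary trait contributed by one item.

    ``mode='marginal'`` integrates the group factor over its prior (the
    adaptive-testing default, since only the primary dimension is scored);
    ``mode='conditional'`` evaluates at the group factor's prior mean.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    if mode == "marginal":
        tg, wg = gauss_hermite(inner_points)
    elif mode == "conditional":
        tg, wg = np.zeros(1), np.ones(1)
    else:
        raise ValueError(f"unknown information mode {mode!r}")
    info = _graded_info_terms(
        np.array([params.a0]),
        np.array([params.ag]),
        np.asarray(params.thresholds)[None, :],
        th,
        tg,
        wg,
    )[0]
    if np.isscalar(theta) or np.asarray(theta).ndim == 0:
        return float(info[0])
    return info


def bank_information(
    bank: Bank,
    theta: float,
    item_ids: Sequence[str] | None = None,
    inner_points: int = 21,
    mode: str = "marginal",
) -> pd.Series:
    """Information of every (or selected) bank item at one trait value.

    Vectorized across items; identical numbers to calling
    :func:`item_information` per item.
    """
    ids = list(item_ids) if item_ids is not None else bank.item_ids
    if mode == "marginal":
        tg, wg = gauss_hermite(inner_points)
    elif mode == "conditional":
        tg, wg = np.zeros(1), np.ones(1)
    else:
        raise ValueError(f"unknown information mode {mode!r}")
    th = np.array([float(theta)])
    out = np.empty(len(ids))
    by_k: dict[int, list[int]] = {}
    for pos, iid in enumerate(ids):
        by_k.setdefault(bank.item(iid).n_categories, []).append(pos)
    for k, positions in by_k.items():
        a0 = np.array([bank.params[ids[p]].a0 for p in positions])
        ag = np.array([bank.params[ids[p]].ag for p in positions])
        thr = np.array([bank.params[ids[p]].thresholds for p in positions])
        out[positions] = _graded_info_terms(a0, ag, thr, th, tg, wg)[:, 0]
    return pd.Series(out, index=ids, name="information")
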