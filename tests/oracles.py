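"""Independent brute-force oracles used to cross-check the package.

Everything here deliberately avoids the package's own quadrature /
selection / ranking code paths: dense trapezoid grids instead of
Gauss-Hermite, explicit loops instead of vectorized scans, pair counting
instead of rank formulas.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from catcad.bank import MISSING, Bank, ResponseMatrix


def _item_prob(params, code: int, th0: np.ndarray, thg: np.ndarray) -> np.ndarray:
    """P(Y = code) for one graded item on broadcast latent grids."""
    c = np.asarray(params.thresholds)
    z = params.a0 * th0 + params.ag * thg
    upper = expit(z - c[code - 1]) if code >= 1 else np.ones_like(z)
    lower = expit(z - c[code]) if code < c.size else np.zeros_like(z)
    return upper - lower


def _norm_pdf(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)


def dense_person_likelihood(
    answers: dict[str, int],
    bank: Bank,
    grid: np.ndarray,
) -> np.ndarray:
    """Unnormalized marginal posterior over theta0 by dense integration.

    Integrates every group factor over a dense grid (trapezoid), one
    subdomain at a time. Returns f(theta0) such that the marginal person
    likelihood is trapz(f * phi(theta0), theta0-grid).
    """
    by_sub: dict[str, list[str]] = {}
    for iid in answers:
        by_sub.setdefault(bank.item(iid).subdomain, []).append(iid)
    f = np.ones_like(grid)
    for sub, iids in by_sub.items():
        inner = np.ones((grid.size, grid.size))  # (theta0, thetag)
        for iid in iids:
            inner *= _item_prob(
                bank.params[iid], answers[iid], grid[:, None], grid[None, :]
            )
        f *= np.trapezoid(inner * _norm_pdf(grid)[None, :], grid, axis=1)
    return f


def dense_marginal_loglik(
    responses: ResponseMatrix, bank: Bank, n_grid: int = 801, span: float = 8.0
) -> float:
    """Brute-force marginal log-likelihood over all persons."""
    grid = np.linspace(-span, span, n_grid)
    total = 0.0
    cache: dict[tuple, float] = {}  # identical response patterns share work
    for i in range(responses.n_persons):
        key = tuple(responses.codes[i].tolist())
        if key not in cache:
            answers = {
                iid: int(c)
                for iid, c in zip(responses.item_ids, responses.codes[i])
                if c != MISSING
            }
            f = dense_person_likelihood(answers, bank, grid)
            cache[key] = float(np.log(np.trapezoid(f * _norm_pdf(grid), grid)))
        total += cache[key]
    return float(total)


def dense_eap(
    answers: dict[str, int], bank: Bank, n_grid: int = 2001, span: float = 9.0
) -> tuple[float, float]:
    """Posterior mean and SD of theta0 by dense-grid integration."""
    grid = np.linspace(-span, span, n_grid)
    post = dense_person_likelihood(answers, bank, grid) * _norm_pdf(grid)
    z = np.trapezoid(post, grid)
    mean = np.trapezoid(post * grid, grid) / z
    var = np.trapezoid(post * (grid - mean) ** 2, grid) / z
    return float(mean), float(np.sqrt(var))


def pairwise_auc(scores, labels) -> float:
    """AUC as the exhaustive concordant-pair proportion (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


def exhaustive_best_item(bank: Bank, theta: float, remaining: list[str], mode: str):
    """Argmax of per-item information by a plain loop over the bank."""
    from catcad.bifactor import item_information

    best_id, best_info = None, -np.inf
    for iid in remaining:  # first-in-order wins ties, ids sorted = id order
        info = item_information(bank.params[iid], theta, mode=mode)
        if info > best_info:
            best_id, best_info = iid, info
    return best_id
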