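"""Seeded generators for item banks, ordinal responses and diagnosis labels.

The default geometry mirrors the assessment setting the toolkit targets: a
211-item bank spread over 5 subdomains (5 / 58 / 79 / 18 / 51 items), 4- or
5-category responses, roughly 700 respondents, and a binary criterion
diagnosis with ~28% prevalence driven by the primary trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from catcad.bank import MISSING, Bank, ItemParams, ItemSpec, ResponseMatrix
from catcad.bifactor import category_probs, gauss_hermite

DEFAULT_SUBDOMAIN_SIZES: dict[str, int] = {
    "exposure": 5,
    "mood_cognition": 58,
    "arousal_reactivity": 79,
    "avoidance": 18,
    "intrusion": 51,
}


@dataclass
class SyntheticTruth:
    """Generating parameters, latent traits and labels behind a data set."""

    bank: Bank
    lambda0: np.ndarray  # true primary loadings, bank order
    lambdag: np.ndarray  # true group loadings, bank order
    poor_items: list[str]  # ids planted with near-zero primary loading
    seed: int
    theta: np.ndarray | None = None  # (n_persons, 1 + n_subdomains)
    labels: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    @property
    def subdomain_order(self) -> list[str]:
        return self.bank.used_subdomains()


def gen_bank(
    n_items: int = 211,
    subdomain_sizes: Mapping[str, int] | None = None,
    category_mix: tuple[float, float] = (0.5, 0.5),
    loading_range: tuple[float, float] = (0.45, 0.90),
    group_loading_range: tuple[float, float] = (0.15, 0.45),
    n_poor_items: int = 0,
    poor_loading_range: tuple[float, float] = (0.02, 0.12),
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a calibrated bank with known (true) parameters.

    ``category_mix`` gives the probabilities of an item having 4 or 5
    response categories.  ``n_poor_items`` items are planted with primary
    loadings inside ``poor_loading_range`` (<= 0.15 by default), the rest
    draw from ``loading_range``.  Thresholds are ordered draws scaled to
    the item's slope metric so that item difficulty spans the trait range.
    """
    sizes = dict(subdomain_sizes or DEFAULT_SUBDOMAIN_SIZES)
    if sum(sizes.values()) != n_items:
        raise ValueError(
            f"subdomain sizes sum to {sum(sizes.values())}, expected {n_items}"
        )
    if not 0 <= n_poor_items <= n_items:
        raise ValueError("n_poor_items out of range")
    if abs(sum(category_mix) - 1.0) > 1e-9:
        raise ValueError("category_mix must sum to 1")
    rng = np.random.default_rng(seed)

    subdomains = list(sizes)
    item_subdomain = [g for g in subdomains for _ in range(sizes[g])]
    poor_idx = set(
        rng.choice(n_items, size=n_poor_items, replace=False).tolist()
    )

    items: list[ItemSpec] = []
    params: dict[str, ItemParams] = {}
    lambda0 = np.empty(n_items)
    lambdag = np.empty(n_items)
    poor_ids: list[str] = []
    for j in range(n_items):
        iid = f"item{j + 1:03d}"
        if j in poor_idx:
            l0 = rng.uniform(*poor_loading_range)
            poor_ids.append(iid)
        else:
            l0 = rng.uniform(*loading_range)
        lg = rng.uniform(*group_loading_range)
        # keep communality away from 1 so slopes stay finite
        cap = 0.95 - l0**2
        lg = min(lg, float(np.sqrt(max(cap, 0.01))))
        uniq = 1.0 - l0**2 - lg**2
        a0 = l0 / np.sqrt(uniq)
        ag = lg / np.sqrt(uniq)
        k = 4 if rng.random() < category_mix[0] else 5
        # thresholds on the linear-predictor scale: centered draws whose
        # spread tracks the item's slope metric
        scale = np.sqrt(1.0 + a0**2 + ag**2)
        center = rng.normal(0.0, 0.7)
        gaps = rng.uniform(0.35, 0.75, size=k - 2)
        tau = center + np.concatenate([[0.0], np.cumsum(gaps)])
        tau -= tau.mean()
        c = tuple(scale * tau)
        items.append(ItemSpec(iid, item_subdomain[j], k))
        params[iid] = ItemParams(float(a0), float(ag), c)
        lambda0[j] = l0
        lambdag[j] = lg

    bank = Bank(items=items, params=params, subdomains=tuple(subdomains))
    return SyntheticTruth(
        bank=bank,
        lambda0=lambda0,
        lambdag=lambdag,
        poor_items=poor_ids,
        seed=seed,
        config={
            "n_items": n_items,
            "subdomain_sizes": sizes,
            "category_mix": list(category_mix),
            "loading_range": list(loading_range),
            "group_loading_range": list(group_loading_range),
            "n_poor_items": n_poor_items,
            "poor_loading_range": list(poor_loading_range),
        },
    )


def gen_responses(
    truth: SyntheticTruth,
    n_persons: int = 713,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> ResponseMatrix:
    """Draw ordinal responses from the generating bifactor model.

    Latent vectors (primary + one factor per subdomain) are independent
    standard normal draws; they are stored on ``truth.theta`` for recovery
    tests.  ``missing_rate`` blanks cells completely at random.
    """
    rng = np.random.default_rng(seed)
    bank = truth.bank
    subdomains = bank.used_subdomains()
    g_index = {g: i + 1 for i, g in enumerate(subdomains)}
    theta = rng.standard_normal((n_persons, 1 + len(subdomains)))
    codes = np.empty((n_persons, len(bank)), dtype=np.int16)
    u = rng.random((n_persons, len(bank)))
    for j, spec in enumerate(bank.items):
        p = bank.params[spec.item_id]
        th0 = theta[:, 0]
        thg = theta[:, g_index[spec.subdomain]]
        probs = category_probs(p.a0, p.ag, p.thresholds, th0, thg)
        cum = np.cumsum(probs, axis=1)
        codes[:, j] = np.minimum(
            (u[:, j : j + 1] > cum).sum(axis=1), spec.n_categories - 1
        )
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        # never blank an entire row
        full_rows = mask.all(axis=1)
        mask[full_rows, 0] = False
        codes = np.where(mask, MISSING, codes)
    truth.theta = theta
    person_ids = [f"p{i + 1:04d}" for i in range(n_persons)]
    return ResponseMatrix(codes, person_ids, bank.item_ids)


def solve_intercept(prevalence: float, beta: float, n_quad: int = 61) -> float:
    """Intercept alpha with E[expit(alpha + beta*theta)] = prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    t, w = gauss_hermite(n_quad)

    def expected(alpha: float) -> float:
        return float(np.sum(w * expit(alpha + beta * t))) - prevalence

    return brentq(expected, -50.0, 50.0)


def gen_diagnosis(
    truth: SyntheticTruth,
    prevalence_target: float = 0.284,
    signal_strength: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Bernoulli labels from a logistic model on the primary trait.

    The intercept is solved so the population prevalence equals the target;
    ``signal_strength`` is the logistic slope on theta0 (0 = null signal).
    """
    if truth.theta is None:
        raise ValueError("generate responses first (truth.theta is unset)")
    rng = np.random.default_rng(seed)
    alpha = solve_intercept(prevalence_target, signal_strength)
    p = expit(alpha + signal_strength * truth.theta[:, 0])
    labels = (rng.random(p.size) < p).astype(np.int8)
    truth.labels = labels
    truth.config.update(
        {
            "prevalence_target": prevalence_target,
            "signal_strength": signal_strength,
            "diagnosis_intercept": alpha,
        }
    )
    return labels
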