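"""Adaptive test administration: item selection, stopping, scoring, tuning.

A session administers the currently most informative item (optionally the
runner-up, for variety), re-scores the examinee by EAP after every
response, and stops once the posterior uncertainty on the 0-100 reporting
scale falls below a precision threshold — or when the bank runs out of
information, the item budget is hit, or the bank is exhausted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from catcad.bank import MISSING, Bank, ResponseMatrix
from catcad.bifactor import LatentState, PosteriorTracker, bank_information

logger = logging.getLogger(__name__)

STOP_PRECISION = "precision"
STOP_REMAINING_INFO = "remaining_info"
STOP_MAX_ITEMS = "max_items"
STOP_BANK_EXHAUSTED = "bank_exhausted"

SEVERITY_LABELS = ("none", "mild", "moderate", "severe")


class BankExhaustedError(RuntimeError):
    """No unadministered item is left to select."""


@dataclass(frozen=True)
class CatConfig:
    """Tuning parameters of the adaptive loop.

    ``se_stop`` is on the 0-100 reporting scale. ``remaining_info_stop``
    stops the test when no remaining item would contribute at least that
    much Fisher information at the current severity estimate.
    ``top2_prob`` is the chance of administering the second most
    informative item instead of the most informative one.
    """

    se_stop: float = 5.0
    min_items: int = 4
    max_items: int = 30
    remaining_info_stop: float = 0.1
    top2_prob: float = 0.0
    start_rule: str = "max_info_at_prior"
    seed: int = 0
    info_mode: str = "marginal"

    def __post_init__(self) -> None:
        if self.se_stop <= 0:
            raise ValueError("se_stop must be > 0")
        if not 1 <= self.min_items <= self.max_items:
            raise ValueError("need 1 <= min_items <= max_items")
        if not 0.0 <= self.top2_prob <= 1.0:
            raise ValueError("top2_prob must be in [0, 1]")
        if self.remaining_info_stop < 0:
            raise ValueError("remaining_info_stop must be >= 0")


@dataclass(frozen=True)
class ScoreTransform:
    """Affine map from the latent scale to a clipped 0-100 severity score."""

    center: float = 50.0
    scale: float = 15.0
    lower: float = 0.0
    upper: float = 100.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")

    def score(self, theta: float) -> float:
        return float(np.clip(self.center + self.scale * theta, self.lower, self.upper))

    def uncertainty(self, se: float) -> float:
        return float(self.scale * se)


@dataclass(frozen=True)
class SeverityThresholds:
    """Three ascending cut scores mapping a 0-100 score to severity bands."""

    t1: float = 35.0
    t2: float = 47.0
    t3: float = 60.0

    def __post_init__(self) -> None:
        cuts = (self.t1, self.t2, self.t3)
        if not all(0.0 <= c <= 100.0 for c in cuts):
            raise ValueError(f"thresholds must lie in [0, 100], got {cuts}")
        if not self.t1 < self.t2 < self.t3:
            raise ValueError(f"thresholds must be strictly ascending, got {cuts}")


def classify_severity(
    score: float, thresholds: SeverityThresholds | None = None
) -> str:
    """Map a 0-100 score to none/mild/moderate/severe (lower-inclusive cuts)."""
    thr = thresholds or SeverityThresholds()
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"score must lie in [0, 100], got {score}")
    if score < thr.t1:
        return SEVERITY_LABELS[0]
    if score < thr.t2:
        return SEVERITY_LABELS[1]
    if score < thr.t3:
        return SEVERITY_LABELS[2]
    return SEVERITY_LABELS[3]


@dataclass
class CatSession:
    """State of one adaptive administration."""

    bank: Bank
    config: CatConfig
    transform: ScoreTransform
    administered: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    trajectory: list[tuple[float, float]] = field(default_factory=list)
    state: LatentState = field(default_factory=lambda: LatentState(0.0, 1.0))
    stop_reason: str | None = None
    pending_item: str | None = None
    unavailable: set[str] = field(default_factory=set)
    _tracker: PosteriorTracker | None = None
    _rng: np.random.Generator | None = None

    @property
    def n_administered(self) -> int:
        return len(self.administered)

    @property
    def score(self) -> float:
        return self.transform.score(self.state.theta)

    @property
    def uncertainty(self) -> float:
        return self.transform.uncertainty(self.state.se)

    def selectable_items(self) -> list[str]:
        taken = set(self.administered) | self.unavailable
        if self.pending_item is not None:
            taken.add(self.pending_item)
        return [i for i in self.bank.item_ids if i not in taken]


def next_item(
    state: LatentState,
    bank: Bank,
    already_administered: Iterable[str],
    config: CatConfig,
    rng: np.random.Generator | None = None,
) -> str:
    """Pick the (or, with probability ``top2_prob``, second) most
    informative unadministered item at the current trait estimate.

    Ties are broken by item id order.
    """
    taken = set(already_administered)
    remaining = [i for i in bank.item_ids if i not in taken]
    if not remaining:
        raise BankExhaustedError("no unadministered items remain")
    info = bank_information(bank, state.theta, remaining, mode=config.info_mode)
    ranked = sorted(remaining, key=lambda i: (-info[i], i))
    if len(ranked) >= 2 and config.top2_prob > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        if rng.random() < config.top2_prob:
            return ranked[1]
    return ranked[0]


def start_session(
    bank: Bank,
    config: CatConfig | None = None,
    transform: ScoreTransform | None = None,
    rng: np.random.Generator | None = None,
    unavailable: Iterable[str] = (),
) -> CatSession:
    """Open a session and select the first item at the prior mean."""
    config = config or CatConfig()
    transform = transform or ScoreTransform()
    if len(bank) == 0:
        raise ValueError("cannot start a session on an empty bank")
    if not bank.is_calibrated:
        raise ValueError("bank must be calibrated before adaptive administration")
    session = CatSession(
        bank=bank,
        config=config,
        transform=transform,
        unavailable=set(unavailable),
        _tracker=PosteriorTracker(
            bank, marginalize_groups=config.info_mode == "marginal"
        ),
        _rng=rng if rng is not None else np.random.default_rng(config.seed),
    )
    if not session.selectable_items():
        raise ValueError("no selectable items in bank")
    session.pending_item = next_item(
        session.state,
        bank,
        session.administered + list(session.unavailable),
        config,
        session._rng,
    )
    return session


def update_session(session: CatSession, response: int) -> CatSession:
    """Record the response to the pending item and re-score by EAP."""
    if session.pending_item is None:
        raise RuntimeError("no pending item; select one with next_item first")
    item_id = session.pending_item
    session._tracker.add_response(item_id, int(response))  # validates the code
    session.administered.append(item_id)
    session.responses.append(int(response))
    session.pending_item = None
    session.state = session._tracker.state()
    session.trajectory.append((session.score, session.uncertainty))
    return session


def should_stop(
    session: CatSession, bank: Bank | None = None, config: CatConfig | None = None
) -> tuple[bool, str | None]:
    """Evaluate the stopping rules in order: exhaustion, budget, precision,
    remaining information. Precision and remaining-information rules are
    only consulted once ``min_items`` items have been administered."""
    bank = bank or session.bank
    config = config or session.config
    n = session.n_administered
    if not session.selectable_items():
        return True, STOP_BANK_EXHAUSTED
    if n >= min(config.max_items, len(bank)):
        return True, STOP_MAX_ITEMS
    if n < config.min_items:
        return False, None
    if session.uncertainty <= config.se_stop:
        return True, STOP_PRECISION
    info = bank_information(
        bank, session.state.theta, session.selectable_items(), mode=config.info_mode
    )
    if float(info.max()) < config.remaining_info_stop:
        return True, STOP_REMAINING_INFO
    return False, None


def run_cat(
    bank: Bank,
    responder: Callable[[str], int],
    config: CatConfig | None = None,
    transform: ScoreTransform | None = None,
    rng: np.random.Generator | None = None,
    unavailable: Iterable[str] = (),
) -> CatSession:
    """Drive a full session, querying ``responder`` for each selected item."""
    session = start_session(bank, config, transform, rng, unavailable)
    while True:
        session = update_session(session, responder(session.pending_item))
        stop, reason = should_stop(session)
        if stop:
            session.stop_reason = reason
            return session
        session.pending_item = next_item(
            session.state,
            bank,
            session.administered + list(session.unavailable),
            session.config,
            session._rng,
        )


def full_bank_score(
    row: np.ndarray, bank: Bank, transform: ScoreTransform, item_ids: Sequence[str]
) -> float:
    """Transformed EAP score from a person's complete response pattern."""
    tracker = PosteriorTracker(bank)
    for iid, code in zip(item_ids, row):
        if code != MISSING:
            tracker.add_response(iid, int(code))
    return transform.score(tracker.state().theta)


def run_simulated_cat(
    full_responses: ResponseMatrix,
    bank: Bank,
    config: CatConfig | None = None,
    transform: ScoreTransform | None = None,
    on_missing: str = "skip",
) -> tuple[list[CatSession], dict]:
    """Replay adaptive sessions from stored complete response patterns.

    Each simulee's responses are read from their row as items are
    adaptively selected. Items a simulee never answered are either removed
    from their selectable pool (``on_missing='skip'``) or the simulee is
    dropped (``'drop'``). The summary reports the item-count distribution
    and the Pearson correlation of final CAT scores with full-bank EAP
    scores.
    """
    if on_missing not in ("skip", "drop"):
        raise ValueError("on_missing must be 'skip' or 'drop'")
    config = config or CatConfig()
    transform = transform or ScoreTransform()
    full_responses.validate_against(bank)
    col = {iid: j for j, iid in enumerate(full_responses.item_ids)}
    missing_cols = [i for i in bank.item_ids if i not in col]
    if missing_cols:
        raise ValueError(f"responses lack columns for bank items: {missing_cols[:5]}")

    sessions: list[CatSession] = []
    cat_scores: list[float] = []
    full_scores: list[float] = []
    n_dropped = 0
    for i in range(full_responses.n_persons):
        row = full_responses.codes[i]
        unavailable = [iid for iid in bank.item_ids if row[col[iid]] == MISSING]
        if unavailable and on_missing == "drop":
            n_dropped += 1
            logger.info(
                "dropping simulee %s: %d missing items",
                full_responses.person_ids[i],
                len(unavailable),
            )
            continue
        rng = np.random.default_rng([config.seed, i])
        session = run_cat(
            bank,
            lambda iid: int(row[col[iid]]),
            config,
            transform,
            rng,
            unavailable,
        )
        sessions.append(session)
        cat_scores.append(session.score)
        full_scores.append(full_bank_score(row, bank, transform, bank.item_ids))

    n_items = np.array([s.n_administered for s in sessions])
    cat_arr, full_arr = np.array(cat_scores), np.array(full_scores)
    if len(sessions) >= 2 and cat_arr.std() > 0 and full_arr.std() > 0:
        r = float(np.corrcoef(cat_arr, full_arr)[0, 1])
    else:
        r = float("nan")
    reasons = pd.Series([s.stop_reason for s in sessions]).value_counts().to_dict()
    summary = {
        "n_sessions": len(sessions),
        "n_dropped": n_dropped,
        "mean_items": float(n_items.mean()) if len(sessions) else float("nan"),
        "min_items": int(n_items.min()) if len(sessions) else 0,
        "max_items": int(n_items.max()) if len(sessions) else 0,
        "correlation_with_full_bank": r,
        "stop_reasons": reasons,
    }
    return sessions, summary


# ---------------------------------------------------------------------------
# Tuning
# ---------------------------------------------------------------------------

FACTORY_GRID_AXES: dict[str, tuple] = {
    "se_stop": (3.0, 4.0, 5.0, 6.0, 7.0, 8.0),
    "remaining_info_stop": (0.0, 0.05, 0.1, 0.2, 0.5),
    "top2_prob": (0.0, 0.25, 0.5, 0.75, 1.0),
    "max_items": (6, 8, 10, 12, 14, 17, 20, 25),
}


def default_tuning_grid(base: CatConfig | None = None) -> list[CatConfig]:
    """Factory grid: full cross of the four tuning axes (1200 configs)."""
    base = base or CatConfig()
    grid = []
    for se, ri, tp, mx in itertools.product(*FACTORY_GRID_AXES.values()):
        grid.append(
            replace(
                base,
                se_stop=se,
                remaining_info_stop=ri,
                top2_prob=tp,
                max_items=mx,
                min_items=min(base.min_items, mx),
            )
        )
    return grid


@dataclass
class TuneResult:
    best: CatConfig
    frontier: pd.DataFrame


def tune(
    full_responses: ResponseMatrix,
    bank: Bank,
    grid: Sequence[CatConfig],
    transform: ScoreTransform | None = None,
    correlation_tolerance: float = 0.005,
    evaluate: Callable[[ResponseMatrix, Bank, CatConfig, ScoreTransform | None], dict]
    | None = None,
) -> TuneResult:
    """Evaluate every grid point by simulated CAT and pick the shortest
    test among those within ``correlation_tolerance`` of the best
    correlation with the full-bank score.

    ``evaluate`` overrides the per-config evaluation (mainly for tests);
    it must return a summary dict with ``mean_items`` and
    ``correlation_with_full_bank``.
    """
    if not grid:
        raise ValueError("tuning grid is empty")
    if evaluate is None:
        def evaluate(resp, bk, cfg, tr):
            return run_simulated_cat(resp, bk, cfg, tr)[1]
    rows = []
    for idx, cfg in enumerate(grid):
        summary = evaluate(full_responses, bank, cfg, transform)
        rows.append(
            {
                "grid_index": idx,
                "se_stop": cfg.se_stop,
                "remaining_info_stop": cfg.remaining_info_stop,
                "top2_prob": cfg.top2_prob,
                "max_items": cfg.max_items,
                "mean_items": summary["mean_items"],
                "correlation": summary["correlation_with_full_bank"],
            }
        )
    frontier = pd.DataFrame(rows)
    best_r = frontier["correlation"].max()
    ok = frontier[frontier["correlation"] >= best_r - correlation_tolerance]
    best_idx = int(ok.sort_values(["mean_items", "grid_index"]).iloc[0]["grid_index"])
    return TuneResult(best=grid[best_idx], frontier=frontier)
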