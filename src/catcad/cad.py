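"""Adaptive diagnostic screening with constrained extremely randomized trees.

Each screening form is a small ensemble (default 2 trees of depth <= 3)
grown by the extra-trees rule: at every node a random subset of items is
drawn, each with one uniformly random cutpoint, and the split with the
best Gini impurity decrease is kept. Because a root-to-leaf path in one
tree touches at most ``depth`` items, a session never presents more than
``n_trees * depth`` distinct items; an item shared between trees is asked
once and its response imputed on re-use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from catcad.bank import MISSING, ResponseMatrix


@dataclass(frozen=True)
class CadConfig:
    """Training-time knobs for the screener ensembles."""

    n_trees: int = 2
    depth: int = 3
    n_forms: int = 10
    k_candidates: int | None = None  # None -> ceil(sqrt(n_items))
    min_node_size: int = 10
    combiner: str = "logistic"  # or "average"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.depth < 1 or self.n_forms < 1:
            raise ValueError("n_trees, depth and n_forms must be >= 1")
        if self.combiner not in ("logistic", "average"):
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class TreeNode:
    """Internal split (item + cutpoint) or leaf (class probability)."""

    prob: float
    n: int
    item: str | None = None
    cut: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.item is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def items_used(self) -> set[str]:
        if self.is_leaf:
            return set()
        return {self.item} | self.left.items_used() | self.right.items_used()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"prob": self.prob, "n": self.n}
        return {
            "prob": self.prob,
            "n": self.n,
            "item": self.item,
            "cut": self.cut,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "item" not in d:
            return cls(prob=d["prob"], n=d["n"])
        return cls(
            prob=d["prob"],
            n=d["n"],
            item=d["item"],
            cut=d["cut"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class CadModel:
    """One screening form: trees plus a linear output combination."""

    trees: list[TreeNode]
    weights: np.ndarray  # length n_trees; logistic coefficients or averages
    intercept: float
    combiner: str
    threshold: float
    item_range: dict[str, int]  # item id -> number of response categories
    seed: int
    degenerate: bool = False

    @property
    def max_items_per_session(self) -> int:
        return sum(max(t.depth(), 0) for t in self.trees)

    def items_used(self) -> set[str]:
        out: set[str] = set()
        for t in self.trees:
            out |= t.items_used()
        return out

    def combine(self, leaf_probs: Sequence[float]) -> float:
        p = np.asarray(leaf_probs, dtype=float)
        if self.combiner == "logistic":
            val = float(expit(self.intercept + float(np.dot(self.weights, p))))
        else:
            val = float(self.intercept + np.dot(self.weights, p))
        return float(np.clip(val, 0.0, 1.0))


@dataclass
class CadSession:
    """One adaptive screening administration."""

    items: list[str]  # distinct items, presentation order
    responses: dict[str, int]
    probability: float
    screen_positive: bool
    n_imputed: int  # tree-node visits answered from an earlier response


def _gini(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    p = y.mean()
    return 2.0 * p * (1.0 - p)


def _grow_tree(
    x: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    depth_left: int,
    config: CadConfig,
    rng: np.random.Generator,
    item_ids: Sequence[str],
) -> TreeNode:
    node_y = y[idx]
    prob = float(node_y.mean())
    leaf = TreeNode(prob=prob, n=int(idx.size))
    if depth_left == 0 or idx.size < config.min_node_size or prob in (0.0, 1.0):
        return leaf
    sub = x[idx]
    lo, hi = sub.min(axis=0), sub.max(axis=0)
    usable = np.where(hi > lo)[0]
    if usable.size == 0:
        return leaf
    k = config.k_candidates or math.ceil(math.sqrt(x.shape[1]))
    cand = rng.choice(usable, size=min(k, usable.size), replace=False)
    parent = _gini(node_y)
    best_gain, best_j, best_cut = -np.inf, None, None
    for j in cand:
        cut = rng.uniform(lo[j], hi[j])
        mask = sub[:, j] < cut
        nl = int(mask.sum())
        if nl == 0 or nl == idx.size:
            continue
        gain = parent - (
            nl * _gini(node_y[mask]) + (idx.size - nl) * _gini(node_y[~mask])
        ) / idx.size
        if gain > best_gain:
            best_gain, best_j, best_cut = gain, int(j), float(cut)
    if best_j is None or best_gain <= 0:
        return leaf
    mask = sub[:, best_j] < best_cut
    return TreeNode(
        prob=prob,
        n=int(idx.size),
        item=item_ids[best_j],
        cut=best_cut,
        left=_grow_tree(x, y, idx[mask], depth_left - 1, config, rng, item_ids),
        right=_grow_tree(x, y, idx[~mask], depth_left - 1, config, rng, item_ids),
    )


def _tree_predict(tree: TreeNode, get: Callable[[str], int]) -> float:
    node = tree
    while not node.is_leaf:
        node = node.left if get(node.item) < node.cut else node.right
    return node.prob


def _tree_predict_all(tree: TreeNode, x: np.ndarray, item_col: dict[str, int]):
    out = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        row = x[i]
        out[i] = _tree_predict(tree, lambda iid: row[item_col[iid]])
    return out


def train_cad(
    responses: ResponseMatrix,
    labels: np.ndarray,
    config: CadConfig | None = None,
    seed: int = 0,
) -> list[CadModel]:
    """Train ``n_forms`` alternative screening forms from distinct seeds.

    Ordinal codes are treated as numeric features. With constant labels a
    degenerate model returning the prevalence is produced and flagged.
    """
    config = config or CadConfig()
    y = np.asarray(labels)
    if y.shape[0] != responses.n_persons:
        raise ValueError("labels length must match number of persons")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if (responses.codes == MISSING).any():
        raise ValueError("screener training requires complete response rows")
    x = responses.codes.astype(float)
    y = y.astype(float)
    item_ids = responses.item_ids
    item_col = {iid: j for j, iid in enumerate(item_ids)}
    item_range = {
        iid: int(responses.codes[:, j].max()) + 1 for j, iid in enumerate(item_ids)
    }
    degenerate = len(np.unique(y)) < 2

    models: list[CadModel] = []
    for f in range(config.n_forms):
        rng = np.random.default_rng([seed, f])
        if degenerate:
            prev = float(y.mean())
            models.append(
                CadModel(
                    trees=[TreeNode(prob=prev, n=y.size) for _ in range(config.n_trees)],
                    weights=np.zeros(config.n_trees),
                    intercept=prev,
                    combiner="average",
                    threshold=config.threshold,
                    item_range=item_range,
                    seed=seed,
                    degenerate=True,
                )
            )
            continue
        idx = np.arange(x.shape[0])
        trees = [
            _grow_tree(x, y, idx, config.depth, config, rng, item_ids)
            for _ in range(config.n_trees)
        ]
        leaf = np.column_stack(
            [_tree_predict_all(t, x, item_col) for t in trees]
        )
        if config.combiner == "logistic" and np.ptp(leaf, axis=0).max() > 0:
            lr = LogisticRegression(C=1000.0, max_iter=2000)
            lr.fit(leaf, y.astype(int))
            weights, intercept = lr.coef_[0].copy(), float(lr.intercept_[0])
            combiner = "logistic"
        else:
            weights = np.full(config.n_trees, 1.0 / config.n_trees)
            intercept = 0.0
            combiner = "average"
        models.append(
            CadModel(
                trees=trees,
                weights=weights,
                intercept=intercept,
                combiner=combiner,
                threshold=config.threshold,
                item_range=item_range,
                seed=seed,
                degenerate=False,
            )
        )
    return models


def select_form(models: Sequence[CadModel], seed: int = 0) -> CadModel:
    """Uniform seeded choice among alternative forms."""
    if not models:
        raise ValueError("no screening forms to choose from")
    rng = np.random.default_rng(seed)
    return models[int(rng.integers(len(models)))]


def administer(model: CadModel, responder: Callable[[str], int]) -> CadSession:
    """Traverse the form's trees, querying each distinct item only once.

    A repeated item reuses the earlier answer (imputation), so at most
    ``n_trees * depth`` distinct items are ever presented.
    """
    answers: dict[str, int] = {}
    order: list[str] = []
    n_imputed = 0

    def get(item_id: str) -> int:
        nonlocal n_imputed
        if item_id in answers:
            n_imputed += 1
            return answers[item_id]
        code = int(responder(item_id))
        n_cat = model.item_range.get(item_id)
        if code < 0 or (n_cat is not None and code >= n_cat):
            raise ValueError(
                f"item {item_id!r}: response {code} out of range (0..{n_cat - 1})"
            )
        answers[item_id] = code
        order.append(item_id)
        return code

    leaf_probs = [_tree_predict(t, get) for t in model.trees]
    prob = model.combine(leaf_probs)
    return CadSession(
        items=order,
        responses=answers,
        probability=prob,
        screen_positive=prob >= model.threshold,
        n_imputed=n_imputed,
    )


def predict_proba(model: CadModel, row: Mapping[str, int]) -> float:
    """Batch prediction from a complete response row.

    Raises if the row lacks an item the traversal needs; equals
    :func:`administer` driven by the same row.
    """

    def get(item_id: str) -> int:
        if item_id not in row:
            raise ValueError(f"response row is missing required item {item_id!r}")
        return int(row[item_id])

    return model.combine([_tree_predict(t, get) for t in model.trees])


def cross_validated_probs(
    responses: ResponseMatrix,
    labels: np.ndarray,
    config: CadConfig | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold screening probabilities (one single-form model per fold).

    Returns pooled out-of-fold probabilities and the fold assignment of
    each person; feed them to :func:`catcad.evaluation.cv_auc` relatives
    or directly to an ROC routine.
    """
    from sklearn.model_selection import StratifiedKFold

    config = config or CadConfig()
    y = np.asarray(labels).astype(int)
    probs = np.empty(y.size)
    fold_of = np.empty(y.size, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(skf.split(np.zeros(y.size), y)):
        sub = ResponseMatrix(
            responses.codes[tr],
            [responses.person_ids[i] for i in tr],
            responses.item_ids,
        )
        model = train_cad(
            sub, y[tr], config=CadConfig(**{**config.__dict__, "n_forms": 1}), seed=seed + k
        )[0]
        for i in te:
            row = dict(zip(responses.item_ids, responses.codes[i]))
            probs[i] = predict_proba(model, row)
        fold_of[te] = k
    return probs, fold_of
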