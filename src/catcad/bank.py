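"""Item-bank and response-matrix domain types shared by all engines."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_SUBDOMAINS = (
    "exposure",
    "mood_cognition",
    "arousal_reactivity",
    "avoidance",
    "intrusion",
)

MISSING = -1  # internal code for a missing ordinal response


@dataclass(frozen=True)
class ItemSpec:
    """Static description of one ordinal item.

    Parameters
    ----------
    item_id:
        Unique identifier within a bank.
    subdomain:
        Group-factor label; must belong to the bank's declared subdomain set.
    n_categories:
        Number of ordinal response categories (codes ``0 .. n_categories-1``).
    stem:
        Optional free-text item stem / time-frame metadata.
    """

    item_id: str
    subdomain: str
    n_categories: int
    stem: str | None = None

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(
                f"item {self.item_id!r}: n_categories must be >= 2, "
                f"got {self.n_categories}"
            )


@dataclass(frozen=True)
class ItemParams:
    """Graded-model parameters for one item under the bifactor restriction.

    ``a0`` is the slope on the primary dimension, ``ag`` the slope on the
    item's single group factor, and ``thresholds`` the ordered category
    boundaries (length ``n_categories - 1``).
    """

    a0: float
    ag: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", thr)
        if len(thr) < 1:
            raise ValueError("at least one threshold required")
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {thr}")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass
class Bank:
    """A collection of items, optionally carrying calibrated parameters."""

    items: list[ItemSpec]
    params: dict[str, ItemParams] = field(default_factory=dict)
    subdomains: tuple[str, ...] = DEFAULT_SUBDOMAINS

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids in bank: {dup}")
        declared = set(self.subdomains)
        extra = {it.subdomain for it in self.items} - declared
        if extra:
            raise ValueError(
                f"items use subdomains outside the declared set: {sorted(extra)}"
            )
        for it in self.items:
            p = self.params.get(it.item_id)
            if p is not None and p.n_categories != it.n_categories:
                raise ValueError(
                    f"item {it.item_id!r}: {it.n_categories} categories declared "
                    f"but {p.n_categories} implied by thresholds"
                )

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def is_calibrated(self) -> bool:
        return all(it.item_id in self.params for it in self.items)

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, item_ids: Iterable[str]) -> "Bank":
        keep = set(item_ids)
        items = [it for it in self.items if it.item_id in keep]
        params = {k: v for k, v in self.params.items() if k in keep}
        return Bank(items=items, params=params, subdomains=self.subdomains)

    def with_params(self, params: Mapping[str, ItemParams]) -> "Bank":
        return Bank(
            items=list(self.items), params=dict(params), subdomains=self.subdomains
        )

    def used_subdomains(self) -> list[str]:
        seen: list[str] = []
        for it in self.items:
            if it.subdomain not in seen:
                seen.append(it.subdomain)
        return seen


class ResponseMatrix:
    """Persons x items grid of ordinal codes with optional missingness.

    Internally stored as an ``int16`` array with ``-1`` marking missing
    cells. Rows with no observed responses are rejected at construction.
    """

    def __init__(
        self,
        codes: np.ndarray,
        person_ids: Sequence[str],
        item_ids: Sequence[str],
    ) -> None:
        codes = np.asarray(codes)
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        if codes.shape != (len(person_ids), len(item_ids)):
            raise ValueError(
                f"shape {codes.shape} inconsistent with {len(person_ids)} persons "
                f"x {len(item_ids)} items"
            )
        if len(set(item_ids)) != len(item_ids):
            raise ValueError("duplicate item ids")
        if len(set(person_ids)) != len(person_ids):
            raise ValueError("duplicate person ids")
        arr = codes.astype(np.int16)
        if np.any(arr < MISSING):
            raise ValueError("response codes must be >= 0 (or -1 for missing)")
        empty = np.where((arr == MISSING).all(axis=1))[0]
        if empty.size:
            raise ValueError(
                f"persons with no observed responses: "
                f"{[person_ids[i] for i in empty[:5]]}"
            )
        self.codes = arr
        self.person_ids = list(person_ids)
        self.item_ids = list(item_ids)

    @property
    def n_persons(self) -> int:
        return self.codes.shape[0]

    @property
    def n_items(self) -> int:
        return self.codes.shape[1]

    def validate_against(self, bank: Bank) -> None:
        """Check every column exists in the bank and codes are in range."""
        spec_by_id = {it.item_id: it for it in bank.items}
        for j, iid in enumerate(self.item_ids):
            spec = spec_by_id.get(iid)
            if spec is None:
                raise ValueError(f"response column {iid!r} not in bank")
            col = self.codes[:, j]
            bad = np.where(col >= spec.n_categories)[0]
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"person {self.person_ids[i]!r}, item {iid!r}: code "
                    f"{int(col[i])} out of range for {spec.n_categories} categories"
                )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.codes.astype(float), index=self.person_ids, columns=self.item_ids
        )
        return df.where(self.codes != MISSING)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseMatrix":
        vals = df.to_numpy(dtype=float)
        codes = np.where(np.isnan(vals), MISSING, vals).astype(np.int16)
        return cls(codes, [str(i) for i in df.index], [str(c) for c in df.columns])

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.codes.tobytes())
        h.update("|".join(self.person_ids).encode())
        h.update("|".join(self.item_ids).encode())
        return h.hexdigest()[:16]


def collapse_sparse_categories(
    responses: ResponseMatrix, bank: Bank
) -> tuple[ResponseMatrix, Bank, dict[str, list[int]]]:
    """Collapse response categories never observed in the data.

    An unobserved category is merged into its lower neighbour (the lowest
    category merges upward), so the fitted model only carries thresholds
    that the data can identify. Returns the recoded matrix, a bank with
    adjusted ``n_categories``, and a log of collapsed category codes per
    item. Items with fewer than two observed categories are rejected.
    """
    codes = responses.codes.copy()
    new_items: list[ItemSpec] = []
    log: dict[str, list[int]] = {}
    spec_by_id = {it.item_id: it for it in bank.items}
    for j, iid in enumerate(responses.item_ids):
        spec = spec_by_id[iid]
        col = codes[:, j]
        observed = np.zeros(spec.n_categories, dtype=bool)
        vals = col[col != MISSING]
        observed[vals] = True
        n_obs = int(observed.sum())
        if n_obs < 2:
            raise ValueError(
                f"item {iid!r}: only {n_obs} observed categor"
                f"{'y' if n_obs == 1 else 'ies'}; cannot calibrate"
            )
        if n_obs < spec.n_categories:
            # dense re-code: observed categories keep their order
            remap = np.cumsum(observed) - 1
            codes[:, j] = np.where(col == MISSING, MISSING, remap[col])
            log[iid] = [int(k) for k in np.where(~observed)[0]]
            spec = ItemSpec(iid, spec.subdomain, n_obs, spec.stem)
        new_items.append(spec)
    out = ResponseMatrix(codes, responses.person_ids, responses.item_ids)
    kept_other = [it for it in bank.items if it.item_id not in set(responses.item_ids)]
    new_bank = Bank(
        items=new_items + kept_other, params={}, subdomains=bank.subdomains
    )
    return out, new_bank, log
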