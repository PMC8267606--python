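"""File formats: delimited text for matrices, JSON for models and summaries.

Every writer embeds a provenance block (package version, seed, config
hash) so any artifact can be traced to the run that produced it. All
formats are plain text and round-trip the in-memory representation.
"""

from __future__ import annotations

import hashlib

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

import catcad
from catcad.bank import MISSING, Bank, ItemParams, ItemSpec, ResponseMatrix
from catcad.cad import CadModel, TreeNode
from catcad.cat import CatConfig, CatSession, ScoreTransform

MAX_THRESHOLD_COLS = 4  # c_1..c_4 supports up to 5 response categories


def config_hash(obj: Any) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance(seed: int | None = None, config: Any = None) -> dict:
    return {
        "tool": "catcad",
        "version": catcad.__version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }


def write_table(df: pd.DataFrame, path: Path, prov: dict | None = None) -> None:
    with open(path, "w") as fh:
        if prov is not None:
            fh.write(f"# provenance: {json.dumps(prov, sort_keys=True)}\n")
        df.to_csv(fh, index=False)


def read_provenance(path: str | Path) -> dict | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# provenance:"):
        return json.loads(first.split(":", 1)[1])
    return None


# ---------------------------------------------------------------------------
# Bank files
# ---------------------------------------------------------------------------


def write_bank(
    bank: Bank, path: str | Path, prov: dict | None = None
) -> None:
    """CSV schema: item_id, subdomain, n_categories, a0, ag, c_1..c_4.

    Parameter cells are blank for uncalibrated items.
    """
    rows = []
    for spec in bank.items:
        if spec.n_categories > MAX_THRESHOLD_COLS + 1:
            raise ValueError(
                f"item {spec.item_id!r}: bank file format supports at most "
                f"{MAX_THRESHOLD_COLS + 1} categories"
            )
        row: dict[str, Any] = {
            "item_id": spec.item_id,
            "subdomain": spec.subdomain,
            "n_categories": spec.n_categories,
        }
        p = bank.params.get(spec.item_id)
        if p is not None:
            row["a0"] = p.a0
            row["ag"] = p.ag
            for i, c in enumerate(p.thresholds, start=1):
                row[f"c_{i}"] = c
        rows.append(row)
    cols = ["item_id", "subdomain", "n_categories", "a0", "ag"] + [
        f"c_{i}" for i in range(1, MAX_THRESHOLD_COLS + 1)
    ]
    df = pd.DataFrame(rows).reindex(columns=cols)
    write_table(df, Path(path), prov)


def read_bank(path: str | Path) -> Bank:
    df = pd.read_csv(path, comment="#")
    required = {"item_id", "subdomain", "n_categories"}
    if missing := required - set(df.columns):
        raise ValueError(f"bank file {path}: missing columns {sorted(missing)}")
    items: list[ItemSpec] = []
    params: dict[str, ItemParams] = {}
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        try:
            spec = ItemSpec(
                str(row.item_id), str(row.subdomain), int(row.n_categories)
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"bank file {path}, line {ln}: {exc}") from exc
        items.append(spec)
        a0 = getattr(row, "a0", float("nan"))
        if a0 is not None and not pd.isna(a0):
            thr = []
            for i in range(1, spec.n_categories):
                c = getattr(row, f"c_{i}", float("nan"))
                if pd.isna(c):
                    raise ValueError(
                        f"bank file {path}, line {ln}: item {spec.item_id!r} "
                        f"has a0 but is missing threshold c_{i}"
                    )
                thr.append(float(c))
            try:
                params[spec.item_id] = ItemParams(
                    float(a0), float(row.ag), tuple(thr)
                )
            except ValueError as exc:
                raise ValueError(f"bank file {path}, line {ln}: {exc}") from exc
    subdomains = tuple(dict.fromkeys(it.subdomain for it in items))
    return Bank(items=items, params=params, subdomains=subdomains)


# ---------------------------------------------------------------------------
# Response matrices and labels
# ---------------------------------------------------------------------------


def write_responses(
    responses: ResponseMatrix, path: str | Path, prov: dict | None = None
) -> None:
    """Delimited matrix, persons as rows, items as columns, blank = missing."""
    df = responses.to_dataframe()
    out = df.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.index.name = "person_id"
    with open(path, "w") as fh:
        if prov is not None:
            fh.write(f"# provenance: {json.dumps(prov, sort_keys=True)}\n")
        out.to_csv(fh)


def read_responses(path: str | Path, bank: Bank | None = None) -> ResponseMatrix:
    df = pd.read_csv(path, comment="#", index_col=0, dtype=str)
    vals = df.to_numpy()
    codes = np.full(vals.shape, MISSING, dtype=np.int16)
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            v = vals[i, j]
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                continue
            try:
                codes[i, j] = int(float(v))
            except ValueError as exc:
                raise ValueError(
                    f"responses file {path}, row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}: bad code {v!r}"
                ) from exc
    rm = ResponseMatrix(
        codes, [str(i) for i in df.index], [str(c) for c in df.columns]
    )
    if bank is not None:
        rm.validate_against(bank)
    return rm


def write_labels(
    labels: Sequence[int],
    person_ids: Sequence[str],
    path: str | Path,
    prov: dict | None = None,
) -> None:
    df = pd.DataFrame({"person_id": list(person_ids), "label": list(map(int, labels))})
    write_table(df, Path(path), prov)


def read_labels(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, comment="#")
    if not {"person_id", "label"} <= set(df.columns):
        raise ValueError(f"labels file {path}: needs person_id and label columns")
    labels = df["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"labels file {path}: labels must be 0/1")
    return labels.astype(np.int8), [str(p) for p in df["person_id"]]


# ---------------------------------------------------------------------------
# CAD model serialization
# ---------------------------------------------------------------------------


def write_model(model: CadModel, path: str | Path, prov: dict | None = None) -> None:
    doc = {
        "format": "catcad-cad-model",
        "provenance": prov,
        "combiner": model.combiner,
        "weights": [float(w) for w in model.weights],
        "intercept": model.intercept,
        "threshold": model.threshold,
        "seed": model.seed,
        "degenerate": model.degenerate,
        "item_range": model.item_range,
        "trees": [t.to_dict() for t in model.trees],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_model(path: str | Path) -> CadModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "catcad-cad-model":
        raise ValueError(f"{path}: not a screener model file")
    return CadModel(
        trees=[TreeNode.from_dict(t) for t in doc["trees"]],
        weights=np.array(doc["weights"], dtype=float),
        intercept=float(doc["intercept"]),
        combiner=doc["combiner"],
        threshold=float(doc["threshold"]),
        item_range={k: int(v) for k, v in doc["item_range"].items()},
        seed=int(doc["seed"]),
        degenerate=bool(doc["degenerate"]),
    )


# ---------------------------------------------------------------------------
# CAT session logs
# ---------------------------------------------------------------------------


def write_session_log(
    session: CatSession, path: str | Path, prov: dict | None = None
) -> None:
    """Line-per-step TSV: step, item, response, score, uncertainty."""
    with open(path, "w") as fh:
        if prov is not None:
            fh.write(f"# provenance: {json.dumps(prov, sort_keys=True)}\n")
        fh.write(f"# stop_reason: {session.stop_reason or ''}\n")
        fh.write("step\titem_id\tresponse\tscore\tuncertainty\n")
        for k, (iid, resp, (score, unc)) in enumerate(
            zip(session.administered, session.responses, session.trajectory), start=1
        ):
            fh.write(f"{k}\t{iid}\t{resp}\t{score:.6f}\t{unc:.6f}\n")


def read_session_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["step", "item_id", "response", "score", "uncertainty"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: malformed session log (columns {list(df.columns)})")
    return df


def replay_session(
    log: pd.DataFrame,
    bank: Bank,
    config: CatConfig | None = None,
    transform: ScoreTransform | None = None,
) -> CatSession:
    """Re-score a logged session from its (item, response) sequence.

    The replay trajectory is identical to the original run because scoring
    is deterministic given the bank and transform.
    """
    from catcad.bifactor import PosteriorTracker
    from catcad.cat import CatSession as _Session
    from catcad.cat import ScoreTransform as _Transform

    config = config or CatConfig()
    transform = transform or _Transform()
    session = _Session(
        bank=bank,
        config=config,
        transform=transform,
        _tracker=PosteriorTracker(
            bank, marginalize_groups=config.info_mode == "marginal"
        ),
    )
    for rec in log.itertuples(index=False):
        session._tracker.add_response(str(rec.item_id), int(rec.response))
        session.administered.append(str(rec.item_id))
        session.responses.append(int(rec.response))
        session.state = session._tracker.state()
        session.trajectory.append((session.score, session.uncertainty))
    return session


def write_json(doc: dict, path: str | Path, prov: dict | None = None) -> None:
    if prov is not None:
        doc = {"provenance": prov, **doc}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
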