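"""Dataset reading, report writing, and the end-to-end pipeline.

Datasets are plain tables of (id, smiles, endpoint) with an optional split
label column, read from CSV/TSV or from ``.smi`` files (SMILES first,
tab-separated).  Duplicate SMILES are detected by exact string match and
reported; QSAR collections assembled from the literature routinely contain
them and they distort split statistics.

``run_pipeline`` ties the modules together: generate or load data, choose
a split (fixed fractions, a provided label file, or the Las Vegas search),
optimize the correlation weights, and write the split, the model, a
per-subset statistics report, and per-molecule predictions with an
applicability-domain flag.  Every artifact embeds the seed and a hash of
the configuration so a run can be replayed exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import splits as splits_mod
from . import stats as stats_mod
from .attributes import AttributeConfig, extract_attributes
from .errors import ParseError
from .model import CLASSIFICATION, REGRESSION
from .optimizer import TargetConfig, optimize
from .synth import GeneratorConfig, generate_dataset, ground_truth


@dataclass
class SmilesRecord:
    id: str
    smiles: str
    endpoint: float
    label: str | None = None


@dataclass
class Dataset:
    records: list[SmilesRecord] = field(default_factory=list)
    task: str = REGRESSION
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def endpoints(self) -> np.ndarray:
        return np.array([r.endpoint for r in self.records])

    @property
    def labels(self) -> list[str] | None:
        labs = [r.label for r in self.records]
        return None if any(l is None for l in labs) else labs  # noqa: E741


def _validate(df: pd.DataFrame, task: str, drop_duplicates: bool) -> Dataset:
    ids = df["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for line, i in enumerate(ids, start=2):
            if i in seen:
                raise ParseError(f"duplicate id {i!r} at line {line}")
            seen.add(i)
    endpoints = pd.to_numeric(df["endpoint"], errors="coerce")
    bad = endpoints.isna()
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
        raise ParseError(f"non-numeric endpoint at line {line}")
    if task == CLASSIFICATION:
        vals = endpoints.to_numpy()
        off = ~np.isin(vals, (0.0, 1.0))
        if off.any():
            line = int(np.nonzero(off)[0][0]) + 2
            raise ParseError(f"classification endpoint not 0/1 at line {line}")
    # duplicate SMILES report (exact string match)
    first_seen: dict[str, str] = {}
    dupes: list[tuple[str, str]] = []
    keep = []
    for i, s in zip(ids, df["smiles"].astype(str)):
        if s in first_seen:
            dupes.append((first_seen[s], i))
            keep.append(False)
        else:
            first_seen[s] = i
            keep.append(True)
    if drop_duplicates:
        df = df[keep]
        ids = df["id"].astype(str).tolist()
        endpoints = endpoints[keep]
    records = [
        SmilesRecord(
            id=i,
            smiles=str(s),
            endpoint=float(e),
            label=(str(l) if l is not None and l == l else None),  # noqa: E741
        )
        for i, s, e, l in zip(  # noqa: E741
            ids,
            df["smiles"],
            endpoints,
            df["label"] if "label" in df.columns else [None] * len(df),
        )
    ]
    return Dataset(records=records, task=task, duplicate_pairs=dupes)


def read_dataset(
    path: str | Path,
    fmt: str | None = None,
    task: str = REGRESSION,
    drop_duplicates: bool = False,
) -> Dataset:
    """Read a dataset from CSV, TSV, or .smi.

    CSV/TSV need columns ``id``, ``smiles``, ``endpoint`` (optional
    ``label``); ``.smi`` is tab-separated SMILES / id / endpoint.  Typed
    parse errors carry one-based line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = fmt or {".csv": "csv", ".tsv": "tsv", ".smi": "smi"}.get(
        path.suffix.lower(), "csv"
    )
    if fmt == "smi":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["smiles", "id", "endpoint"]
        )
    else:
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")
    missing = {"id", "smiles", "endpoint"} - set(df.columns)
    if missing:
        raise ParseError(f"missing columns: {sorted(missing)}")
    return _validate(df, task, drop_duplicates)


# ---------------------------------------------------------------------------
# report writers


def _fmt(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "-"
    if isinstance(v, float) and math.isinf(v):
        return "inf"
    return f"{v:.4g}" if isinstance(v, float) else str(v)


REGRESSION_COLUMNS = ["set", "n", "R2", "CCC", "IIC", "CII", "Q2", "CCCP", "RMSE", "MAE", "F"]
CLASSIFICATION_COLUMNS = ["set", "n", "Sensitivity", "Specificity", "Accuracy", "MCC"]


def write_stats_report(path: str | Path, per_subset: dict[str, Any], task: str) -> None:
    """One TSV row per subset, columns mirroring the standard report layout."""
    lines = []
    if task == REGRESSION:
        lines.append("\t".join(REGRESSION_COLUMNS))
        for subset, st in per_subset.items():
            lines.append(
                "\t".join(
                    [subset, str(st.n)]
                    + [_fmt(getattr(st, a)) for a in
                       ("r2", "ccc", "iic", "cii", "q2", "cccp", "rmse", "mae", "f")]
                )
            )
    else:
        lines.append("\t".join(CLASSIFICATION_COLUMNS))
        for subset, st in per_subset.items():
            lines.append(
                "\t".join(
                    [subset, str(st.n)]
                    + [_fmt(getattr(st, a)) for a in
                       ("sensitivity", "specificity", "accuracy", "mcc")]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_split(path: str | Path, split: splits_mod.Split) -> None:
    lines = ["id,label"] + [f"{i},{lab}" for i, lab in split.assignment.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_split(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    if {"id", "label"} - set(df.columns):
        raise ParseError("split file needs columns id,label")
    bad = ~df["label"].isin(list(splits_mod.SUBSETS))
    if bad.any():
        raise ParseError("split labels must be A, P, C or V")
    return dict(zip(df["id"].astype(str), df["label"]))


def write_trace(path: str | Path, records: list[dict]) -> None:
    if not records:
        Path(path).write_text("")
        return
    cols = list(records[0])
    lines = ["\t".join(cols)]
    for r in records:
        lines.append("\t".join(_fmt(r[c]) if isinstance(r[c], float) else str(r[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pipeline


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path) -> dict[str, Path]:
    """Run split -> train -> stats -> predict and write all artifacts.

    ``config`` keys (all optional unless noted):

    - ``task``: "regression" (default) or "classification"
    - ``data``: path to a dataset file, or ``{"synthetic": {...}}`` with
      :class:`~cwqsar.synth.GeneratorConfig` fields (required)
    - ``split``: ``{"fractions": [...], "seed": int}`` |
      ``{"file": path}`` | ``{"lasvegas": {"tests": K, "probe_epochs": E}}``
    - ``target``: :class:`~cwqsar.optimizer.TargetConfig` fields
    - ``attributes``: :class:`~cwqsar.attributes.AttributeConfig` fields
    - ``epochs``, ``threshold``, ``delta``, ``seed``

    Writes split.csv, model.json, stats.tsv, predictions.csv, trace.tsv
    and run_log.json; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    task = config.get("task", REGRESSION)
    seed = int(config.get("seed", 0))

    data_spec = config["data"]
    if isinstance(data_spec, dict) and "synthetic" in data_spec:
        gen_fields = dict(data_spec["synthetic"])
        gen_fields.setdefault("task", task)
        gen_fields.setdefault("seed", seed)
        gcfg = GeneratorConfig(**gen_fields)
        df = generate_dataset(gcfg)
        (out / "ground_truth.json").write_text(
            json.dumps(ground_truth(gcfg), indent=1)
        )
        dataset = _validate(df, task, drop_duplicates=False)
    else:
        dataset = read_dataset(
            data_spec, task=task,
            drop_duplicates=bool(config.get("drop_duplicates", False)),
        )

    ids, smiles, y = dataset.ids, dataset.smiles, dataset.endpoints
    acfg = AttributeConfig(**config.get("attributes", {}))
    tcfg = TargetConfig(**config.get("target", {}))
    epochs = int(config.get("epochs", 30))
    threshold = int(config.get("threshold", 1))
    delta = float(config.get("delta", 0.1))

    split_spec = config.get("split", {})
    if "file" in split_spec:
        assignment = read_split(split_spec["file"])
        missing = set(ids) - set(assignment)
        if missing:
            raise ParseError(f"split file misses ids: {sorted(missing)[:5]}")
        split = splits_mod.Split(
            assignment={i: assignment[i] for i in ids}, fractions=(0, 0, 0, 0)
        )
        lv_trace = None
    elif "lasvegas" in split_spec:
        lv = split_spec["lasvegas"]
        split, lv_trace = splits_mod.las_vegas(
            ids, smiles, y,
            n_tests=int(lv.get("tests", 10)),
            probe_epochs=int(lv.get("probe_epochs", 5)),
            fractions=tuple(lv.get("fractions", (0.25, 0.25, 0.25, 0.25))),
            target=tcfg, threshold=threshold, attr_config=acfg,
            seed=seed,
        )
    else:
        split = splits_mod.random_split(
            ids,
            tuple(split_spec.get("fractions", (0.25, 0.25, 0.25, 0.25))),
            seed=int(split_spec.get("seed", seed)),
        )
        lv_trace = None
    labels = split.labels_for(ids)

    state, trace = optimize(
        smiles, y, labels,
        target=tcfg, epochs=epochs, threshold=threshold, seed=seed,
        attr_config=acfg, task=task, delta=delta,
    )

    bags = [extract_attributes(s, acfg) for s in smiles]
    pred = np.array([state.predict(b) for b in bags])
    defects = splits_mod.compute_defects(ids, bags, labels, state.weight_table)

    per_subset: dict[str, Any] = {}
    for subset in splits_mod.SUBSETS:
        idx = [i for i, lab in enumerate(labels) if lab == subset]
        if not idx:
            continue
        if task == REGRESSION:
            per_subset[subset] = stats_mod.regression_stats(y[idx], pred[idx])
        else:
            calls = (pred[idx] >= 0.5).astype(int)
            per_subset[subset] = stats_mod.classification_stats(
                y[idx].astype(int), calls
            )

    paths = {
        "split": out / "split.csv",
        "model": out / "model.json",
        "stats": out / "stats.tsv",
        "predictions": out / "predictions.csv",
        "trace": out / "trace.tsv",
        "log": out / "run_log.json",
    }
    write_split(paths["split"], split)
    paths["model"].write_text(state.to_json())
    write_stats_report(paths["stats"], per_subset, task)
    pred_df = pd.DataFrame(
        {
            "id": ids,
            "smiles": smiles,
            "label": labels,
            "observed": y,
            "predicted": pred,
            "defect": [defects.smiles_defects[i] for i in ids],
            "in_domain": [
                splits_mod.in_domain(defects.smiles_defects[i], defects.mean_defect)
                for i in ids
            ],
        }
    )
    if task == CLASSIFICATION:
        pred_df["predicted_class"] = (pred >= 0.5).astype(int)
    pred_df.to_csv(paths["predictions"], index=False)
    write_trace(paths["trace"], trace.to_records())
    if lv_trace is not None:
        paths["lasvegas"] = out / "lasvegas.tsv"
        write_trace(paths["lasvegas"], lv_trace.to_records())
    log = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "duplicate_smiles_pairs": dataset.duplicate_pairs,
        "subset_sizes": split.sizes(),
        "mean_defect": defects.mean_defect,
    }
    paths["log"].write_text(json.dumps(log, indent=1, default=str))
    return paths
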