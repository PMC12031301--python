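"""Optimal descriptor and the one-descriptor model built on it.

A molecule's descriptor value is the sum, over its attribute bag, of the
correlation weight of each non-blocked attribute times its multiplicity:

    DCW = sum_k  count_k * CW_k        (blocked attributes contribute 0)

An attribute is *blocked* when it occurs too rarely in the active training
set (fewer than ``threshold`` occurrences), because its weight could not be
optimized reliably.  The endpoint model is the univariate line

    y = C0 + C1 * DCW

fit by ordinary least squares.  For binary endpoints the same line acts as
a semi-correlation classifier: a molecule is called active when the
regression response reaches 0.5 (boundary inclusive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np

from .attributes import AttributeBag
from .errors import (
    DegenerateDataError,
    ModelStateError,
    TaskMismatchError,
)

REGRESSION = "regression"
CLASSIFICATION = "classification"


@dataclass
class WeightTable:
    """Correlation weights per attribute key, with blocking bookkeeping.

    ``counts`` records occurrence totals per structured-training subset
    (keys "A", "P", "C"); ``blocked`` lists the keys excluded from the
    descriptor.  Blocked keys keep a weight entry of 0 so that serialized
    tables are self-contained.
    """

    weights: dict[str, float] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    blocked: set[str] = field(default_factory=set)

    @classmethod
    def from_bags(
        cls,
        bags_by_subset: dict[str, Iterable[AttributeBag]],
        threshold: int = 1,
    ) -> "WeightTable":
        """Build the table from attribute bags grouped by subset label.

        A key is blocked iff its total occurrence count in the active
        training set ("A") is below ``threshold``.
        """
        counts: dict[str, dict[str, int]] = {}
        for label, bags in bags_by_subset.items():
            for bag in bags:
                for key, c in bag.keys.items():
                    counts.setdefault(key, {}).setdefault(label, 0)
                    counts[key][label] += c
        table = cls()
        table.counts = counts
        for key, per_subset in counts.items():
            if per_subset.get("A", 0) < threshold:
                table.blocked.add(key)
                table.weights[key] = 0.0
            else:
                table.weights[key] = 1.0
        return table

    def active_keys(self) -> list[str]:
        return sorted(k for k in self.weights if k not in self.blocked)

    def dcw(self, bag: AttributeBag) -> float:
        return dcw(bag, self)


def dcw(bag: AttributeBag, table: WeightTable) -> float:
    """Descriptor of correlation weights of one molecule.

    Sums multiplicity times weight over the bag's non-blocked keys; keys
    absent from the table (unseen in training) contribute nothing, as do
    blocked keys.  An empty bag scores 0.
    """
    total = 0.0
    for key, count in bag.keys.items():
        if key in table.blocked:
            continue
        w = table.weights.get(key)
        if w is not None:
            total += count * w
    return total


def fit_regression(dcw_values, endpoints) -> tuple[float, float]:
    """Ordinary least squares for the univariate line y = C0 + C1 * DCW.

    Raises
    ------
    DegenerateDataError
        if the descriptor has zero variance (typically an over-blocked
        weight table collapsing every molecule to the same descriptor).
    """
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DegenerateDataError("need matching 1-D vectors with n >= 3")
    mx = x.mean()
    sxx = float(((x - mx) ** 2).sum())
    if sxx <= 1e-300:
        raise DegenerateDataError(
            "descriptor variance is zero (over-blocked weight table?)"
        )
    c1 = float(((x - mx) * (y - y.mean())).sum() / sxx)
    c0 = float(y.mean() - c1 * mx)
    return c0, c1


@dataclass
class ModelState:
    """A trained one-descriptor model: weights plus regression coefficients.

    ``config`` is an arbitrary JSON-serializable snapshot of the settings
    that produced the model (attribute families, target function, epochs,
    threshold); ``seed`` is the optimization seed.  The JSON round trip is
    exact: floats are serialized with full repr precision.
    """

    weight_table: WeightTable
    c0: float | None = None
    c1: float | None = None
    task: str = REGRESSION
    config: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    @property
    def fitted(self) -> bool:
        return self.c0 is not None and self.c1 is not None

    def predict(self, bag: AttributeBag) -> float:
        if not self.fitted:
            raise ModelStateError("model has no regression coefficients yet")
        return self.c0 + self.c1 * dcw(bag, self.weight_table)

    def classify(self, bag: AttributeBag) -> int:
        """Semi-correlation class call: active (1) iff the response >= 0.5."""
        if self.task != CLASSIFICATION:
            raise TaskMismatchError("classify() requires a classification model")
        return 1 if self.predict(bag) >= 0.5 else 0

    def to_json(self) -> str:
        payload = {
            "task": self.task,
            "c0": self.c0,
            "c1": self.c1,
            "seed": self.seed,
            "config": self.config,
            "weights": dict(sorted(self.weight_table.weights.items())),
            "blocked": sorted(self.weight_table.blocked),
            "counts": {
                k: dict(sorted(v.items()))
                for k, v in sorted(self.weight_table.counts.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelState":
        payload = json.loads(text)
        table = WeightTable(
            weights=dict(payload["weights"]),
            counts={k: dict(v) for k, v in payload["counts"].items()},
            blocked=set(payload["blocked"]),
        )
        return cls(
            weight_table=table,
            c0=payload["c0"],
            c1=payload["c1"],
            task=payload["task"],
            config=payload["config"],
            seed=payload["seed"],
        )


def predict(model: ModelState, bag: AttributeBag) -> float:
    return model.predict(bag)


def classify(model: ModelState, bag: AttributeBag) -> int:
    return model.classify(bag)
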