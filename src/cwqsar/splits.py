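"""Structured splits, statistical defects, applicability domain, Las Vegas.

The data are divided four ways: an active training set A (weights are
tuned against it), a passive training set P (a concurrent check that the
weights generalize), a calibration set C (the maturing model's criteria
are measured on it), and a validation set V (never seen during training).

How evenly an attribute is spread over A, P and C is measured by its
*statistical defect*

    d_k = |P - P'|/(N + N') + |P - P''|/(N + N'') + |P' - P''|/(N' + N'')

where P, P', P'' are the probabilities of the attribute (fraction of
molecules containing it) in A, P, C and N, N', N'' the corresponding
molecule counts.  A molecule's defect D_j sums d_k over its non-blocked
attributes, and a molecule is inside the applicability domain when
D_j < 2 * mean(D) over the structured training set.

The Las Vegas split search draws random splits, runs a short Monte Carlo
probe on each, and keeps the split whose probe achieves the best
calibration determination coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Hashable, Sequence

import numpy as np

from . import stats
from .attributes import AttributeBag, AttributeConfig, extract_attributes
from .errors import SplitError, UndefinedStatisticError
from .model import WeightTable, dcw
from .optimizer import DEFAULT_THRESHOLD, OptimizationTrace, TargetConfig, optimize

SUBSETS = ("A", "P", "C", "V")


@dataclass
class Split:
    """Assignment of every record to exactly one of A, P, C, V."""

    assignment: dict[Hashable, str]
    fractions: tuple[float, float, float, float]

    def ids(self, subset: str) -> list:
        return [i for i, lab in self.assignment.items() if lab == subset]

    def labels_for(self, ids: Sequence[Hashable]) -> list[str]:
        return [self.assignment[i] for i in ids]

    def sizes(self) -> dict[str, int]:
        out = {s: 0 for s in SUBSETS}
        for lab in self.assignment.values():
            out[lab] += 1
        return out


def random_split(
    ids: Sequence[Hashable],
    fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> Split:
    """Seeded shuffle followed by a contiguous four-way cut.

    Cut points are ``round(n * cumulative_fraction)``, so subset sizes
    differ from the exact products by at most one molecule.
    """
    n = len(ids)
    if n < 8:
        raise SplitError("need at least 8 records for a four-way split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    bounds = [int(round(n * c)) for c in np.cumsum(fractions)]
    bounds[-1] = n
    assignment: dict[Hashable, str] = {}
    start = 0
    for label, stop in zip(SUBSETS, bounds):
        if stop <= start:
            raise SplitError(f"subset {label!r} would be empty")
        for k in order[start:stop]:
            assignment[ids[int(k)]] = label
        start = stop
    return Split(assignment=assignment, fractions=tuple(fractions))


def balanced_subset(
    actives: Sequence[Hashable], inactives: Sequence[Hashable], seed: int = 0
) -> list:
    """All actives plus an equal-size random sample of inactives."""
    if len(inactives) < len(actives):
        raise SplitError("fewer inactives than actives; cannot balance")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(inactives), size=len(actives), replace=False)
    return list(actives) + [inactives[int(i)] for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# statistical defects and applicability domain


@dataclass
class DefectTable:
    attribute_defects: dict[str, float] = field(default_factory=dict)
    smiles_defects: dict[Hashable, float] = field(default_factory=dict)
    mean_defect: float = 0.0


def attribute_defect(
    presence: dict[str, tuple[int, int]],
) -> float:
    """Defect of one attribute from per-subset (molecules-with, subset-size).

    ``presence`` maps each of "A", "P", "C" to a pair (number of molecules
    containing the attribute, number of molecules in the subset).  A term
    whose two counts are both zero contributes nothing (the probabilities
    agree at zero).
    """
    vals = {}
    for s in ("A", "P", "C"):
        n_with, n_total = presence[s]
        vals[s] = (n_with / n_total if n_total else 0.0, n_with)
    if all(v[1] == 0 for v in vals.values()):
        raise UndefinedStatisticError("attribute absent from A, P and C")
    d = 0.0
    for s1, s2 in (("A", "P"), ("A", "C"), ("P", "C")):
        (p1, n1), (p2, n2) = vals[s1], vals[s2]
        if n1 + n2 > 0:
            d += abs(p1 - p2) / (n1 + n2)
    return d


def compute_defects(
    ids: Sequence[Hashable],
    bags: Sequence[AttributeBag],
    labels: Sequence[str],
    table: WeightTable,
) -> DefectTable:
    """Attribute and per-molecule defects for a given split.

    Molecule defects sum the defects of the molecule's distinct non-blocked
    attributes; the mean defect is taken over the structured training set
    (A + P + C) only, and validation molecules are judged against it.
    """
    subset_ids = {s: [] for s in ("A", "P", "C")}
    for i, lab in zip(range(len(ids)), labels):
        if lab in subset_ids:
            subset_ids[lab].append(i)
    sizes = {s: len(v) for s, v in subset_ids.items()}
    # molecules-containing counts per subset
    containing: dict[str, dict[str, int]] = {}
    for s, idxs in subset_ids.items():
        for i in idxs:
            for key in bags[i].keys:
                containing.setdefault(key, {}).setdefault(s, 0)
                containing[key][s] += 1
    d_k: dict[str, float] = {}
    for key, per in containing.items():
        d_k[key] = attribute_defect(
            {s: (per.get(s, 0), sizes[s]) for s in ("A", "P", "C")}
        )
    out = DefectTable(attribute_defects=d_k)
    training_defects = []
    for rid, bag, lab in zip(ids, bags, labels):
        dj = sum(
            d_k[key]
            for key in bag.keys
            if key in d_k and key not in table.blocked
        )
        out.smiles_defects[rid] = dj
        if lab in ("A", "P", "C"):
            training_defects.append(dj)
    out.mean_defect = float(np.mean(training_defects)) if training_defects else 0.0
    return out


def smiles_defect(bag: AttributeBag, defects: DefectTable, table: WeightTable) -> float:
    """Defect of one molecule: sum of its non-blocked attributes' defects."""
    return sum(
        defects.attribute_defects[key]
        for key in bag.keys
        if key in defects.attribute_defects and key not in table.blocked
    )


def in_domain(d_j: float, mean_defect: float) -> bool:
    """Applicability-domain test: D_j < 2 * mean defect.

    When every defect is zero (perfectly balanced split) the strict
    inequality would exclude everything; that degenerate case is defined
    as all-in-domain.
    """
    if mean_defect == 0:
        return True
    return d_j < 2.0 * mean_defect


# ---------------------------------------------------------------------------
# attribute partition census and the Las Vegas algorithm


@dataclass
class PartitionCensus:
    w_pct: int
    n111: int
    n110: int
    n101: int
    n100: int
    n_all: int


def partition_census(table: WeightTable) -> PartitionCensus:
    """Distinct-attribute census over the structured training subsets.

    Of the attributes seen in the active training set: N111 also occur in
    both P and C, N110 in P only, N101 in C only, N100 in neither.  NAll
    is the number of distinct attributes in A, and W% the percentage of
    all distinct attributes (over A, P, C) that are non-blocked, i.e.
    taking part in the optimization.
    """
    in_sub = {
        s: {k for k, per in table.counts.items() if per.get(s, 0) > 0}
        for s in ("A", "P", "C")
    }
    a, p, c = in_sub["A"], in_sub["P"], in_sub["C"]
    n111 = len(a & p & c)
    n110 = len((a & p) - c)
    n101 = len((a & c) - p)
    n100 = len(a - p - c)
    total = len(a | p | c)
    nonblocked = len([k for k in (a | p | c) if k not in table.blocked])
    w_pct = int(round(100 * nonblocked / total)) if total else 0
    return PartitionCensus(w_pct, n111, n110, n101, n100, len(a))


@dataclass
class LasVegasRow:
    test: int
    w_pct: int
    n111: int
    n110: int
    n101: int
    n100: int
    n_all: int
    cccp: float
    r2_a: float
    r2_p: float
    r2_c: float
    best_r2_c: float
    best_test: int
    failed: bool = False


@dataclass
class LasVegasTrace:
    rows: list[LasVegasRow] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [asdict(r) for r in self.rows]


def las_vegas(
    ids: Sequence[Hashable],
    smiles: Sequence[str],
    endpoints: Sequence[float],
    *,
    n_tests: int = 10,
    fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    probe_epochs: int = 5,
    target: TargetConfig | None = None,
    threshold: int = DEFAULT_THRESHOLD,
    attr_config: AttributeConfig | None = None,
    seed: int = 0,
) -> tuple[Split, LasVegasTrace]:
    """Randomized split search keeping the best-calibrating probe.

    Each test draws a fresh random split and runs a short Monte Carlo
    probe; the split whose probe reaches the largest calibration R² wins.
    A failed probe (degenerate split) is recorded with R²_C = 0 and the
    search continues.
    """
    if n_tests < 1:
        raise SplitError("need at least one Las Vegas test")
    rng = np.random.default_rng(seed)
    trace = LasVegasTrace()
    best_r2c = -math.inf
    best_split: Split | None = None
    best_test = 0
    acfg = attr_config or AttributeConfig()
    for t in range(1, n_tests + 1):
        split_seed = int(rng.integers(0, 2**31 - 1))
        probe_seed = int(rng.integers(0, 2**31 - 1))
        try:
            split = random_split(ids, fractions, seed=split_seed)
            labels = split.labels_for(ids)
            state, _ = optimize(
                smiles,
                endpoints,
                labels,
                target=target,
                epochs=probe_epochs,
                threshold=threshold,
                seed=probe_seed,
                attr_config=acfg,
            )
            bags = [extract_attributes(s, acfg) for s in smiles]
            pred = np.array(
                [state.c0 + state.c1 * dcw(b, state.weight_table) for b in bags]
            )
            y = np.asarray(endpoints, dtype=float)
            idx = {s: [i for i, lab in enumerate(labels) if lab == s] for s in SUBSETS}
            r2a = stats.pearson_r(y[idx["A"]], pred[idx["A"]]) ** 2
            r2p = stats.pearson_r(y[idx["P"]], pred[idx["P"]]) ** 2
            r2c = stats.pearson_r(y[idx["C"]], pred[idx["C"]]) ** 2
            try:
                cccp_c = stats.cccp(
                    stats.loo_influence(y[idx["C"]], pred[idx["C"]])
                )
            except UndefinedStatisticError:
                cccp_c = math.nan
            census = partition_census(state.weight_table)
            failed = False
        except Exception:
            split = None
            census = PartitionCensus(0, 0, 0, 0, 0, 0)
            cccp_c, r2a, r2p, r2c = math.nan, 0.0, 0.0, 0.0
            failed = True
        if not failed and r2c > best_r2c:
            best_r2c, best_split, best_test = r2c, split, t
        trace.rows.append(
            LasVegasRow(
                test=t,
                w_pct=census.w_pct,
                n111=census.n111,
                n110=census.n110,
                n101=census.n101,
                n100=census.n100,
                n_all=census.n_all,
                cccp=cccp_c,
                r2_a=r2a,
                r2_p=r2p,
                r2_c=r2c,
                best_r2_c=best_r2c if best_split is not None else 0.0,
                best_test=best_test,
                failed=failed,
            )
        )
    if best_split is None:
        raise SplitError("every Las Vegas probe failed")
    return best_split, trace
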