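"""Splits, statistical defects, applicability domain, Las Vegas search."""

import numpy as np
import pytest

from cwqsar.attributes import AttributeBag, extract_attributes
from cwqsar.errors import SplitError, UndefinedStatisticError
from cwqsar.model import WeightTable
from cwqsar.splits import (
    attribute_defect,
    balanced_subset,
    compute_defects,
    in_domain,
    las_vegas,
    partition_census,
    random_split,
)
from cwqsar.synth import generate_dataset

from conftest import easy_config


def test_random_split_sizes_and_determinism():
    ids = list(range(8))
    sp = random_split(ids, seed=0)
    assert sorted(sp.sizes().values()) == [2, 2, 2, 2]
    assert random_split(ids, seed=0).assignment == sp.assignment
    assert random_split(ids, seed=1).assignment != sp.assignment

    big = random_split(list(range(394)), seed=3)
    assert big.sizes() == {"A": 98, "P": 99, "C": 99, "V": 98}


def test_random_split_errors():
    with pytest.raises(SplitError):
        random_split(list(range(7)))
    with pytest.raises(SplitError):
        random_split(list(range(20)), fractions=(0.5, 0.3, 0.3, 0.1))
    with pytest.raises(SplitError):
        random_split(list(range(10)), fractions=(0.97, 0.01, 0.01, 0.01))


def test_balanced_subset():
    picked = balanced_subset(list("abcde"), list(range(20)), seed=4)
    assert len(picked) == 10
    assert set("abcde") <= set(picked)
    assert balanced_subset(list("ab"), [1, 2], seed=0) == ["a", "b", 1, 2]
    assert balanced_subset(list("abcde"), list(range(20)), seed=4) == picked
    with pytest.raises(SplitError):
        balanced_subset([1, 2, 3], [1])


def test_attribute_defect_arithmetic():
    equal = {"A": (5, 10), "P": (10, 20), "C": (2, 4)}  # all probabilities 0.5
    assert attribute_defect(equal) == pytest.approx(0.0, abs=1e-15)
    only_a = {"A": (5, 10), "P": (0, 20), "C": (0, 4)}
    assert attribute_defect(only_a) > 0
    # direct arithmetic on an arbitrary table
    table = {"A": (3, 10), "P": (6, 20), "C": (1, 4)}
    p = {s: c / n for s, (c, n) in table.items()}
    n = {s: c for s, (c, _) in table.items()}
    expected = (
        abs(p["A"] - p["P"]) / (n["A"] + n["P"])
        + abs(p["A"] - p["C"]) / (n["A"] + n["C"])
        + abs(p["P"] - p["C"]) / (n["P"] + n["C"])
    )
    assert attribute_defect(table) == pytest.approx(expected, abs=1e-15)
    with pytest.raises(UndefinedStatisticError):
        attribute_defect({"A": (0, 10), "P": (0, 20), "C": (0, 4)})


def _bag(keys: dict) -> AttributeBag:
    bag = AttributeBag()
    for k, c in keys.items():
        bag.add(k, "Sk", c)
    return bag


def test_molecule_defect_sums_only_non_blocked():
    ids = ["m1", "m2", "m3"]
    bags = [_bag({"C": 2, "N": 1}), _bag({"C": 1}), _bag({"N": 1})]
    labels = ["A", "P", "C"]
    table = WeightTable(
        weights={"C": 1.0, "N": 0.0},
        counts={"C": {"A": 2, "P": 1}, "N": {"A": 1, "C": 1}},
        blocked={"N"},
    )
    defects = compute_defects(ids, bags, labels, table)
    d_c = defects.attribute_defects["C"]
    # m1 contains C (non-blocked) and N (blocked): only C counts
    assert defects.smiles_defects["m1"] == pytest.approx(d_c)
    assert defects.smiles_defects["m3"] == 0.0  # only the blocked attribute


def test_in_domain_rules():
    assert in_domain(0.5, 0.5)
    assert not in_domain(1.25, 0.5)
    assert in_domain(0.0, 0.0)  # all-zero defects: everything in domain
    assert in_domain(123.0, 0.0)


def test_partition_census_hand_fixture():
    counts = {
        "everywhere": {"A": 3, "P": 1, "C": 2},
        "train_only": {"A": 1, "P": 2},
        "a_and_c": {"A": 2, "C": 1},
        "a_only": {"A": 1},
        "c_only": {"C": 4},
    }
    table = WeightTable(
        weights={k: 1.0 for k in counts},
        counts=counts,
        blocked={"a_only", "c_only"},
    )
    census = partition_census(table)
    assert (census.n111, census.n110, census.n101, census.n100) == (1, 1, 1, 1)
    assert census.n_all == 4
    assert census.n111 + census.n110 + census.n101 + census.n100 <= census.n_all
    assert census.w_pct == round(100 * 3 / 5)


def test_defects_on_identical_generators_mostly_in_domain():
    df = generate_dataset(easy_config(n=120, seed=8))
    ids = df["id"].tolist()
    labels = random_split(ids, seed=1).labels_for(ids)
    bags = [extract_attributes(s) for s in df["smiles"]]
    table = WeightTable.from_bags(
        {
            lab: [b for b, l in zip(bags, labels) if l == lab]  # noqa: E741
            for lab in ("A", "P", "C")
        },
        threshold=1,
    )
    defects = compute_defects(ids, bags, labels, table)
    flags = [
        in_domain(defects.smiles_defects[i], defects.mean_defect) for i in ids
    ]
    assert np.mean(flags) >= 0.9


def test_las_vegas_trace_contract():
    df = generate_dataset(easy_config(n=80, seed=31))
    ids = df["id"].tolist()
    best, trace = las_vegas(
        ids,
        df["smiles"].tolist(),
        df["endpoint"].to_numpy(),
        n_tests=4,
        probe_epochs=2,
        threshold=1,
        seed=13,
    )
    assert len(trace.rows) == 4
    bests = [r.best_r2_c for r in trace.rows]
    assert all(b >= a for a, b in zip(bests, bests[1:]))
    r2cs = [r.r2_c for r in trace.rows]
    winner = trace.rows[-1].best_test
    assert r2cs[winner - 1] == max(r2cs)
    assert trace.rows[-1].best_r2_c == pytest.approx(max(r2cs))
    sizes = best.sizes()
    assert all(sizes[s] > 0 for s in "APCV")
    with pytest.raises(SplitError):
        las_vegas(ids, df["smiles"].tolist(), df["endpoint"].to_numpy(), n_tests=0)


def test_las_vegas_single_test_returns_that_split():
    df = generate_dataset(easy_config(n=60, seed=32))
    ids = df["id"].tolist()
    best, trace = las_vegas(
        ids,
        df["smiles"].tolist(),
        df["endpoint"].to_numpy(),
        n_tests=1,
        probe_epochs=1,
        threshold=1,
        seed=0,
    )
    assert len(trace.rows) == 1
    assert trace.rows[0].best_test == 1
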