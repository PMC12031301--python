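"""Monte Carlo optimization of correlation weights.

The weights of all non-blocked attributes are tuned by seeded coordinate
search: each epoch visits the attributes in a fresh random order and, for
the visited attribute, evaluates a grid of additive perturbations (integer
multiples of the step ``delta`` up to ``coarse_range``), commits the best
strictly improving one, then refines with a fine step (``delta`` / 5).
Only strictly improving moves are ever accepted.  Two target functions are
supported:

    T1 = RA + RP - |RA - RP| * F1 + (IIC + CII) * F2
    T2 = T1 + CCCP * F3

where RA and RP are the Pearson correlations of the model on the active
and passive training sets, and IIC, CII, CCCP are the correlation-quality
criteria computed on the calibration set.  Defaults F1 = F2 = 0.5 and
F3 = 0.3.  The validation set is never read during optimization.

A criterion that is momentarily undefined (e.g. CCCP with no supporters)
makes the proposed move count as non-improving instead of aborting the
run.  Runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .attributes import AttributeBag, AttributeConfig, extract_attributes
from .errors import (
    ComparabilityError,
    ConfigurationError,
    DegenerateDataError,
    SplitError,
    UndefinedStatisticError,
)
from .model import CLASSIFICATION, REGRESSION, ModelState, WeightTable, fit_regression

T1 = "T1"
T2 = "T2"

#: blocking threshold: minimum occurrences in the active training set for a
#: weight to be tuned.  Rarer attributes have unestimable weights and let the
#: model memorize the training data, so they are excluded from the descriptor.
DEFAULT_THRESHOLD = 5


@dataclass(frozen=True)
class TargetConfig:
    """Target-function settings for the Monte Carlo optimization.

    ``criteria_set`` names the subset on which IIC/CII/CCCP are evaluated
    during optimization (calibration by default — the subset that probes
    the maturing model without having driven the fit).  ``f3`` is ignored
    under variant T1.
    """

    variant: str = T2
    f1: float = 0.5
    f2: float = 0.5
    f3: float = 0.3
    criteria_set: str = "C"

    def __post_init__(self):
        if self.variant not in (T1, T2):
            raise ConfigurationError(f"unknown target variant {self.variant!r}")
        if min(self.f1, self.f2, self.f3) < 0:
            raise ConfigurationError("F1, F2, F3 must be non-negative")


def target_value(
    ra: float,
    rp: float,
    iic: float,
    cii: float,
    cccp: float | None,
    cfg: TargetConfig,
) -> float:
    """Evaluate T1 or T2 from already-computed components."""
    t = ra + rp - abs(ra - rp) * cfg.f1 + (iic + cii) * cfg.f2
    if cfg.variant == T2:
        if cccp is None:
            raise UndefinedStatisticError("T2 requires a CCCP value")
        t += cccp * cfg.f3
    return t


@dataclass
class TraceRow:
    epoch: int
    target: float
    ra: float
    rp: float
    iic: float
    cii: float
    cccp: float
    accepted_moves: int


@dataclass
class OptimizationTrace:
    rows: list[TraceRow] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [asdict(r) for r in self.rows]


class _BatchObjective:
    """Vectorized target evaluation for batches of candidate descriptors.

    Candidate descriptor vectors are the columns of a matrix; every
    statistic (regression fit, subset correlations, IIC, leave-one-out
    influence and its CII/CCCP aggregates) is computed column-wise with
    array operations.  A column whose statistics are undefined (zero
    variance somewhere, one-sided residuals, no supporters when CCCP is
    needed) gets a NaN target, which no comparison treats as improving.
    """

    def __init__(self, y, masks, cfg: TargetConfig, fit_on: str):
        self.cfg = cfg
        self.ia = masks["A"]
        self.ip = masks["P"]
        if cfg.criteria_set not in masks:
            raise ConfigurationError(f"unknown criteria set {cfg.criteria_set!r}")
        self.ic = masks[cfg.criteria_set]
        self.ifit = (
            np.concatenate([masks["A"], masks["P"]]) if fit_on == "AP" else masks["A"]
        )
        self.y = y
        self.ya = y[self.ia]
        self.yp = y[self.ip]
        self.yc = y[self.ic]
        self.yf = y[self.ifit]
        self.needs_cccp = cfg.variant == T2 and cfg.f3 != 0

    @staticmethod
    def _colwise_r(yv: np.ndarray, p: np.ndarray) -> np.ndarray:
        n = yv.size
        sy = yv.sum()
        vy = n * (yv * yv).sum() - sy * sy
        sx = p.sum(axis=0)
        vx = n * (p * p).sum(axis=0) - sx * sx
        num = n * (yv @ p) - sx * sy
        denom2 = vx * vy
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom2 > 0, num / np.sqrt(np.maximum(denom2, 1e-300)), np.nan)
        return r

    def targets(self, d_cols: np.ndarray) -> tuple[np.ndarray, dict]:
        """Target value per column of ``d_cols`` (shape n_molecules x m)."""
        cfg = self.cfg
        df = d_cols[self.ifit]
        nf = df.shape[0]
        mx = df.mean(axis=0)
        sxx = ((df - mx) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c1 = np.where(
                sxx > 0, ((df - mx) * (self.yf - self.yf.mean())[:, None]).sum(axis=0) / sxx, np.nan
            )
        c0 = self.yf.mean() - c1 * mx

        pa = c0 + c1 * d_cols[self.ia]
        pp = c0 + c1 * d_cols[self.ip]
        pc = c0 + c1 * d_cols[self.ic]

        ra = self._colwise_r(self.ya, pa)
        rp = self._colwise_r(self.yp, pp)

        # IIC on the criteria subset
        resid = self.yc[:, None] - pc
        neg = resid < 0
        n_neg = neg.sum(axis=0)
        n_pos = resid.shape[0] - n_neg
        sum_neg = np.where(neg, -resid, 0.0).sum(axis=0)
        sum_pos = np.where(~neg, resid, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mae_neg = sum_neg / n_neg
            mae_pos = sum_pos / n_pos
            hi = np.maximum(mae_neg, mae_pos)
            lo = np.minimum(mae_neg, mae_pos)
            ratio = np.where(hi > 0, lo / hi, 1.0)
        rc = self._colwise_r(self.yc, pc)
        iic = np.where((n_neg > 0) & (n_pos > 0), rc * ratio, np.nan)
        # exact fit: zero residuals on both sides -> IIC = r by convention
        exact = (sum_neg + sum_pos) == 0
        iic = np.where(exact, rc, iic)

        # leave-one-out influence of each calibration point on r
        yv = self.yc
        nc = yv.size
        sy, syy = yv.sum(), (yv * yv).sum()
        sx = pc.sum(axis=0)
        sxx = (pc * pc).sum(axis=0)
        sxy = yv @ pc
        m = nc - 1
        vx = m * (sxx - pc * pc) - (sx - pc) ** 2
        vy = m * (syy - yv[:, None] ** 2) - (sy - yv[:, None]) ** 2
        num = m * (sxy - yv[:, None] * pc) - (sx - pc) * (sy - yv[:, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            r_loo = np.where((vx > 0) & (vy > 0), num / np.sqrt(np.maximum(vx * vy, 1e-300)), np.nan)
        delta = r_loo - rc
        opp = np.where(delta > 0, delta, 0.0).sum(axis=0)
        sup = np.where(delta < 0, -delta, 0.0).sum(axis=0)
        cii = 1.0 - opp
        with np.errstate(invalid="ignore", divide="ignore"):
            cccp = np.where(sup > 0, 1.0 - opp / sup, np.nan)

        with np.errstate(invalid="ignore"):
            t = ra + rp - np.abs(ra - rp) * cfg.f1 + (iic + cii) * cfg.f2
            if self.needs_cccp:
                t = t + cccp * cfg.f3
        comps = {"ra": ra, "rp": rp, "iic": iic, "cii": cii, "cccp": cccp,
                 "c0": c0, "c1": c1}
        return t, comps


def _prepare(
    smiles: Sequence[str],
    endpoints: Sequence[float],
    labels: Sequence[str],
    attr_config: AttributeConfig,
    threshold: int,
):
    if len(smiles) != len(endpoints) or len(smiles) != len(labels):
        raise SplitError("smiles, endpoints and labels must align")
    for subset in ("A", "P", "C"):
        if subset not in labels:
            raise SplitError(f"subset {subset!r} is empty")
    bags = [extract_attributes(s, attr_config) for s in smiles]
    by_subset: dict[str, list[AttributeBag]] = {"A": [], "P": [], "C": []}
    for bag, lab in zip(bags, labels):
        if lab in by_subset:
            by_subset[lab].append(bag)
    table = WeightTable.from_bags(by_subset, threshold=threshold)
    active = table.active_keys()
    if not active:
        raise DegenerateDataError("every attribute is blocked")
    col = {k: j for j, k in enumerate(active)}
    x = np.zeros((len(smiles), len(active)))
    for i, bag in enumerate(bags):
        for key, c in bag.keys.items():
            j = col.get(key)
            if j is not None:
                x[i, j] = c
    masks = {
        s: np.asarray([i for i, lab in enumerate(labels) if lab == s], dtype=int)
        for s in ("A", "P", "C", "V")
    }
    # Validation endpoints are invisible to the optimizer: the objective is
    # built from a copy with the V entries zeroed out.
    y = np.asarray(endpoints, dtype=float).copy()
    if masks["V"].size:
        y[masks["V"]] = 0.0
    return bags, table, active, x, masks, y


def optimize(
    smiles: Sequence[str],
    endpoints: Sequence[float],
    labels: Sequence[str],
    *,
    target: TargetConfig | None = None,
    epochs: int = 30,
    threshold: int = DEFAULT_THRESHOLD,
    seed: int = 0,
    attr_config: AttributeConfig | None = None,
    task: str = REGRESSION,
    delta: float = 0.1,
    coarse_range: int = 10,
    fit_on: str = "AP",
    max_line_steps: int = 60,
) -> tuple[ModelState, OptimizationTrace]:
    """Tune correlation weights by seeded Monte Carlo coordinate search.

    Parameters
    ----------
    smiles, endpoints, labels
        Aligned per-molecule inputs; ``labels`` assigns each molecule to
        A (active training), P (passive training), C (calibration) or
        V (validation).  Validation endpoints are never read.
    target
        Target-function settings (variant, F1-F3, criteria subset).
    epochs
        Full passes over the non-blocked attributes; 0 returns the
        initialized weights untouched.
    threshold
        Minimum active-training occurrence count for an attribute to stay
        non-blocked (default 5; see the weight table's blocking contract).
    delta, coarse_range
        Proposal geometry: the visit evaluates steps ``k * delta`` for
        k in -coarse_range..coarse_range, commits the best strictly
        improving one, then refines with steps of ``delta / 5``.
    fit_on
        Which molecules the regression coefficients are fit on: "AP"
        (default, active plus passive training) or "A".

    Returns the trained :class:`ModelState` and a per-epoch trace.  Fully
    deterministic for a fixed seed.
    """
    cfg = target or TargetConfig()
    acfg = attr_config or AttributeConfig()
    if fit_on not in ("AP", "A"):
        raise ConfigurationError("fit_on must be 'AP' or 'A'")
    if epochs < 0:
        raise ConfigurationError("epochs must be >= 0")
    bags, table, active, x, masks, y = _prepare(
        smiles, endpoints, labels, acfg, threshold
    )
    obj = _BatchObjective(y, masks, cfg, fit_on)

    rng = np.random.default_rng(seed)
    n_attr = len(active)
    w = 1.0 + rng.uniform(-0.1, 0.1, size=n_attr)
    d = x @ w

    def single(dv):
        t, comps = obj.targets(dv[:, None])
        return float(t[0]), {k: float(v[0]) for k, v in comps.items()}

    current, comps = single(d)
    if math.isnan(current):
        current = -math.inf

    steps = delta * np.concatenate(
        [np.arange(-coarse_range, 0), np.arange(1, coarse_range + 1)]
    )
    fine = delta / 5.0

    trace = OptimizationTrace()
    for epoch in range(epochs):
        accepted = 0
        order = rng.permutation(n_attr)
        for j in order:
            xj = x[:, j]
            cand = d[:, None] + xj[:, None] * steps[None, :]
            t_cand, _ = obj.targets(cand)
            with np.errstate(invalid="ignore"):
                improving = t_cand > current
            if improving.any():
                k = int(np.nanargmax(np.where(improving, t_cand, -np.inf)))
                w[j] += steps[k]
                d = cand[:, k].copy()
                current = float(t_cand[k])
                accepted += 1
            # fine refinement around the (possibly unchanged) point
            for sgn in (fine, -fine):
                moved = False
                for _ in range(max_line_steps):
                    t_new, _ = obj.targets((d + sgn * xj)[:, None])
                    t_new = float(t_new[0])
                    if t_new > current:
                        w[j] += sgn
                        d = d + sgn * xj
                        current = t_new
                        accepted += 1
                        moved = True
                    else:
                        break
                if moved:
                    break
        current, comps = single(d)
        if math.isnan(current):
            current = -math.inf
        trace.rows.append(
            TraceRow(
                epoch,
                current,
                comps["ra"],
                comps["rp"],
                comps["iic"],
                comps["cii"],
                comps["cccp"],
                accepted,
            )
        )

    for key, wj in zip(active, w):
        table.weights[key] = float(wj)
    ifit = obj.ifit
    c0, c1 = fit_regression(d[ifit], y[ifit])
    state = ModelState(
        weight_table=table,
        c0=c0,
        c1=c1,
        task=task if task in (REGRESSION, CLASSIFICATION) else REGRESSION,
        config={
            "target": asdict(cfg),
            "epochs": epochs,
            "threshold": threshold,
            "delta": delta,
            "coarse_range": coarse_range,
            "fit_on": fit_on,
            "attr_config": asdict(acfg),
            "split_fingerprint": _split_fingerprint(labels),
        },
        seed=seed,
    )
    return state, trace


def _split_fingerprint(labels: Iterable[str]) -> str:
    h = hashlib.sha256(",".join(labels).encode()).hexdigest()
    return h[:16]


def extract_promoters(
    runs: Sequence[ModelState],
) -> list[tuple[str, list[float]]]:
    """Attributes with a strictly positive weight in every run.

    Runs must share the split and configuration (only the seed may
    differ); these consistently positive attributes are interpreted as
    promoters of endpoint increase.
    """
    if len(runs) < 2:
        raise ComparabilityError("promoter extraction needs at least two runs")
    ref = dict(runs[0].config)
    for run in runs[1:]:
        if dict(run.config) != ref:
            raise ComparabilityError("runs differ in split or configuration")
    common = set(runs[0].weight_table.weights)
    for run in runs[1:]:
        common &= set(run.weight_table.weights)
    out: list[tuple[str, list[float]]] = []
    for key in sorted(common):
        if any(key in run.weight_table.blocked for run in runs):
            continue
        cws = [run.weight_table.weights[key] for run in runs]
        if all(cw > 0 for cw in cws):
            out.append((key, cws))
    return out
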