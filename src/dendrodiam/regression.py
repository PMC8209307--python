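"""Fitting and evaluating node-class-specific diameter models.

The statistical core: Pearson's coefficient of determination, ordinary least
squares through the origin with the uncentered adjusted R-squared, stepwise
pair selection with an improvement constant, train/test model fitting over a
morphology archive, prediction scoring, the Rall 3/2 branch-point check, and
the diameter autocorrelation with its double-exponential decay fit.

Conventions
-----------
* No model carries an intercept.  R^2 is therefore uncentered,
  ``R2 = 1 - SSR / sum(y^2)``, and the adjusted version is
  ``1 - (1 - R2) * n / (n - p)`` — the standard regression-through-origin
  convention.
* Feature selection considers singles first, then pairs in descending order
  of single adjusted R^2; a pair wins only if it beats both of its singles by
  at least the improvement constant (default 0.001) and the best model so far.
* Autocorrelation lags are counted in *nodes* along parent chains, so the
  fitted space constants are in node-separation units.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import morphometry
from .morphometry import FEATURE_NAMES, NodeClass, feature_table
from .models import DiameterModel, ModelSet
from .swc import Morphology, SWCStructureError

__all__ = [
    "UndefinedStatisticError",
    "SingularMatrixError",
    "OLSResult",
    "AutocorrFit",
    "pearson_r2",
    "ols_no_intercept",
    "select_features",
    "fit_model_set",
    "train_test_split",
    "evaluate_prediction",
    "mean_prediction_r2",
    "rall_check",
    "pd_equality_fraction",
    "diameter_autocorrelation",
]


class UndefinedStatisticError(ValueError):
    """A correlation requested on a zero-variance vector."""


class SingularMatrixError(ValueError):
    """Rank-deficient design matrix; names the offending columns."""


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in x or y")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


@dataclass(frozen=True)
class OLSResult:
    coefficients: tuple[float, ...]
    features: tuple[str, ...]
    r2: float
    adj_r2: float
    n: int

    @property
    def p(self) -> int:
        return len(self.coefficients)


def ols_no_intercept(X, y, feature_names=None) -> OLSResult:
    """Least squares through the origin with uncentered (adjusted) R^2.

    Negative adjusted R^2 is reported as-is, never clipped.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(p))
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [feature_names[i] for i in range(p)
               if diag[i] <= diag.max() * 1e-10]
        raise SingularMatrixError(
            f"design matrix rank {rank} < {p}; offending columns: {bad or list(feature_names)}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    ssr = float(np.sum((y - X @ beta) ** 2))
    sst = float(np.sum(y**2))
    if sst == 0:
        raise UndefinedStatisticError("response is identically zero")
    r2 = 1.0 - ssr / sst
    adj = 1.0 - (1.0 - r2) * n / (n - p)
    return OLSResult(tuple(float(b) for b in beta), tuple(feature_names), r2, adj, n)


@dataclass
class SelectionResult:
    features: tuple[str, ...]
    adj_r2: float
    single_scores: dict = field(default_factory=dict)
    pair_scores: dict = field(default_factory=dict)


def _class_rows(table: pd.DataFrame, node_class, tree_label) -> pd.DataFrame:
    node_class = NodeClass(node_class).value
    rows = table[table["node_class"] == node_class]
    if tree_label is not None:
        rows = rows[rows["tree_label"] == tree_label]
    return rows


def select_features(
    table: pd.DataFrame,
    node_class,
    tree_label=None,
    improvement: float = 0.001,
    candidates=FEATURE_NAMES,
) -> SelectionResult:
    """Stepwise single-then-pair feature selection by adjusted R^2.

    1. Score each candidate alone against D and rank them.
    2. Walk features in descending single score, pairing each with every
       other candidate.
    3. A pair is retained only if its adjusted R^2 exceeds *both* of its
       singles by at least ``improvement`` and exceeds the best model seen
       so far (including the best single).  Otherwise the best single wins.

    The result is invariant to row order and candidate order (ties broken
    alphabetically).
    """
    rows = _class_rows(table, node_class, tree_label)
    if rows.empty:
        raise UndefinedStatisticError(
            f"no rows for class {node_class} / label {tree_label}"
        )
    y = rows["D"].to_numpy(float)
    singles: dict[str, float] = {}
    for f in candidates:
        x = rows[f].to_numpy(float)
        if np.ptp(x) == 0 and np.all(x == 0):
            continue  # feature absent for this class (e.g. LP at terminals)
        try:
            singles[f] = ols_no_intercept(x, y, (f,)).adj_r2
        except (SingularMatrixError, ValueError):
            continue
    if not singles:
        raise UndefinedStatisticError("no usable candidate features")

    ranked = sorted(singles, key=lambda f: (-singles[f], f))
    best_feats: tuple[str, ...] = (ranked[0],)
    best_adj = singles[ranked[0]]
    pairs: dict[tuple[str, str], float] = {}
    for f in ranked:
        for g in ranked:
            if g == f or (g, f) in pairs or (f, g) in pairs:
                continue
            X = rows[[f, g]].to_numpy(float)
            try:
                adj = ols_no_intercept(X, y, (f, g)).adj_r2
            except SingularMatrixError:
                continue
            pairs[(f, g)] = adj
            qualifies = (
                adj >= singles[f] + improvement
                and adj >= singles[g] + improvement
                and adj > best_adj  # must also beat the best model so far
            )
            if qualifies:
                best_feats = tuple(sorted((f, g)))
                best_adj = adj
    return SelectionResult(best_feats, best_adj, singles, pairs)


def train_test_split(morphologies, fraction: float = 0.5, seed: int | None = None):
    """Uniform random per-archive split of morphologies into (train, test)."""
    rng = np.random.default_rng(seed)
    ms = list(morphologies)
    idx = rng.permutation(len(ms))
    n_train = max(1, int(round(fraction * len(ms))))
    n_train = min(n_train, len(ms) - 1) if len(ms) > 1 else n_train
    train = [ms[i] for i in idx[:n_train]]
    test = [ms[i] for i in idx[n_train:]]
    return train, test


def fit_model_set(
    train,
    cell_type: str = "",
    improvement: float = 0.001,
    seed: int | None = None,
    candidates=FEATURE_NAMES,
    name: str | None = None,
) -> ModelSet:
    """Fit one diameter model per (node class x dendrite label) on pooled
    training nodes: stepwise feature selection followed by OLS through the
    origin.  A class with too few nodes falls back to {PD} when possible and
    is skipped (with a warning) otherwise."""
    train = list(train)
    if len(train) < 2:
        raise ValueError("need at least 2 training morphologies")
    table = feature_table(train)
    ms = ModelSet(
        name=name or f"fitted-{cell_type or 'archive'}",
        cell_type=cell_type,
        provenance={
            "train_ids": [m.metadata.get("name", m.metadata.get("source", "?"))
                          for m in train],
            "seed": seed,
            "improvement": improvement,
        },
    )
    for label in sorted(table["tree_label"].unique()):
        for node_class in NodeClass:
            rows = _class_rows(table, node_class, label)
            y = rows["D"].to_numpy(float)
            if len(rows) < 4:  # p + 2 with p <= 2
                if len(rows) >= 3 and np.ptp(rows["PD"].to_numpy(float)) >= 0:
                    _warnings.warn(
                        f"{label}/{node_class.value}: only {len(rows)} nodes; "
                        "falling back to a PD-only fit"
                    )
                    res = ols_no_intercept(rows["PD"].to_numpy(float), y, ("PD",))
                    ms.add(DiameterModel(node_class, label, ("PD",),
                                         res.coefficients, res.adj_r2, res.n))
                else:
                    _warnings.warn(
                        f"{label}/{node_class.value}: too few nodes, model skipped"
                    )
                continue
            sel = select_features(table, node_class, label, improvement, candidates)
            X = rows[list(sel.features)].to_numpy(float)
            res = ols_no_intercept(X, y, sel.features)
            ms.add(DiameterModel(node_class, label, sel.features,
                                 res.coefficients, res.adj_r2, res.n))
    return ms


def evaluate_prediction(orig: Morphology, pred: Morphology) -> dict:
    """Per-dendrite-label R^2 between original and predicted diameters.

    Requires identical topology.  Pearson R^2 is scale-free: a uniformly
    rescaled prediction still scores 1.0.  Returns label -> R^2 plus 'all'.
    """
    if len(orig) != len(pred):
        raise SWCStructureError("morphologies differ in node count")
    o_feats = morphometry.compute_features(orig)
    for nid in o_feats:
        if nid not in pred:
            raise SWCStructureError(f"node {nid} missing from prediction")
        if orig.node(nid).parent_id != pred.node(nid).parent_id:
            raise SWCStructureError(f"topology differs at node {nid}")
    by_label: dict[str, tuple[list, list]] = {}
    all_o, all_p = [], []
    for nid, f in o_feats.items():
        d_o, d_p = orig.node(nid).diameter, pred.node(nid).diameter
        by_label.setdefault(f.tree_label, ([], []))
        by_label[f.tree_label][0].append(d_o)
        by_label[f.tree_label][1].append(d_p)
        all_o.append(d_o)
        all_p.append(d_p)
    out = {}
    for label, (xo, xp) in by_label.items():
        try:
            out[label] = pearson_r2(xo, xp)
        except (UndefinedStatisticError, ValueError):
            out[label] = float("nan")
    try:
        out["all"] = pearson_r2(all_o, all_p)
    except (UndefinedStatisticError, ValueError):
        out["all"] = float("nan")
    return out


def mean_prediction_r2(pairs, label: str = "all") -> float:
    """Mean per-morphology R^2 across (original, predicted) pairs."""
    scores = []
    for orig, pred in pairs:
        r2 = evaluate_prediction(orig, pred).get(label, float("nan"))
        if np.isfinite(r2):
            scores.append(r2)
    if not scores:
        raise UndefinedStatisticError("no finite per-morphology R^2 values")
    return float(np.mean(scores))


def rall_check(morphologies) -> dict:
    """Branch-point 3/2-power-rule correlations, per dendrite label.

    ``sum_rule_r2``: R^2 between parent D^1.5 and the *sum* of child D^1.5 at
    each branch point.  ``per_child_r2``: the rejected variant, individual
    branching-child D against parent D^1.5.
    """
    sums: dict[str, tuple[list, list]] = {}
    per_child: dict[str, tuple[list, list]] = {}
    for m in morphologies:
        for n in m.dendritic_nodes():
            kids = m.dendritic_children(n.node_id)
            if len(kids) < 2:
                continue
            label = morphometry.tree_label(n)
            x = n.diameter**1.5
            sums.setdefault(label, ([], []))
            sums[label][0].append(x)
            sums[label][1].append(sum(k.diameter**1.5 for k in kids))
            per_child.setdefault(label, ([], []))
            for k in kids:
                per_child[label][0].append(x)
                per_child[label][1].append(k.diameter)
    out: dict[str, dict[str, float]] = {"sum_rule_r2": {}, "per_child_r2": {}}
    for label, (x, y) in sums.items():
        if len(x) >= 3:
            out["sum_rule_r2"][label] = pearson_r2(x, y)
    for label, (x, y) in per_child.items():
        if len(x) >= 3:
            out["per_child_r2"][label] = pearson_r2(x, y)
    return out


def pd_equality_fraction(
    table: pd.DataFrame, node_class=NodeClass.CONTINUING, tol: float = 1e-6
) -> float:
    """Fraction of nodes of a class whose diameter equals their parent's.

    ``tol`` is in micrometres; the default treats file-precision values as
    exact."""
    rows = _class_rows(table, node_class, None)
    if rows.empty:
        return float("nan")
    d = rows["D"].to_numpy(float)
    pd_ = rows["PD"].to_numpy(float)
    return float(np.mean(np.abs(d - pd_) <= tol))


@dataclass
class AutocorrFit:
    lags: np.ndarray          # node-separation counts, 0..max_lag
    acf: np.ndarray           # averaged autocorrelation, acf[0] == 1
    A1: float
    lambda1: float            # smaller space constant, node units
    A2: float
    lambda2: float            # larger space constant, node units
    per_morphology: list = field(default_factory=list)


def _morphology_diameter_acf(m: Morphology, max_lag: int) -> np.ndarray:
    """Correlation of dendritic diameters with their k-step ancestors."""
    feats_nodes = m.dendritic_nodes()
    acf = np.full(max_lag + 1, np.nan)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        xs, ys = [], []
        for n in feats_nodes:
            anc = n
            ok = True
            for _ in range(k):
                anc = m.parent(anc)
                if anc is None or not m.is_dendritic(anc):
                    ok = False
                    break
            if ok:
                xs.append(n.diameter)
                ys.append(anc.diameter)
        if len(xs) >= 3 and np.ptp(xs) > 0 and np.ptp(ys) > 0:
            acf[k] = stats.pearsonr(xs, ys).statistic
    return acf


def _double_exp(k, a1, lam1, a2, lam2):
    return a1 * np.exp(-k / lam1) + a2 * np.exp(-k / lam2)


def diameter_autocorrelation(morphologies, max_lag: int = 20) -> AutocorrFit:
    """Average the per-morphology diameter autocorrelation along parent
    chains and fit a double-exponential decay, A1 e^{-k/l1} + A2 e^{-k/l2}.

    Lags are node counts.  Returns space constants ordered lambda1 <= lambda2,
    amplitudes constrained nonnegative, initialization from a log-linear
    single-exponential fit.  Constant-diameter archives raise
    :class:`UndefinedStatisticError` (autocorrelation undefined), and a lag
    range no morphology can support is shrunk with a warning.
    """
    per = []
    for m in morphologies:
        per.append(_morphology_diameter_acf(m, max_lag))
    per_arr = np.array(per)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_acf = np.nanmean(per_arr, axis=0)
    valid = np.isfinite(mean_acf)
    if not valid[1:].any():
        raise UndefinedStatisticError(
            "diameter autocorrelation undefined (constant diameters or "
            "paths shorter than lag 1)"
        )
    last = int(np.max(np.nonzero(valid)))
    if last < max_lag:
        _warnings.warn(
            f"paths support lags only up to {last}; shrinking lag range"
        )
    lags = np.arange(last + 1)
    acf = mean_acf[: last + 1]
    good = np.isfinite(acf)
    k, a = lags[good].astype(float), acf[good]

    # log-linear initialization on the positive part
    pos = a > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(k[pos], np.log(a[pos]), 1)
        lam0 = -1.0 / slope if slope < 0 else float(max_lag)
    else:
        lam0 = 1.0
    lam0 = float(np.clip(lam0, 0.1, 10 * max(1, last)))
    p0 = [0.5, max(0.1, lam0 / 3), 0.5, lam0]
    bounds = ([0, 1e-3, 0, 1e-3], [np.inf] * 4)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        popt, _ = optimize.curve_fit(
            _double_exp, k, a, p0=p0, bounds=bounds, maxfev=20000,
            xtol=1e-8, ftol=1e-8,
        )
    a1, lam1, a2, lam2 = popt
    if lam1 > lam2:
        a1, lam1, a2, lam2 = a2, lam2, a1, lam1
    return AutocorrFit(lags, acf, float(a1), float(lam1), float(a2),
                       float(lam2), per)
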