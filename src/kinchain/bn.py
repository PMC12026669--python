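"""Discrete Bayesian-network classification of IBS profiles.

The classifier discretizes the continuous IBS scores into equal-frequency
bins and models the joint distribution of the discretized scores given the
kinship-chain label with a small directed network: the class is a root, every
score is a child of the class, and the empirically dependent score pairs
(A-IBS→A-IBS0 and X-IBS→X-IBS0) carry an extra edge.  Conditional
probability tables use add-one smoothing; the class prior is uniform because
simulated classes are balanced.

The observed sexes of the two individuals (``sexes`` ∈ {MM, MF, FF}) enter
as an ordinary observed node: in casework the sexes of the compared persons
are known, and only chains compatible with them should receive posterior
mass.  A missing Y score (any pair that is not male–male) is a dedicated
"inapplicable" category, not an imputed value.

Structure learning (``structure_mode="learned"``) greedily adds score→score
edges by BIC on top of the forced class→score edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .ibs import SCORE_COLUMNS

#: default feature set: observed pair sexes plus the six IBS scores
DEFAULT_FEATURES = ["sexes"] + SCORE_COLUMNS

#: categorical feature domains (everything else is equal-frequency binned)
_CATEGORICAL = {"sexes": ["FF", "FM", "MM"], "m_ibs": [0, 1]}

#: score pairs with known intra-marker dependence (parent -> child)
FIXED_EXTRA_EDGES = [("a_ibs", "a_ibs0"), ("x_ibs", "x_ibs0")]


def default_n_bins(n: int) -> int:
    """Equal-frequency bin count: max(2, ⌊n^(1/3)⌋) for n training rows."""
    return max(2, int(np.floor(np.cbrt(n))))


@dataclass
class DiscretizationModel:
    """Maps raw feature columns to integer category codes."""

    features: list[str]
    edges: dict[str, np.ndarray] = field(default_factory=dict)
    categories: dict[str, list] = field(default_factory=dict)
    n_categories: dict[str, int] = field(default_factory=dict)
    missing_code: dict[str, int] = field(default_factory=dict)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """(n, n_features) int codes; out-of-range values clamp to edge bins."""
        cols = []
        for f in self.features:
            v = table[f]
            if f in self.categories:
                cats = self.categories[f]
                codes = pd.Categorical(v, categories=cats).codes.astype(int)
                codes = np.where(codes < 0, 0, codes)
            else:
                codes = np.searchsorted(self.edges[f], v.to_numpy(float),
                                        side="right")
                if f in self.missing_code:
                    codes = np.where(np.isnan(v.to_numpy(float)),
                                     self.missing_code[f], codes)
            cols.append(codes)
        return np.column_stack(cols)


def fit_discretizer(table: pd.DataFrame, features: list[str] | None = None,
                    n_bins: int | None = None) -> DiscretizationModel:
    """Equal-frequency discretization of the continuous scores.

    ``n_bins`` defaults to max(2, ⌊n^(1/3)⌋).  Categorical columns (sexes,
    m_ibs) pass through; a missing-capable column (y_ibs) gets one extra
    "inapplicable" category for NaN.
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    features = list(features) if features is not None else [
        f for f in DEFAULT_FEATURES if f in table.columns]
    B = n_bins if n_bins is not None else default_n_bins(len(table))
    model = DiscretizationModel(features)
    for f in features:
        if f in _CATEGORICAL:
            model.categories[f] = list(_CATEGORICAL[f])
            model.n_categories[f] = len(_CATEGORICAL[f])
            continue
        v = table[f].to_numpy(float)
        obs = v[~np.isnan(v)]
        if len(obs) == 0:
            edges = np.array([])
        else:
            q = np.quantile(obs, np.arange(1, B) / B)
            edges = np.unique(q)
            # interior edges only: values above the last edge fall in the
            # top bin, so drop edges equal to the maximum
            edges = edges[edges < obs.max()]
        # an all-missing column is simply the inapplicable category; only a
        # constant observed score deserves a warning
        if len(obs) > 0 and len(edges) == 0 and len(np.unique(obs)) == 1:
            warnings.warn(f"score column {f!r} is constant; single category",
                          stacklevel=2)
        model.edges[f] = edges
        n_cat = len(edges) + 1
        if np.isnan(v).any() or f == "y_ibs":
            model.missing_code[f] = n_cat
            n_cat += 1
        model.n_categories[f] = n_cat
    return model


@dataclass
class BNModel:
    """A fitted Bayesian-network classifier over discretized IBS scores."""

    classes: list
    features: list[str]
    disc: DiscretizationModel
    parent: dict[str, str | None]          # extra (non-class) parent
    log_cpts: dict[str, np.ndarray]        # (C, K) or (C, Kp, K)
    log_prior: np.ndarray

    def predict_log_proba(self, table: pd.DataFrame) -> np.ndarray:
        codes = self.disc.transform(table)
        col = {f: i for i, f in enumerate(self.features)}
        ll = np.tile(self.log_prior[None, :], (len(table), 1))
        for f in self.features:
            cpt = self.log_cpts[f]
            cf = codes[:, col[f]]
            p = self.parent[f]
            if p is None:
                ll += cpt[:, cf].T
            else:
                ll += cpt[:, codes[:, col[p]], cf].T
        return ll

    def predict_proba(self, table: pd.DataFrame) -> pd.DataFrame:
        ll = self.predict_log_proba(table)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, columns=self.classes, index=table.index)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Argmax labels; ties break to the lexicographically first class."""
        ll = self.predict_log_proba(table)
        return np.asarray(self.classes, dtype=object)[ll.argmax(axis=1)]


def _count_cpts(codes: np.ndarray, y: np.ndarray, classes: list,
                features: list[str], parent: dict[str, str | None],
                n_cat: dict[str, int]) -> dict[str, np.ndarray]:
    col = {f: i for i, f in enumerate(features)}
    C = len(classes)
    out = {}
    for f in features:
        K = n_cat[f]
        p = parent[f]
        if p is None:
            counts = np.ones((C, K))
            np.add.at(counts, (y, codes[:, col[f]]), 1)
        else:
            counts = np.ones((C, n_cat[p], K))
            np.add.at(counts, (y, codes[:, col[p]], codes[:, col[f]]), 1)
        out[f] = np.log(counts / counts.sum(axis=-1, keepdims=True))
    return out


def _loglik(codes, y, features, parent, log_cpts) -> float:
    col = {f: i for i, f in enumerate(features)}
    total = 0.0
    for f in features:
        p = parent[f]
        if p is None:
            total += log_cpts[f][y, codes[:, col[f]]].sum()
        else:
            total += log_cpts[f][y, codes[:, col[p]], codes[:, col[f]]].sum()
    return float(total)


def fit_bn(table: pd.DataFrame, labels, structure_mode: str = "fixed",
           features: list[str] | None = None,
           disc: DiscretizationModel | None = None) -> BNModel:
    """Fit the classifier.

    ``fixed`` (default) uses class→score edges plus the A-IBS→A-IBS0 and
    X-IBS→X-IBS0 dependencies; ``learned`` hill-climbs score→score edges
    (at most one extra parent per score) by BIC.
    """
    y_raw = np.asarray(labels)
    if len(y_raw) != len(table):
        raise ValueError("labels must match the score table length")
    classes = sorted(pd.unique(y_raw))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if disc is None:
        disc = fit_discretizer(table, features)
    features = disc.features
    class_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_idx[c] for c in y_raw])
    codes = disc.transform(table)
    n_cat = disc.n_categories

    parent: dict[str, str | None] = {f: None for f in features}
    if structure_mode == "fixed":
        for p, f in FIXED_EXTRA_EDGES:
            if p in features and f in features:
                parent[f] = p
    elif structure_mode == "learned":
        n = len(table)
        scores = [f for f in features if f != "sexes"]

        def bic(par):
            cpts = _count_cpts(codes, y, classes, features, par, n_cat)
            k = sum(len(classes) * (n_cat[par[f]] if par[f] else 1)
                    * (n_cat[f] - 1) for f in features)
            return _loglik(codes, y, features, par, cpts) \
                - 0.5 * np.log(n) * k

        best = bic(parent)
        improved = True
        while improved:
            improved = False
            for f in scores:
                if parent[f] is not None:
                    continue
                for p in scores:
                    if p == f or _would_cycle(parent, p, f):
                        continue
                    trial = dict(parent)
                    trial[f] = p
                    s = bic(trial)
                    if s > best + 1e-9:
                        best, parent, improved = s, trial, True
    else:
        raise ValueError(f"unknown structure_mode {structure_mode!r}")

    log_cpts = _count_cpts(codes, y, classes, features, parent, n_cat)
    log_prior = np.full(len(classes), -np.log(len(classes)))
    return BNModel(classes, features, disc, parent, log_cpts, log_prior)


def _would_cycle(parent: dict[str, str | None], p: str, f: str) -> bool:
    cur = p
    while cur is not None:
        if cur == f:
            return True
        cur = parent.get(cur)
    return False


def predict(model: BNModel, profiles: pd.DataFrame) -> pd.DataFrame:
    """Posterior distribution over class labels for each profile row."""
    return model.predict_proba(profiles)


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class CVResult:
    accuracy: float
    top2_accuracy: float
    per_class: pd.Series
    confusion: pd.DataFrame
    fold_accuracies: list[float]


def cross_validate(table: pd.DataFrame, labels, k: int = 5, seed: int = 0,
                   features: list[str] | None = None,
                   structure_mode: str = "fixed",
                   n_bins: int | None = None) -> CVResult:
    """Stratified k-fold cross-validation, refitting the discretizer and the
    network on each training split."""
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ValueError(f"classes smaller than k={k}: {small}")
    classes = sorted(counts.index)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=object)
    top2_hit = np.zeros(len(y), dtype=bool)
    fold_acc = []
    for train, test in skf.split(np.zeros(len(y)), y):
        tr = table.iloc[train]
        disc = fit_discretizer(tr, features, n_bins=n_bins)
        model = fit_bn(tr, y[train], structure_mode, disc=disc)
        ll = model.predict_log_proba(table.iloc[test])
        pred = np.asarray(model.classes, dtype=object)[ll.argmax(axis=1)]
        y_pred[test] = pred
        order = np.argsort(-ll, axis=1)[:, :2]
        cls_arr = np.asarray(model.classes, dtype=object)
        top2_hit[test] = (cls_arr[order] == y[test, None]).any(axis=1)
        fold_acc.append(float((pred == y[test]).mean()))
    acc = float((y_pred == y).mean())
    per_class = pd.Series({c: float((y_pred[y == c] == c).mean())
                           for c in classes}, name="accuracy")
    confusion = pd.crosstab(pd.Series(y, name="true"),
                            pd.Series(y_pred, name="predicted"))
    confusion = confusion.reindex(index=classes, columns=classes,
                                  fill_value=0)
    return CVResult(acc, float(top2_hit.mean()), per_class, confusion,
                    fold_acc)


#: marker-set ladder used in the ablation experiments
MARKER_SETS = {
    "A": ["a_ibs", "a_ibs0"],
    "A+X": ["a_ibs", "a_ibs0", "x_ibs", "x_ibs0"],
    "A+X+Y": ["a_ibs", "a_ibs0", "x_ibs", "x_ibs0", "y_ibs"],
    "A+X+Y+M": ["a_ibs", "a_ibs0", "x_ibs", "x_ibs0", "y_ibs", "m_ibs"],
}


def features_for_markers(markers: list[str] | str,
                         include_sexes: bool = True) -> list[str]:
    """Feature columns for a marker-set name ("A+X+Y+M") or list of marker
    letters; the observed sex pair is always available to the classifier."""
    if isinstance(markers, str):
        key = markers
    else:
        key = "+".join(markers)
    if key not in MARKER_SETS:
        raise ValueError(f"unknown marker set {key!r}; "
                         f"choose from {list(MARKER_SETS)}")
    feats = list(MARKER_SETS[key])
    return (["sexes"] + feats) if include_sexes else feats


def marker_ablation(table: pd.DataFrame, labels,
                    marker_sets: list[str] | None = None, k: int = 5,
                    seed: int = 0) -> pd.DataFrame:
    """Cross-validated accuracy for a nested ladder of marker sets."""
    if marker_sets is None:
        marker_sets = list(MARKER_SETS)
    if not marker_sets:
        raise ValueError("empty marker-set list")
    rows = []
    for ms in marker_sets:
        res = cross_validate(table, labels, k=k, seed=seed,
                             features=features_for_markers(ms))
        rows.append({"marker_set": ms, "accuracy": res.accuracy,
                     "top2_accuracy": res.top2_accuracy})
    return pd.DataFrame(rows)


def related_vs_unrelated(table: pd.DataFrame, related_kc: str,
                         markers: str = "A+X+Y+M", k: int = 5,
                         seed: int = 0) -> CVResult:
    """Binary task: one related chain against its sex-matched unrelated
    chain, as simulated rows of the score table."""
    from .kc import parse_kc, sex_matched_unrelated
    chain = parse_kc(related_kc)
    un = sex_matched_unrelated(chain)
    sub = table[table["kc"].isin([str(chain), un])]
    labels = np.where(sub["kc"] == un, "UN", "REL")
    return cross_validate(sub, labels, k=k, seed=seed,
                          features=features_for_markers(markers))


# ---------------------------------------------------------------------------
# persistence

def save_model(model: BNModel, path: str) -> None:
    """Persist a fitted classifier (bins, structure, CPTs) as JSON."""
    import json
    doc = {
        "classes": list(model.classes),
        "features": model.features,
        "parent": model.parent,
        "log_prior": model.log_prior.tolist(),
        "log_cpts": {f: c.tolist() for f, c in model.log_cpts.items()},
        "discretizer": {
            "features": model.disc.features,
            "edges": {f: e.tolist() for f, e in model.disc.edges.items()},
            "categories": model.disc.categories,
            "n_categories": model.disc.n_categories,
            "missing_code": model.disc.missing_code,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> BNModel:
    import json
    with open(path) as fh:
        doc = json.load(fh)
    d = doc["discretizer"]
    disc = DiscretizationModel(
        features=d["features"],
        edges={f: np.asarray(e) for f, e in d["edges"].items()},
        categories=d["categories"],
        n_categories=d["n_categories"],
        missing_code=d["missing_code"],
    )
    return BNModel(
        classes=doc["classes"], features=doc["features"], disc=disc,
        parent=doc["parent"],
        log_cpts={f: np.asarray(c) for f, c in doc["log_cpts"].items()},
        log_prior=np.asarray(doc["log_prior"]))
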