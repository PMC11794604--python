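"""Class balancing, decision-tree fitting and interpretable rule extraction.

The classifier learns on log10-transformed features (log KD, log T0,
log t1/2) because the candidates are sampled log-uniformly; interpolation
or axis-aligned splits in raw nM space would distort the sampled manifold.
Thresholds are reported back in natural units (nM, h).

The tree hyperparameters are fixed: depth 5, Gini criterion,
``min_samples_split=3``, best splitter, balanced class weights; training
uses a stratified 90/10 split with stratified five-fold cross-validation
on the training portion.

The top-level surface is the statsmodels-style pair
:class:`OccupancyRuleModel` / :class:`OccupancyRuleResults`; the underlying
steps (:func:`smote_balance`, :func:`fit_tree`, :func:`extract_rules`,
:func:`evaluate`, :func:`validate_rules`) are plain functions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, confusion_matrix, f1_score,
                             precision_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

FEATURES = ("log_kd", "log_t0", "log_thalf")
#: natural-unit column and unit per feature
FEATURE_INFO = {
    "log_kd": ("kd_nM", "nM"),
    "log_t0": ("t0_nM", "nM"),
    "log_thalf": ("thalf_h", "h"),
}

__all__ = [
    "FEATURES", "feature_frame", "smote_balance", "fit_tree",
    "extract_rules", "evaluate", "validate_rules", "Rule",
    "OccupancyRuleModel", "OccupancyRuleResults",
]


def feature_frame(df: pd.DataFrame) -> pd.DataFrame:
    """log10 feature matrix from a labeled candidate table."""
    return pd.DataFrame({
        "log_kd": np.log10(df["kd_nM"].to_numpy(float)),
        "log_t0": np.log10(df["t0_nM"].to_numpy(float)),
        "log_thalf": np.log10(df["thalf_h"].to_numpy(float)),
    })


# ---------------------------------------------------------------------------
# SMOTE


def smote_balance(X: pd.DataFrame, y: pd.Series, k_neighbors: int = 5,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Oversample every minority class up to the majority count.

    Synthetic Minority Oversampling: each synthetic point lies uniformly on
    the segment between a random minority point and one of its
    ``k_neighbors`` nearest neighbours within the same class (Euclidean
    distance in feature space).  Original rows are returned unmodified and
    first; the provenance series marks rows 'original' / 'synthetic'.
    """
    X = X.reset_index(drop=True)
    y = pd.Series(np.asarray(y), name=getattr(y, "name", "label"))
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("SMOTE needs at least two classes")
    n_major = counts.iloc[0]
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls, n_cls in counts.items():
        deficit = n_major - n_cls
        if deficit == 0:
            continue
        pts = X[y == cls].to_numpy(float)
        if n_cls == 1:
            warnings.warn(
                f"minority class {cls!r} has a single row; replicating it "
                "instead of interpolating", RuntimeWarning)
            new_X.append(pd.DataFrame(np.repeat(pts, deficit, axis=0),
                                      columns=X.columns))
            new_y.append(pd.Series([cls] * deficit, name=y.name))
            continue
        k = k_neighbors
        if n_cls <= k:
            k = max(1, n_cls - 1)
            warnings.warn(
                f"minority class {cls!r} has only {n_cls} rows; "
                f"reducing k_neighbors to {k}", RuntimeWarning)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        _, nbr = nn.kneighbors(pts)          # column 0 is the point itself
        base = rng.integers(0, n_cls, size=deficit)
        pick = rng.integers(1, k + 1, size=deficit)
        gap = rng.random(deficit)[:, None]
        synth = pts[base] + gap * (pts[nbr[base, pick]] - pts[base])
        new_X.append(pd.DataFrame(synth, columns=X.columns))
        new_y.append(pd.Series([cls] * deficit, name=y.name))
    Xb = pd.concat(new_X, ignore_index=True)
    yb = pd.concat(new_y, ignore_index=True)
    provenance = pd.Series(
        ["original"] * len(X) + ["synthetic"] * (len(Xb) - len(X)),
        name="provenance")
    return Xb, yb, provenance


# ---------------------------------------------------------------------------
# tree fitting and metrics


def _tree(seed: int, ml_cfg: Mapping[str, Any] | None = None
          ) -> DecisionTreeClassifier:
    cfg = dict(max_depth=5, criterion="gini", min_samples_split=3,
               splitter="best", class_weight="balanced")
    if ml_cfg:
        cfg.update({k: ml_cfg[k] for k in
                    ("max_depth", "criterion", "min_samples_split",
                     "class_weight") if k in ml_cfg})
    return DecisionTreeClassifier(random_state=seed, **cfg)


def evaluate(clf: DecisionTreeClassifier, X_test: pd.DataFrame,
             y_test: pd.Series) -> dict[str, Any]:
    """Held-out metrics: accuracy, per-class precision/F1, confusion, AUC."""
    if len(X_test) == 0:
        raise ValueError("empty test set")
    pred = clf.predict(X_test)
    classes = list(clf.classes_)
    out: dict[str, Any] = {
        "accuracy": accuracy_score(y_test, pred),
        "precision": dict(zip(classes, precision_score(
            y_test, pred, labels=classes, average=None,
            zero_division=0.0))),
        "f1": dict(zip(classes, f1_score(
            y_test, pred, labels=classes, average=None,
            zero_division=0.0))),
        "confusion": pd.DataFrame(
            confusion_matrix(y_test, pred, labels=classes),
            index=classes, columns=classes),
    }
    if len(classes) == 2:
        score = clf.predict_proba(X_test)[:, 1]
        out["roc_auc"] = roc_auc_score(
            (np.asarray(y_test) == classes[1]).astype(int), score)
    return out


def fit_tree(Xb: pd.DataFrame, yb: pd.Series, seed: int = 0,
             test_size: float = 0.1, cv_folds: int = 5,
             ml_cfg: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Stratified 90/10 split, five-fold CV on the training part, final fit.

    Returns the fitted classifier, the split, fold-level CV accuracies
    (mean and sd) and held-out metrics.
    """
    if len(pd.unique(yb)) < 2:
        raise ValueError("need at least two classes to fit")
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xb, yb, test_size=test_size, stratify=yb, random_state=seed)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_acc = []
    for tr_idx, va_idx in skf.split(X_tr, y_tr):
        clf = _tree(seed, ml_cfg).fit(X_tr.iloc[tr_idx], y_tr.iloc[tr_idx])
        cv_acc.append(accuracy_score(
            y_tr.iloc[va_idx], clf.predict(X_tr.iloc[va_idx])))
    clf = _tree(seed, ml_cfg).fit(X_tr, y_tr)
    return {
        "clf": clf,
        "X_train": X_tr, "y_train": y_tr,
        "X_test": X_te, "y_test": y_te,
        "cv_accuracy_mean": float(np.mean(cv_acc)),
        "cv_accuracy_sd": float(np.std(cv_acc)),
        "cv_accuracies": cv_acc,
        "test_metrics": evaluate(clf, X_te, y_te),
    }


# ---------------------------------------------------------------------------
# rule extraction


@dataclass(frozen=True)
class Rule:
    """One root-to-leaf conjunction predicting a class.

    Conditions are (feature, op, threshold) with op in {"<=", ">"} and the
    threshold in natural units (nM for KD and T0, h for t1/2); the matching
    log10 thresholds drive evaluation.
    """

    rule_id: str
    predicted_class: str
    conditions: tuple[tuple[str, str, float], ...]   # natural units
    log_conditions: tuple[tuple[str, str, float], ...]
    impurity: float
    leaf_accuracy: float
    support: float           # fraction of training rows in the leaf
    n_samples: int

    def evaluate(self, X: pd.DataFrame) -> np.ndarray:
        """Boolean mask of rows satisfying every condition (log features)."""
        mask = np.ones(len(X), bool)
        for feat, op, thr in self.log_conditions:
            col = X[feat].to_numpy(float)
            mask &= (col <= thr) if op == "<=" else (col > thr)
        return mask

    def bound(self, feature: str, op: str) -> float | None:
        """Natural-unit threshold for (feature, op), or None if absent."""
        for feat, o, thr in self.conditions:
            if feat == feature and o == op:
                return thr
        return None

    def as_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [list(c) for c in self.conditions]
        d["log_conditions"] = [list(c) for c in self.log_conditions]
        return d


def extract_rules(clf: DecisionTreeClassifier, X_train: pd.DataFrame,
                  y_train: pd.Series, target_class: str | None = None
                  ) -> list[Rule]:
    """All root-to-leaf paths (optionally of one class) as ranked rules.

    Per-feature conjunctions keep only the tightest bound in each
    direction.  Support and leaf accuracy are unweighted fractions of the
    training rows routed to the leaf.  Ranking: ascending Gini impurity,
    then descending leaf accuracy, then descending support.
    """
    tree = clf.tree_
    feature_names = list(X_train.columns)
    leaf_of_row = clf.apply(X_train)
    y_arr = np.asarray(y_train)
    n_rows = len(y_arr)

    rules: list[Rule] = []

    def walk(node: int, path: list[tuple[str, str, float]]) -> None:
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:                                    # leaf
            in_leaf = leaf_of_row == node
            n_leaf = int(in_leaf.sum())
            pred = clf.classes_[np.argmax(tree.value[node][0])]
            if target_class is not None and pred != target_class:
                return
            acc = (float((y_arr[in_leaf] == pred).mean())
                   if n_leaf else float("nan"))
            # tightest bound per (feature, direction)
            tight: dict[tuple[str, str], float] = {}
            for feat, op, thr in path:
                key = (feat, op)
                if key not in tight:
                    tight[key] = thr
                else:
                    tight[key] = (min(tight[key], thr) if op == "<="
                                  else max(tight[key], thr))
            log_conds = tuple(sorted(
                (feat, op, thr) for (feat, op), thr in tight.items()))
            nat_conds = tuple((f, op, float(10.0 ** thr))
                              for f, op, thr in log_conds)
            rules.append(Rule(
                rule_id=f"leaf{node}",
                predicted_class=str(pred),
                conditions=nat_conds,
                log_conditions=log_conds,
                # sklearn can report -1e-17 for weighted pure leaves; a
                # signed zero must not outrank an exact zero
                impurity=float(max(tree.impurity[node], 0.0)),
                leaf_accuracy=acc,
                support=n_leaf / n_rows if n_rows else 0.0,
                n_samples=n_leaf))
            return
        feat = feature_names[tree.feature[node]]
        thr = float(tree.threshold[node])
        walk(left, path + [(feat, "<=", thr)])
        walk(right, path + [(feat, ">", thr)])

    walk(0, [])
    rules.sort(key=lambda r: (round(r.impurity, 12), -r.leaf_accuracy,
                              -r.support))
    return rules


# ---------------------------------------------------------------------------
# rule validation against the simulator


def validate_rules(rules: Sequence[Rule], scenario, phys,
                   config: Mapping[str, Any], n_probes: int = 20,
                   seed: int = 0) -> pd.DataFrame:
    """Probe each rule region with fresh simulated candidates.

    Samples ``n_probes`` candidates log-uniformly inside the rule's box
    (intersected with the screening ranges), simulates them under the
    rule's scenario, and reports the fraction whose simulated label equals
    the rule's predicted class.
    """
    from .cohort import run_cohort  # local import to avoid a cycle

    if not len(rules):
        return pd.DataFrame(
            columns=["rule_id", "predicted_class", "n_probes", "agreement"])
    ranges = config["sampling"]
    log_rng = {"log_kd": np.log10(ranges["kd"]),
               "log_t0": np.log10(ranges["t0"]),
               "log_thalf": np.log10(ranges["t_half"])}
    rng = np.random.default_rng(seed)
    rows = []
    for rule in rules:
        box = {f: list(log_rng[f]) for f in FEATURES}
        for feat, op, thr in rule.log_conditions:
            if op == "<=":
                box[feat][1] = min(box[feat][1], thr)
            else:
                box[feat][0] = max(box[feat][0], thr)
        if any(lo >= hi for lo, hi in box.values()):
            rows.append({"rule_id": rule.rule_id,
                         "predicted_class": rule.predicted_class,
                         "n_probes": 0, "agreement": float("nan")})
            continue
        probes = pd.DataFrame({
            "candidate_id": [f"probe_{rule.rule_id}_{i}"
                             for i in range(n_probes)],
            "kd_nM": 10 ** rng.uniform(*box["log_kd"], n_probes),
            "t0_nM": 10 ** rng.uniform(*box["log_t0"], n_probes),
            "thalf_h": 10 ** rng.uniform(*box["log_thalf"], n_probes),
        })
        labeled = run_cohort(probes, [scenario], phys, config)[
            scenario.scenario_id]
        agree = (labeled["label_binary"] == rule.predicted_class).mean()
        rows.append({"rule_id": rule.rule_id,
                     "predicted_class": rule.predicted_class,
                     "n_probes": n_probes, "agreement": float(agree)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results surface


class OccupancyRuleModel:
    """Decision-tree rule model over a labeled virtual cohort.

    Parameters
    ----------
    data
        Labeled candidate table (columns kd_nM, t0_nM, thalf_h and the
        label column); typically one scenario's output of
        :func:`mtpa.cohort.run_cohort`.
    label_col
        "label_binary" (optimal vs non-optimal at TO>90%) or "label_multi"
        (low/medium/high bands).
    drop_nonconverged
        Exclude records whose steady-state search hit the interval cap.
    """

    def __init__(self, data: pd.DataFrame, label_col: str = "label_binary",
                 drop_nonconverged: bool = True,
                 ml_cfg: Mapping[str, Any] | None = None):
        if drop_nonconverged and "converged" in data:
            data = data[data["converged"]]
        if "failed" in data:
            data = data[~data["failed"]]
        self.data = data.reset_index(drop=True)
        self.label_col = label_col
        self.ml_cfg = dict(ml_cfg or {})

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "OccupancyRuleModel":
        return cls(data, **kw)

    def fit(self, seed: int = 0, smote: bool = True,
            split_first: bool = False) -> "OccupancyRuleResults":
        """Balance, split, cross-validate and fit the tree.

        By default SMOTE runs before the 90/10 split (the balanced dataset
        is treated as ground truth); ``split_first=True`` applies the
        stricter order in which synthetic points never reach the test set.
        """
        X = feature_frame(self.data)
        y = self.data[self.label_col].astype(str)
        k = int(self.ml_cfg.get("smote_k_neighbors", 5))
        test_size = float(self.ml_cfg.get("test_size", 0.1))
        cv_folds = int(self.ml_cfg.get("cv_folds", 5))
        if smote and not split_first:
            Xb, yb, provenance = smote_balance(X, y, k, seed)
            fitres = fit_tree(Xb, yb, seed, test_size, cv_folds, self.ml_cfg)
        elif smote and split_first:
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=test_size, stratify=y, random_state=seed)
            Xb, yb, provenance = smote_balance(
                X_tr.reset_index(drop=True), y_tr.reset_index(drop=True),
                k, seed)
            fitres = fit_tree(Xb, yb, seed, test_size, cv_folds, self.ml_cfg)
            fitres["X_test"] = X_te.reset_index(drop=True)
            fitres["y_test"] = y_te.reset_index(drop=True)
            fitres["test_metrics"] = evaluate(fitres["clf"], X_te, y_te)
        else:
            Xb, yb = X, y
            provenance = pd.Series(["original"] * len(X), name="provenance")
            fitres = fit_tree(Xb, yb, seed, test_size, cv_folds, self.ml_cfg)
        return OccupancyRuleResults(self, fitres, provenance, seed)


class OccupancyRuleResults:
    """Fitted tree, its metrics and the extracted rule set."""

    def __init__(self, model: OccupancyRuleModel, fitres: dict,
                 provenance: pd.Series, seed: int):
        self.model = model
        self.tree_ = fitres["clf"]
        self.X_train = fitres["X_train"]
        self.y_train = fitres["y_train"]
        self.X_test = fitres["X_test"]
        self.y_test = fitres["y_test"]
        self.cv_accuracy_mean = fitres["cv_accuracy_mean"]
        self.cv_accuracy_sd = fitres["cv_accuracy_sd"]
        self.test_metrics = fitres["test_metrics"]
        self.provenance = provenance
        self.seed = seed

    @property
    def accuracy(self) -> float:
        """Held-out (10%) accuracy."""
        return float(self.test_metrics["accuracy"])

    def rules(self, target_class: str | None = None) -> list[Rule]:
        return extract_rules(self.tree_, self.X_train, self.y_train,
                             target_class)

    def top_rule(self, target_class: str = "optimal") -> Rule | None:
        ranked = self.rules(target_class)
        return ranked[0] if ranked else None

    def to_json(self) -> str:
        """Portable tree serialization (log10-unit thresholds)."""
        t = self.tree_.tree_
        return json.dumps({
            "features": list(self.X_train.columns),
            "classes": [str(c) for c in self.tree_.classes_],
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "impurity": t.impurity.tolist(),
            "n_node_samples": t.n_node_samples.tolist(),
            "value": t.value.tolist(),
        })

    def summary(self, target_class: str | None = None,
                max_rules: int = 5) -> str:
        """Readable fit report: metrics plus the top-ranked rules."""
        tm = self.test_metrics
        lines = [
            "Occupancy rule model (depth-5 Gini CART)",
            "=" * 48,
            f"training rows          {len(self.X_train):>8d}",
            f"held-out rows          {len(self.X_test):>8d}",
            f"CV accuracy (5-fold)   {self.cv_accuracy_mean:8.4f} "
            f"+/- {self.cv_accuracy_sd:.4f}",
            f"held-out accuracy      {tm['accuracy']:8.4f}",
        ]
        if "roc_auc" in tm:
            lines.append(f"held-out ROC AUC       {tm['roc_auc']:8.4f}")
        lines.append("")
        lines.append(f"top rules ({target_class or 'all classes'}):")
        for rule in self.rules(target_class)[:max_rules]:
            conds = " & ".join(
                f"{FEATURE_INFO[f][0].split('_')[0].upper()} {op} "
                f"{thr:.3g} {FEATURE_INFO[f][1]}"
                for f, op, thr in rule.conditions) or "(always)"
            lines.append(
                f"  -> {rule.predicted_class:<12s} gini={rule.impurity:.3f} "
                f"acc={rule.leaf_accuracy:.3f} "
                f"support={rule.support:.3f}  {conds}")
        return "\n".join(lines)
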