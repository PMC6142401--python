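"""Differential component testing, clustering metrics and classification.

Covers the downstream evaluation harness: per-component two-sample
t-tests with BH correction, clustering purity / Gini impurity /
cophenetic comparison, a one-vs-one max-vote SVM with explicit
indeterminable calls, binary classification metrics with honest
undefined values, McNemar's paired comparison, and a subsampling
experiment contrasting feature spaces at shrinking training sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.svm import SVC

from .annotate import bh_adjust
from .fcspace import FCProjection


# ---------------------------------------------------------------- DE testing

def de_fc_test(scores: FCProjection | np.ndarray, groups,
               alpha: float = 0.05, family_size: int | None = None,
               equal_var: bool = False) -> pd.DataFrame:
    """Two-sided two-sample t-test per component between two groups.

    Welch's variant by default; BH correction over `family_size`
    (defaults to the number of components).  Returns a per-component
    table with a boolean `de` column (p_adj < alpha).
    """
    X = scores.scores if isinstance(scores, FCProjection) else np.asarray(scores)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    a = X[:, groups == levels[0]]
    b = X[:, groups == levels[1]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p_adj = bh_adjust(p, family_size)
    fc_ids = scores.fc_ids if isinstance(scores, FCProjection) \
        else [f"FC{i + 1}" for i in range(X.shape[0])]
    return pd.DataFrame({"fc": fc_ids, "t": t, "p": p, "p_adj": p_adj,
                         "de": p_adj < alpha})


# ------------------------------------------------------------- cluster eval

@dataclass
class ClusterEval:
    purity: float
    gini: dict[int, float]               # cluster -> Gini impurity
    assignment: dict[int, object]        # cluster -> majority mega-class
    tied_clusters: list[int]


def cluster_eval(assignments, mega_labels) -> ClusterEval:
    """Purity and per-cluster Gini impurity against mega-class labels.

    Each cluster is classified as its majority mega-class (ties to the
    lower-indexed class, flagged); purity is the overall fraction of
    samples matching their cluster's class, Gini(C) = 1 - sum f_j^2
    over class fractions within the cluster.
    """
    assignments = np.asarray(assignments)
    mega_labels = np.asarray(mega_labels)
    if assignments.size != mega_labels.size or assignments.size == 0:
        raise ValueError("assignments and labels must align and be nonempty")
    classes = sorted(pd.unique(mega_labels).tolist())
    correct = 0
    gini, assignment, tied = {}, {}, []
    for c in sorted(pd.unique(assignments).tolist()):
        members = mega_labels[assignments == c]
        counts = np.array([(members == k).sum() for k in classes])
        frac = counts / counts.sum()
        gini[c] = float(1.0 - (frac ** 2).sum())
        top = int(np.argmax(counts))  # first maximum = lower-indexed class
        if (counts == counts[top]).sum() > 1:
            tied.append(c)
        assignment[c] = classes[top]
        correct += int(counts[top])
    return ClusterEval(correct / assignments.size, gini, assignment, tied)


def cophenetic_correlation(z1: np.ndarray, z2: np.ndarray) -> float:
    """Pearson correlation of cophenetic distances of two trees.

    Both arguments are scipy linkage matrices over the same leaves in
    the same order.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("trees must share the same leaf set")
    d1 = hierarchy.cophenet(z1)
    d2 = hierarchy.cophenet(z2)
    return float(np.corrcoef(d1, d2)[0, 1])


# ------------------------------------------------------------ classification

@dataclass
class ConfusionMatrix:
    classes: list
    counts: np.ndarray       # classes x classes, averaged over runs
    idc: np.ndarray          # per-class indeterminable calls (averaged)
    totals: np.ndarray       # per-class sample totals
    call_rate: np.ndarray    # per-class mean CR
    sensitivity: np.ndarray  # per-class correct / called

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.classes, columns=self.classes)
        df["IDC"] = self.idc
        df["Total"] = self.totals
        df["CR"] = self.call_rate
        df["Sensitivity"] = self.sensitivity
        return df


def _ovo_vote(models: dict, X: np.ndarray, classes: list) -> list:
    """Majority vote over pairwise classifiers; ties -> None (IDC)."""
    votes = np.zeros((X.shape[0], len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for (a, b), clf in models.items():
        pred = clf.predict(X)
        for i, p in enumerate(pred):
            votes[i, index[p]] += 1
    calls = []
    for i in range(X.shape[0]):
        best = votes[i].max()
        winners = np.flatnonzero(votes[i] == best)
        calls.append(classes[winners[0]] if winners.size == 1 else None)
    return calls


def maxvote_classify(scores: np.ndarray, labels, folds: int = 30, runs: int = 3,
                     seed: int = 0, C: float = 1.0) -> ConfusionMatrix:
    """Cross-validated one-vs-one linear-SVM classification with max vote.

    `scores` is samples x features.  For each run the samples are
    shuffled into `folds` stratified folds; each held-out sample's call
    is the majority vote over all pairwise linear SVMs trained on the
    remaining folds, with vote ties recorded as indeterminable calls
    (IDC).  Counts are averaged over runs; per-class sensitivity is
    correct calls over determinable calls of that class.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    k = len(classes)
    counts = np.zeros((runs, k, k))
    idc = np.zeros((runs, k))
    cidx = {c: i for i, c in enumerate(classes)}
    for r in range(runs):
        rng = np.random.default_rng(seed + r)
        fold_of = np.empty(y.size, dtype=int)
        # stratified fold assignment
        for c in classes:
            members = np.flatnonzero(y == c)
            rng.shuffle(members)
            fold_of[members] = np.arange(members.size) % folds
        for f in range(folds):
            test = fold_of == f
            if not test.any():
                continue
            Xtr, ytr = X[~test], y[~test]
            models = {}
            for a, b in combinations(classes, 2):
                mask = (ytr == a) | (ytr == b)
                if len(pd.unique(ytr[mask])) < 2:
                    warnings.warn(
                        f"class pair ({a}, {b}) incomplete in a training fold; skipped",
                        stacklevel=2)
                    continue
                clf = SVC(kernel="linear", C=C)
                clf.fit(Xtr[mask], ytr[mask])
                models[(a, b)] = clf
            calls = _ovo_vote(models, X[test], classes)
            for true, call in zip(y[test], calls):
                if call is None:
                    idc[r, cidx[true]] += 1
                else:
                    counts[r, cidx[true], cidx[call]] += 1
    totals = np.array([(y == c).sum() for c in classes], dtype=float)
    mean_counts = counts.mean(axis=0)
    mean_idc = idc.mean(axis=0)
    called = mean_counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cr = np.where(totals > 0, called / totals, np.nan)
        sens = np.where(called > 0, np.diag(mean_counts) / called, np.nan)
    return ConfusionMatrix(classes, mean_counts, mean_idc, totals, cr, sens)


# ----------------------------------------------------------- binary metrics

@dataclass
class MetricsRecord:
    TP: int
    TN: int
    FP: int
    FN: int
    PPV: float | None
    NPV: float | None
    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP

    @property
    def pred_P(self) -> int:
        return self.TP + self.FP

    @property
    def pred_N(self) -> int:
        return self.TN + self.FN


def binary_metrics(predictions, truth, positive_class) -> MetricsRecord:
    """PPV, NPV, sensitivity, specificity and accuracy for a binary task.

    PPV (NPV) is None when no positive (negative) prediction was made;
    undefined values are never silently reported as 0.
    """
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    pos = true == positive_class
    ppos = pred == positive_class
    TP = int((pos & ppos).sum())
    TN = int((~pos & ~ppos).sum())
    FP = int((~pos & ppos).sum())
    FN = int((pos & ~ppos).sum())
    ppv = TP / (TP + FP) if (TP + FP) > 0 else None
    npv = TN / (TN + FN) if (TN + FN) > 0 else None
    sens = TP / (TP + FN) if (TP + FN) > 0 else np.nan
    spec = TN / (TN + FP) if (TN + FP) > 0 else np.nan
    acc = (TP + TN) / true.size
    return MetricsRecord(TP, TN, FP, FN, ppv, npv, sens, spec, acc)


def mcnemar_compare(pred_a, pred_b, truth, alpha: float = 0.05):
    """McNemar's test with continuity correction on two paired classifiers.

    Returns (statistic, p, verdict); identical prediction vectors yield
    verdict "identical" with an undefined statistic.
    """
    pa = np.asarray(pred_a)
    pb = np.asarray(pred_b)
    t = np.asarray(truth)
    if not (pa.size == pb.size == t.size):
        raise ValueError("prediction and truth vectors must align")
    if np.array_equal(pa, pb):
        return None, None, "identical"
    a_ok = pa == t
    b_ok = pb == t
    b_count = int((a_ok & ~b_ok).sum())
    c_count = int((~a_ok & b_ok).sum())
    if b_count + c_count == 0:
        return None, None, "identical"
    statistic = (abs(b_count - c_count) - 1) ** 2 / (b_count + c_count)
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p, ("different" if p < alpha else "not_different")


# ------------------------------------------------------ subsampling harness

def _train_predict(Xtr, ytr, Xte, C: float = 1.0):
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xtr, ytr)
    return clf.predict(Xte)


def subsample_experiment(spaces: dict[str, np.ndarray], labels,
                         positive_class, negative_class,
                         test_sizes: tuple[int, int] = (22, 37),
                         fractions=(0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 1.0),
                         repeats: int = 200, runs: int = 10, seed: int = 0,
                         C: float = 1.0) -> pd.DataFrame:
    """Classifier performance versus training-set size in several feature spaces.

    Each entry of `spaces` maps a space name to a samples x features
    matrix over the same samples.  Per run, `test_sizes` positive and
    negative samples are held out; for every fraction and repeat, the
    remaining pools are subsampled, one linear SVM per space is trained,
    and binary metrics plus pairwise McNemar comparisons across spaces
    are computed on the held-out set.  Repeats are averaged within a
    run (undefined PPV/NPV excluded, with counts reported); fraction 1.0
    runs once per run.  Returns a tidy table with mean and SD over runs.
    """
    y = np.asarray(labels)
    pos_pool = np.flatnonzero(y == positive_class)
    neg_pool = np.flatnonzero(y == negative_class)
    n_test_pos, n_test_neg = test_sizes
    if n_test_pos >= pos_pool.size or n_test_neg >= neg_pool.size:
        raise ValueError("pools too small for the requested test sizes")
    names = list(spaces)
    metric_names = ["PPV", "NPV", "sensitivity", "specificity", "accuracy"]
    # per (fraction, space, metric): list over runs of within-run means
    acc: dict[tuple, list] = {}
    undef: dict[tuple, int] = {}
    diff_pct: dict[float, list] = {f: [] for f in fractions}

    for r in range(runs):
        run_seed = seed + r
        rng = np.random.default_rng(run_seed)
        test_pos = rng.choice(pos_pool, n_test_pos, replace=False)
        test_neg = rng.choice(neg_pool, n_test_neg, replace=False)
        test_idx = np.r_[test_pos, test_neg]
        train_pos = np.setdiff1d(pos_pool, test_pos)
        train_neg = np.setdiff1d(neg_pool, test_neg)
        y_test = y[test_idx]
        for frac in fractions:
            n_rep = 1 if frac == 1.0 else repeats
            per_space: dict[str, dict[str, list]] = {
                s: {m: [] for m in metric_names} for s in names}
            n_diff = 0
            n_pairs = 0
            for rep in range(n_rep):
                rep_rng = np.random.default_rng(run_seed * 1000 + rep)
                if frac == 1.0:
                    tr_idx = np.r_[train_pos, train_neg]
                else:
                    k_pos = max(1, round(frac * train_pos.size))
                    k_neg = max(1, round(frac * train_neg.size))
                    tr_idx = np.r_[rep_rng.choice(train_pos, k_pos, replace=False),
                                   rep_rng.choice(train_neg, k_neg, replace=False)]
                preds = {}
                for s in names:
                    X = spaces[s]
                    preds[s] = _train_predict(X[tr_idx], y[tr_idx], X[test_idx], C)
                    rec = binary_metrics(preds[s], y_test, positive_class)
                    for m in metric_names:
                        v = getattr(rec, m)
                        if v is None:
                            undef[(frac, s, m)] = undef.get((frac, s, m), 0) + 1
                        else:
                            per_space[s][m].append(v)
                for sa, sb in combinations(names, 2):
                    _, _, verdict = mcnemar_compare(preds[sa], preds[sb], y_test)
                    n_pairs += 1
                    if verdict == "different":
                        n_diff += 1
            for s in names:
                for m in metric_names:
                    vals = per_space[s][m]
                    key = (frac, s, m)
                    acc.setdefault(key, []).append(
                        float(np.mean(vals)) if vals else np.nan)
            if n_pairs:
                diff_pct[frac].append(100.0 * n_diff / n_pairs)

    rows = []
    for (frac, s, m), vals in acc.items():
        arr = np.asarray(vals, dtype=float)
        ok = arr[~np.isnan(arr)]
        rows.append({
            "fraction": frac, "space": s, "metric": m,
            "mean": float(ok.mean()) if ok.size else np.nan,
            "sd": float(ok.std(ddof=1)) if ok.size > 1 else 0.0,
            "n_undefined": undef.get((frac, s, m), 0),
        })
    for frac, vals in diff_pct.items():
        if vals:
            arr = np.asarray(vals)
            rows.append({"fraction": frac, "space": "both", "metric": "pct_different",
                         "mean": float(arr.mean()),
                         "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                         "n_undefined": 0})
    return pd.DataFrame(rows).sort_values(
        ["fraction", "space", "metric"]).reset_index(drop=True)
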