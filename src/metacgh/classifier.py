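"""Nearest-shrunken-centroids classification of metastasis site.

The shrunken-centroids (PAM-style) model standardizes each class-centroid
difference from the overall centroid,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n),

soft-thresholds it, d'_ik = sign(d_ik) * max(|d_ik| - delta, 0), and moves
the centroid back, xbar'_ik = xbar_i + m_k * (s_i + s0) * d'_ik. Here s_i is
the pooled within-class standard deviation of feature i and s0 a fudge
constant (median of the s_i by default) guarding against tiny variances.
Classification minimizes the penalized discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k,

with class probabilities proportional to exp(-delta_k / 2). Features with a
nonzero shrunken difference in at least one class are the selected features;
their count shrinks monotonically as delta grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold

from .io import AcghDataset, CloneMap


@dataclass
class NscModel:
    class_labels: list[str]
    overall_centroid: np.ndarray
    class_centroids: np.ndarray        # raw, class x feature
    shrunken_centroids: np.ndarray     # class x feature
    pooled_sd: np.ndarray              # s_i
    s0: float
    delta: float
    priors: np.ndarray

    @property
    def selected_features(self) -> np.ndarray:
        """Indices of features whose shrunken centroid differs from the
        overall centroid in at least one class."""
        diff = self.shrunken_centroids - self.overall_centroid
        return np.flatnonzero(np.any(np.abs(diff) > 0, axis=0))


def train_nsc(
    X: np.ndarray,
    y: np.ndarray,
    delta: float,
    priors: np.ndarray | None = None,
    s0_percentile: float = 50.0,
    s0: float | None = None,
) -> NscModel:
    """Fit the shrunken-centroids model at shrinkage level ``delta``.

    Priors default to empirical class frequencies; ``s0`` is the
    ``s0_percentile`` point of the pooled sds (median by default) unless
    given explicitly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute before training")
    labels = sorted(set(y), key=list(y).index)  # first-appearance order
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    counts = np.array([(y == k).sum() for k in labels])
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")

    overall = X.mean(axis=0)
    cent = np.stack([X[y == k].mean(axis=0) for k in labels])
    within_ss = np.zeros(p)
    for k, lab in enumerate(labels):
        resid = X[y == lab] - cent[k]
        within_ss += (resid * resid).sum(axis=0)
    s = np.sqrt(within_ss / (n - len(labels)))
    if s0 is None:
        s0 = float(np.percentile(s, s0_percentile))
    m = np.sqrt(1.0 / counts - 1.0 / n)

    scale = m[:, None] * (s + s0)[None, :]
    d = (cent - overall) / scale
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall + scale * d_shrunk

    if priors is None:
        priors = counts / n
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()
    return NscModel(labels, overall, cent, shrunken, s, s0, float(delta), priors)


def predict_nsc(model: NscModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class probabilities for one vector or a matrix.

    Discriminant ties break toward the larger prior, then label order.
    Returns (labels, probabilities) with probability columns in
    ``model.class_labels`` order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.overall_centroid):
        raise ValueError(f"feature dimension {X.shape[1]} does not match model "
                         f"({len(model.overall_centroid)})")
    denom = (model.pooled_sd + model.s0) ** 2
    disc = np.empty((X.shape[0], len(model.class_labels)))
    for k in range(len(model.class_labels)):
        diff = X - model.shrunken_centroids[k]
        disc[:, k] = (diff * diff / denom).sum(axis=1) - 2.0 * np.log(model.priors[k])
    # stable softmax of -disc/2
    z = -0.5 * (disc - disc.min(axis=1, keepdims=True))
    prob = np.exp(z)
    prob /= prob.sum(axis=1, keepdims=True)
    # argmin with tie-break: larger prior, then label order
    order = np.lexsort((np.arange(len(model.priors)), -model.priors))
    best = order[np.argmin(disc[:, order], axis=1)]
    labels = np.array([model.class_labels[k] for k in best], dtype=object)
    return labels, prob


@dataclass
class CvResult:
    delta_grid: np.ndarray
    error: np.ndarray         # mean misclassification error per delta
    error_se: np.ndarray      # standard error over folds
    n_selected: np.ndarray    # mean selected-feature count per delta
    chosen_delta: float


def default_delta_grid(X: np.ndarray, y: np.ndarray, n: int = 15) -> np.ndarray:
    """Evenly spaced shrinkage levels from 0 to the smallest delta that
    empties the model (max |d_ik| at delta=0)."""
    model = train_nsc(X, y, 0.0)
    scale = (np.sqrt(1.0 / np.array([(y == k).sum() for k in model.class_labels]) - 1.0 / len(y))[:, None]
             * (model.pooled_sd + model.s0)[None, :])
    dmax = np.max(np.abs((model.class_centroids - model.overall_centroid) / scale))
    return np.linspace(0.0, dmax, n)


def cross_validate_nsc(
    X: np.ndarray,
    y: np.ndarray,
    delta_grid: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    priors: np.ndarray | None = None,
) -> CvResult:
    """Stratified k-fold cross-validated error over a shrinkage grid.

    The chosen delta is the largest whose mean error is within one standard
    error of the minimum (parsimony: prefer more shrinkage). Fold count
    degrades to the smallest class size when necessary.
    """
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid.size == 0:
        raise ValueError("delta_grid is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    smallest = min((y == k).sum() for k in set(y))
    n_folds = min(n_folds, smallest)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = np.zeros((n_folds, len(delta_grid)))
    n_sel = np.zeros((n_folds, len(delta_grid)))
    for f, (tr, te) in enumerate(skf.split(X, y.astype(str))):
        for j, delta in enumerate(delta_grid):
            model = train_nsc(X[tr], y[tr], delta, priors=priors)
            pred, _ = predict_nsc(model, X[te])
            errors[f, j] = np.mean(pred != y[te])
            n_sel[f, j] = len(model.selected_features)
    err = errors.mean(axis=0)
    se = errors.std(axis=0, ddof=1) / np.sqrt(n_folds)
    j_min = int(np.argmin(err))
    ok = np.flatnonzero(err <= err[j_min] + se[j_min])
    chosen = float(delta_grid[ok.max()])
    return CvResult(delta_grid, err, se, n_sel.mean(axis=0), chosen)


def save_nsc(model: NscModel, path) -> None:
    """Serialize a model as a flat tab-separated file: a commented header
    with labels, delta, s0 and priors, then one row per feature with the
    overall centroid, pooled sd, and per-class raw/shrunken centroids."""
    labels_field = "\t".join(model.class_labels)
    priors_field = "\t".join(repr(float(p)) for p in model.priors)
    head = [
        f"# class_labels\t{labels_field}",
        f"# delta\t{model.delta!r}",
        f"# s0\t{model.s0!r}",
        f"# priors\t{priors_field}",
    ]
    cols = {"overall_centroid": model.overall_centroid, "pooled_sd": model.pooled_sd}
    for k, lab in enumerate(model.class_labels):
        cols[f"centroid_{lab}"] = model.class_centroids[k]
        cols[f"shrunken_{lab}"] = model.shrunken_centroids[k]
    body = pd.DataFrame(cols).to_csv(sep="\t", index_label="feature",
                                     float_format="%.17g")
    with open(path, "w") as fh:
        fh.write("\n".join(head) + "\n" + body)


def load_nsc(path) -> NscModel:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, *vals = line[1:].strip().split("\t")
            meta[key] = vals
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col="feature",
                         float_precision="round_trip")
    labels = meta["class_labels"]
    return NscModel(
        labels,
        df["overall_centroid"].to_numpy(),
        np.stack([df[f"centroid_{lab}"].to_numpy() for lab in labels]),
        np.stack([df[f"shrunken_{lab}"].to_numpy() for lab in labels]),
        df["pooled_sd"].to_numpy(),
        float(meta["s0"][0]),
        float(meta["delta"][0]),
        np.array([float(v) for v in meta["priors"]]),
    )


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class ClassifierEval:
    confusion: pd.DataFrame
    accuracy: float
    sensitivity: float
    specificity: float
    positive_label: str
    probabilities: pd.Series  # positive-class probability per sample
    roc_points: np.ndarray    # (fpr, tpr) rows from (0,0) to (1,1)
    auc: float


def roc_from_score(scores: np.ndarray, truth: np.ndarray, positive_label: str) -> tuple[np.ndarray, float]:
    """ROC points and trapezoid AUC from a raw ranking score (higher score =
    more positive). Tied scores are grouped into single ROC steps."""
    truth = np.asarray(truth, dtype=object)
    pos = truth == positive_label
    if pos.all() or not pos.any():
        raise ValueError("truth must contain both classes")
    fpr, tpr, _ = skmetrics.roc_curve(pos.astype(int), np.asarray(scores, dtype=float),
                                      drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(np.trapezoid(tpr, fpr))


def evaluate(
    predictions: np.ndarray,
    probabilities: np.ndarray,
    truth: np.ndarray,
    positive_label: str,
    sample_ids: list[str] | None = None,
) -> ClassifierEval:
    """Confusion matrix, accuracy/sensitivity/specificity for the declared
    positive class, and a probability-ranked ROC with trapezoid AUC."""
    truth = np.asarray(truth, dtype=object)
    predictions = np.asarray(predictions, dtype=object)
    if positive_label not in set(truth):
        raise ValueError(f"positive label {positive_label!r} absent from truth")
    labels = sorted(set(truth) | set(predictions), key=str)
    conf = pd.crosstab(pd.Series(truth, name="truth"), pd.Series(predictions, name="predicted")
                       ).reindex(index=labels, columns=labels, fill_value=0)
    acc = float(np.mean(predictions == truth))
    is_pos = truth == positive_label
    pred_pos = predictions == positive_label
    sens = float((pred_pos & is_pos).sum() / is_pos.sum())
    spec = float((~pred_pos & ~is_pos).sum() / (~is_pos).sum())
    probs = np.asarray(probabilities, dtype=float)
    roc, auc = roc_from_score(probs, truth, positive_label)
    idx = sample_ids if sample_ids is not None else list(range(len(truth)))
    return ClassifierEval(conf, acc, sens, spec, positive_label,
                          pd.Series(probs, index=idx, name="p_positive"), roc, auc)


def mann_whitney_auc(scores: np.ndarray, truth: np.ndarray, positive_label: str) -> float:
    """AUC via the Mann-Whitney U identity U / (n_pos * n_neg), with the
    standard half-credit for ties (midranks)."""
    truth = np.asarray(truth, dtype=object)
    pos = truth == positive_label
    r = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Feature report


def feature_report(model: NscModel, clone_map: CloneMap) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Selected clones with genomic annotation, plus per-arm enrichment.

    Enrichment per chromosome arm is the one-sided hypergeometric tail:
    drawing |selected| clones from the array, probability of at least the
    observed number landing on the arm. Returns (features, arm_enrichment).
    """
    sel = model.selected_features
    tab = clone_map.table
    feats = tab.iloc[sel][["clone_id", "chromosome", "arm", "position_bp"]].copy()
    diff = model.shrunken_centroids[:, sel] - model.overall_centroid[sel]
    for k, lab in enumerate(model.class_labels):
        feats[f"shrunken_diff_{lab}"] = diff[k]
    feats = feats.reset_index(drop=True)

    arms = pd.Series(clone_map.arm_label())
    total = len(clone_map)
    n_sel = len(sel)
    records = []
    sel_arms = arms.iloc[sel] if n_sel else pd.Series(dtype=object)
    for arm, n_arm in arms.value_counts().items():
        k_obs = int((sel_arms == arm).sum())
        p = float(hypergeom.sf(k_obs - 1, total, int(n_arm), n_sel)) if n_sel else 1.0
        records.append({"arm": arm, "clones_on_arm": int(n_arm),
                        "selected_on_arm": k_obs, "p_enrichment": p})
    enr = pd.DataFrame(records).sort_values("p_enrichment", ignore_index=True)
    return feats, enr


# ---------------------------------------------------------------------------
# Task plumbing


def impute_arm_median(dataset: AcghDataset) -> np.ndarray:
    """Clone-level matrix with missing values imputed by the per-sample
    chromosome-arm median (falling back to the per-sample median, then 0)."""
    X = dataset.log2.copy()
    arms = dataset.clone_map.arm_label()
    for arm in pd.unique(arms):
        cols = np.flatnonzero(arms == arm)
        block = X[:, cols]
        med = np.nanmedian(np.where(np.isnan(block), np.nan, block), axis=1)
        med = np.where(np.isnan(med), np.nanmedian(X, axis=1), med)
        inds = np.where(np.isnan(block))
        block[inds] = np.nan_to_num(med[inds[0]])
        X[:, cols] = block
    return np.nan_to_num(X)


def task_labels(groups: np.ndarray, task: str) -> tuple[np.ndarray, np.ndarray, str]:
    """Packaged two-class tasks: 'lm-vs-rest' (LM against PM+M0) and
    'pm-vs-m0' (PM against M0, LM samples dropped). Returns
    (sample mask, labels, positive label)."""
    groups = np.asarray(groups, dtype=object)
    if task == "lm-vs-rest":
        mask = np.ones(len(groups), dtype=bool)
        labels = np.where(groups == "LM", "LM", "rest").astype(object)
        return mask, labels, "LM"
    if task == "pm-vs-m0":
        mask = np.isin(groups, ["PM", "M0"])
        return mask, groups[mask], "PM"
    raise ValueError(f"unknown task {task!r}")
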