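"""CTC-versus-PBMC classification harness.

Marker-restricted feature selection, train-fitted normalization/PCA, three
classifier families (Gaussian naive Bayes, random forest, gradient
boosting), leave-one-dataset-out evaluation, and differential ranking of
surface-protein markers.

Throughout, CTC is the positive class.  Reported metrics:

    accuracy = (TP + TN) / (TP + TN + FP + FN)
    F1       = 2 TP / (2 TP + FP + FN)
    MCC      = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    kappa    = (p_o − p_e) / (1 − p_e)

Single-class evaluation sets report accuracy/F1 and NA for MCC and kappa.

Leave-one-dataset-out: each dataset (study/batch) is held out in turn; the
median library size, the PCA transform and the classifier are all fitted on
the remaining datasets only and applied, frozen, to the held-out cells — no
held-out cell influences any fitted quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from statsmodels.stats.multitest import multipletests

from .preprocess import _dense

__all__ = [
    "select_features",
    "fit_transform_pca",
    "train_classifier",
    "confusion_metrics",
    "evaluate",
    "leave_one_dataset_out",
    "rank_surface_markers",
]

POSITIVE_CLASS = "CTC"


class ClassifyError(ValueError):
    pass


def select_features(adata: ad.AnnData, marker_list: Sequence[str]) -> ad.AnnData:
    """Restrict the matrix to marker genes (case-normalized exact match)."""
    lut = {g.upper(): g for g in adata.var_names}
    hits = [lut[m.upper()] for m in marker_list if m.upper() in lut]
    hits = list(dict.fromkeys(hits))
    if not hits:
        raise ClassifyError("no marker genes found in matrix")
    return adata[:, hits].copy()


@dataclass
class PCATransform:
    """Train-fitted PCA applied consistently to train and test partitions."""

    pca: PCA
    feature_names: tuple

    def apply(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(np.asarray(X, dtype=float))

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_


def fit_transform_pca(train: np.ndarray, n_components: int,
                      feature_names: Sequence[str] | None = None):
    """Fit PCA on the training matrix only; returns (transform, embedding)."""
    train = np.asarray(train, dtype=float)
    cap = min(train.shape)
    if n_components > cap:
        raise ClassifyError(
            f"n_components={n_components} exceeds min(n_cells, n_features)={cap}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(train)
    names = tuple(feature_names) if feature_names is not None else ()
    return PCATransform(pca=pca, feature_names=names), emb


_ALGOS = {"nb", "rf", "gbm"}


def train_classifier(
    X: np.ndarray,
    y: Sequence[str],
    algo: str = "gbm",
    seed: int = 0,
    **hyperparams,
):
    """Fit one of the three classifier families on (features, labels).

    Defaults: naive Bayes with Gaussian likelihoods on log-expression;
    random forest with 500 trees; gradient boosting with 100 rounds of
    depth-3 trees at learning rate 0.1.  Deterministic under ``seed``.
    """
    algo = algo.lower()
    if algo not in _ALGOS:
        raise ClassifyError(f"algo must be one of {sorted(_ALGOS)}")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ClassifyError("training labels contain a single class")
    if algo == "nb":
        model = GaussianNB(**hyperparams)
    elif algo == "rf":
        hp = {"n_estimators": 500, **hyperparams}
        model = RandomForestClassifier(random_state=seed, **hp)
    else:
        hp = {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1,
              **hyperparams}
        model = GradientBoostingClassifier(random_state=seed, **hp)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Accuracy, F1, MCC and Cohen's kappa from confusion counts."""
    n = tp + tn + fp + fn
    if n == 0:
        raise ClassifyError("empty confusion matrix")
    acc = (tp + tn) / n
    f1_den = 2 * tp + fp + fn
    f1 = 2 * tp / f1_den if f1_den else float("nan")
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den) if mcc_den else float("nan")
    p_o = acc
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else float("nan")
    return {"tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "accuracy": acc, "f1": f1, "mcc": float(mcc), "kappa": kappa}


def evaluate(model, X: np.ndarray, y: Sequence[str],
             positive: str = POSITIVE_CLASS) -> dict:
    """Confusion counts and metrics on an evaluation set (CTC positive).

    Single-class test sets get accuracy/F1 with MCC and kappa reported as
    NaN and a reason recorded under ``note``.
    """
    y = np.asarray(y)
    if len(y) == 0:
        raise ClassifyError("empty evaluation set")
    X = np.asarray(X, dtype=float)
    if X.shape[1] != getattr(model, "n_features_in_", X.shape[1]):
        raise ClassifyError(
            f"feature misalignment: model expects {model.n_features_in_}, "
            f"got {X.shape[1]}"
        )
    pred = model.predict(X)
    pos_t, pos_p = y == positive, pred == positive
    rep = confusion_metrics(
        tp=int((pos_t & pos_p).sum()), tn=int((~pos_t & ~pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()), fn=int((pos_t & ~pos_p).sum()),
    )
    if len(np.unique(y)) < 2:
        rep["mcc"] = rep["kappa"] = float("nan")
        rep["note"] = "single-class evaluation set; MCC/kappa undefined"
    else:
        rep["note"] = ""
    # probabilistic cancer-origin score where available
    if hasattr(model, "predict_proba"):
        pos_col = list(model.classes_).index(positive)
        rep["mean_positive_score"] = float(model.predict_proba(X)[:, pos_col].mean())
        rep["score_kind"] = "probability"
    return rep


def _median_normalize_split(train_X, test_X):
    """Median normalization with the median library size fitted on train."""
    train_X, test_X = np.asarray(train_X, float), np.asarray(test_X, float)
    t_tot = train_X.sum(axis=1)
    s_tot = test_X.sum(axis=1)
    if (t_tot <= 0).any() or (s_tot <= 0).any():
        raise ClassifyError("cells with zero totals; filter before classification")
    med = float(np.median(t_tot))
    return train_X * (med / t_tot)[:, None], test_X * (med / s_tot)[:, None]


def leave_one_dataset_out(
    adata: ad.AnnData,
    dataset_col: str = "batch",
    label_col: str = "class_label",
    algo: str = "gbm",
    norm: str = "median",
    n_components: int = 20,
    marker_list: Sequence[str] | None = None,
    seed: int = 0,
    mixed_pbmc_sample: int | None = None,
    return_models: bool = False,
):
    """Hold out each dataset in turn; train on the rest; report metrics.

    ``adata`` holds raw (or already filtered) counts; median normalization
    (train-fitted) and log1p run inside each fold so no held-out cell
    leaks into normalization, PCA or classifier fitting.
    ``norm``: "median" (reference configuration) or "median+pca".
    ``mixed_pbmc_sample``: when set, each evaluation set is the held-out
    dataset's CTCs plus that many PBMCs sampled (seeded) from the held-out
    partition, emulating mixed CTC + background evaluation sets.
    """
    if norm not in ("median", "median+pca"):
        raise ClassifyError("norm must be 'median' or 'median+pca'")
    obs = adata.obs
    for col in (dataset_col, label_col):
        if col not in obs.columns:
            raise ClassifyError(f"annotation column {col!r} missing")
    datasets = list(pd.unique(obs[dataset_col]))
    if len(datasets) < 2:
        raise ClassifyError("need >= 2 datasets for leave-one-dataset-out")

    work = select_features(adata, marker_list) if marker_list is not None else adata
    X_all = _dense(work.X).astype(float)
    y_all = np.asarray(obs[label_col]).astype(str)
    ds_all = np.asarray(obs[dataset_col]).astype(str)

    rng = np.random.default_rng(seed)
    rows = []
    models: dict = {}
    for held in map(str, datasets):
        te = ds_all == held
        tr = ~te
        if len(np.unique(y_all[tr])) < 2:
            raise ClassifyError(f"training partition for held-out {held!r} "
                                "lacks a class")
        te_idx = np.flatnonzero(te)
        if mixed_pbmc_sample is not None:
            ctc = te_idx[y_all[te_idx] == POSITIVE_CLASS]
            pbmc = te_idx[y_all[te_idx] != POSITIVE_CLASS]
            take = min(mixed_pbmc_sample, len(pbmc))
            pbmc = rng.choice(pbmc, size=take, replace=False)
            te_idx = np.concatenate([ctc, pbmc])
        Xtr, Xte = _median_normalize_split(X_all[tr], X_all[te_idx])
        Xtr, Xte = np.log1p(Xtr), np.log1p(Xte)
        if norm == "median+pca":
            transform, Xtr = fit_transform_pca(
                Xtr, min(n_components, min(Xtr.shape))
            )
            Xte = transform.apply(Xte)
        model = train_classifier(Xtr, y_all[tr], algo=algo, seed=seed)
        models[held] = model
        rep = evaluate(model, Xte, y_all[te_idx])
        rep.update(dataset=held, algo=algo, norm=norm,
                   n_train=int(tr.sum()), n_test=len(te_idx))
        rows.append(rep)
    report = pd.DataFrame(rows).set_index("dataset")
    first = ["algo", "norm", "n_train", "n_test", "tp", "tn", "fp", "fn",
             "accuracy", "f1", "mcc", "kappa"]
    report = report[first + [c for c in report.columns if c not in first]]
    return (report, models) if return_models else report


def rank_surface_markers(
    adata: ad.AnnData,
    surface_genes: Sequence[str],
    label_col: str = "class_label",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank surface-protein genes differentially upregulated in CTCs.

    Wilcoxon rank-sum (Mann–Whitney U) per gene, CTC vs PBMC, with
    Benjamini–Hochberg adjustment and log2 fold-change of (pseudo-counted)
    mean expression; sorted by adjusted p then descending fold-change.
    """
    feats = select_features(adata, surface_genes)
    y = np.asarray(adata.obs[label_col]).astype(str)
    if len(np.unique(y)) < 2:
        raise ClassifyError("both classes required")
    X = _dense(feats.X).astype(float)
    pos, neg = y == POSITIVE_CLASS, y != POSITIVE_CLASS
    stats, pvals, lfc = [], [], []
    for j in range(X.shape[1]):
        a, b = X[pos, j], X[neg, j]
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            u, p = np.nan, 1.0
        else:
            u, p = scipy.stats.mannwhitneyu(a, b, alternative="greater")
        stats.append(u)
        pvals.append(p)
        lfc.append(np.log2((a.mean() + 1.0) / (b.mean() + 1.0)))
    adj = multipletests(pvals, alpha=alpha, method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene": list(feats.var_names), "statistic": stats, "pvalue": pvals,
        "padj": adj, "log2fc": lfc,
    })
    out["significant"] = out["padj"] < alpha
    return out.sort_values(["padj", "log2fc"], ascending=[True, False]).reset_index(
        drop=True
    )
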