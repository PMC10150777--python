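"""Epimutation-based risk stratification.

Two complementary views of the cis-CSCE methylation profile:

* an unsupervised one — a 2-d embedding (UMAP with n_neighbors=15 and a
  euclidean metric, or a deterministic PCA fallback) clustered by
  k-means (k=3), with cluster membership tested against cancer status
  and survival;
* a supervised one — a random forest trained with repeated stratified
  5-fold cross-validation over an mtry (max_features) grid, whose
  out-of-model prediction probabilities act as a cancer risk score.
  An operating threshold on the score is chosen by the Youden index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold

__all__ = [
    "ClusterResult",
    "embed_and_cluster",
    "CancerRiskModel",
    "RiskModelReport",
    "youden_threshold",
    "YoudenResult",
]


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    """2-d embedding + k-means labels with cancer-status and survival tests."""

    embedding: pd.DataFrame  # samples x (dim1, dim2)
    labels: pd.Series  # sample -> 1..k
    k: int
    method: str
    chi2: float | None = None
    chi2_p: float | None = None
    logrank_p: float | None = None

    def summary(self) -> str:
        sizes = self.labels.value_counts().sort_index()
        lines = [f"{self.method} embedding + k-means (k={self.k})"]
        lines.append("  cluster sizes: " + ", ".join(f"{c}:{n}" for c, n in sizes.items()))
        if self.chi2_p is not None:
            lines.append(f"  cluster x cancer status: chi2={self.chi2:.2f}, p={self.chi2_p:.3g}")
        if self.logrank_p is not None:
            lines.append(f"  log-rank across clusters: p={self.logrank_p:.3g}")
        return "\n".join(lines)


def embed_and_cluster(
    features: pd.DataFrame,
    k: int = 3,
    embed: str = "pca",
    seed: int = 0,
    n_neighbors: int = 15,
    cancer_status: pd.Series | None = None,
    survival: pd.DataFrame | None = None,
) -> ClusterResult:
    """Embed samples (rows) into 2-d and k-means cluster the projection.

    ``embed="umap"`` uses UMAP(n_neighbors=15, n_components=2,
    metric="euclidean"); ``"pca"`` is the deterministic fallback.
    Optional ``cancer_status`` (per-sample 0/1) adds a chi-square test of
    cluster x status; optional ``survival`` (columns surv_time,
    surv_event indexed by sample) adds a log-rank test across clusters.
    """
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} samples for k={k}")
    if embed == "umap":
        import umap

        reducer = umap.UMAP(
            n_neighbors=n_neighbors, n_components=2, metric="euclidean", random_state=seed
        )
        emb = reducer.fit_transform(X)
    elif embed == "pca":
        emb = PCA(n_components=2, svd_solver="full").fit_transform(X - X.mean(axis=0))
    else:
        raise ValueError(f"unknown embedding {embed!r}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
    labels = pd.Series(km.labels_ + 1, index=features.index, name="cluster")
    embedding = pd.DataFrame(emb, index=features.index, columns=["dim1", "dim2"])

    chi2 = chi2_p = logrank_p = None
    if cancer_status is not None:
        tab = pd.crosstab(labels, cancer_status.loc[labels.index])
        chi2, chi2_p = stats.chi2_contingency(tab)[:2]
        chi2, chi2_p = float(chi2), float(chi2_p)
    if survival is not None:
        from lifelines.statistics import multivariate_logrank_test

        sv = survival.loc[survival.index.intersection(labels.index)].dropna(
            subset=["surv_time"]
        )
        if len(sv) and labels.loc[sv.index].nunique() >= 2:
            res = multivariate_logrank_test(
                sv["surv_time"], labels.loc[sv.index], sv["surv_event"].astype(int)
            )
            logrank_p = float(res.p_value)
    return ClusterResult(
        embedding=embedding, labels=labels, k=k, method=embed,
        chi2=chi2, chi2_p=chi2_p, logrank_p=logrank_p,
    )


# ---------------------------------------------------------------------------
# Youden threshold


@dataclass(frozen=True)
class YoudenResult:
    threshold: float
    j: float
    sensitivity: float
    specificity: float
    ppv: float


def youden_threshold(scores, labels, reference_spec: float | None = None) -> YoudenResult:
    """Operating threshold maximizing Youden's J = sens + spec - 1.

    Candidates are the observed score values (predict positive when
    score >= threshold); ties on J resolve to the smaller threshold.
    ``reference_spec``, if given, instead selects the smallest threshold
    achieving at least that specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pos, neg = int((y == 1).sum()), int((y == 0).sum())
    best = None
    # J compared via the integer quantity tp*neg - fp*pos (== J*pos*neg),
    # so exact ties resolve deterministically to the smaller threshold
    for t in np.unique(s):  # ascending
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        j_num = tp * neg - fp * pos
        spec = 1 - fp / neg
        if reference_spec is not None:
            if spec >= reference_spec and best is None:
                best = (j_num, t, tp, fp)
        elif best is None or j_num > best[0]:
            best = (j_num, t, tp, fp)
    if best is None:
        raise ValueError(f"no threshold reaches specificity {reference_spec}")
    j_num, t, tp, fp = best
    sens = tp / pos
    spec = 1 - fp / neg
    ppv = tp / (tp + fp) if tp + fp else np.nan
    return YoudenResult(
        threshold=float(t), j=float(j_num / (pos * neg)), sensitivity=float(sens),
        specificity=float(spec), ppv=float(ppv),
    )


# ---------------------------------------------------------------------------
# risk model


def _auc_ci(y, s, metric, n_boot, rng):
    """Stratified bootstrap percentile CI."""
    y = np.asarray(y)
    s = np.asarray(s)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(idx_pos, size=len(idx_pos), replace=True)
        ineg = rng.choice(idx_neg, size=len(idx_neg), replace=True)
        idx = np.concatenate([ip, ineg])
        vals[b] = metric(y[idx], s[idx])
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


@dataclass
class RiskModelReport:
    """Fitted risk model: scores, discrimination and operating point."""

    best_mtry: int
    cv_auroc: float
    scores: dict[str, pd.Series]  # split -> per-sample risk score in [0, 1]
    auroc: dict[str, float]
    auroc_ci: dict[str, tuple[float, float]]
    auprc: dict[str, float]
    auprc_ci: dict[str, tuple[float, float]]
    youden: YoudenResult
    threshold_split: str
    roles: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "best_mtry": self.best_mtry,
            "cv_auroc": self.cv_auroc,
            "auroc": self.auroc,
            "auroc_ci": {k: list(v) for k, v in self.auroc_ci.items()},
            "auprc": self.auprc,
            "auprc_ci": {k: list(v) for k, v in self.auprc_ci.items()},
            "threshold": self.youden.threshold,
            "sensitivity": self.youden.sensitivity,
            "specificity": self.youden.specificity,
            "ppv": self.youden.ppv,
            "scores": {k: v.round(6).to_dict() for k, v in self.scores.items()},
        }

    def summary(self) -> str:
        lines = [
            f"random-forest cancer risk score (mtry={self.best_mtry}, "
            f"CV AUROC={self.cv_auroc:.3f})"
        ]
        for split in self.auroc:
            lo, hi = self.auroc_ci[split]
            plo, phi = self.auprc_ci[split]
            lines.append(
                f"  {split}: AUROC {self.auroc[split]:.3f} ({lo:.3f}-{hi:.3f}), "
                f"AUPRC {self.auprc[split]:.3f} ({plo:.3f}-{phi:.3f})"
            )
        y = self.youden
        lines.append(
            f"  Youden threshold ({self.threshold_split}): {y.threshold:.3f} "
            f"(sens {y.sensitivity:.3f}, spec {y.specificity:.3f}, ppv {y.ppv:.3f})"
        )
        return "\n".join(lines)


class CancerRiskModel:
    """Random-forest cancer risk score over cis-CSCE methylation.

    The external validation cohort trains the model (repeated
    stratified 5-fold CV tuning mtry by grid search); the internal
    validation and discovery cohorts are scored as validation and test
    sets.  Prediction probabilities are the risk scores.

    Parameters
    ----------
    train, validation, test : (X, y) tuples
        Feature DataFrames (samples x probes, identical columns) and
        binary outcome Series.
    mtry_grid : list of int, optional
        Default {sqrt(p)/2, sqrt(p), 2 sqrt(p)} clipped to [1, p].
    """

    def __init__(
        self,
        train,
        validation,
        test,
        cv_folds: int = 5,
        cv_repeats: int = 5,
        mtry_grid: list[int] | None = None,
        n_estimators: int = 500,
        n_bootstrap: int = 2000,
    ):
        self.train, self.validation, self.test = train, validation, test
        cols = list(train[0].columns)
        for name, (X, y) in (("validation", validation), ("test", test)):
            if list(X.columns) != cols:
                raise ValueError(f"feature columns of {name} set do not match training set")
            if pd.Series(y).nunique() < 2:
                raise ValueError(f"outcome is constant in the {name} set")
        if pd.Series(train[1]).nunique() < 2:
            raise ValueError("outcome is constant in the training set")
        p = len(cols)
        if mtry_grid is None:
            root = int(np.sqrt(p))
            mtry_grid = sorted({max(1, root // 2), max(1, root), min(p, max(1, 2 * root))})
        self.mtry_grid = [int(m) for m in mtry_grid]
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.n_estimators = n_estimators
        self.n_bootstrap = n_bootstrap

    def fit(self, seed: int = 0) -> RiskModelReport:
        Xtr, ytr = self.train
        cv = RepeatedStratifiedKFold(
            n_splits=self.cv_folds, n_repeats=self.cv_repeats, random_state=seed
        )
        grid = GridSearchCV(
            RandomForestClassifier(n_estimators=self.n_estimators, random_state=seed),
            param_grid={"max_features": self.mtry_grid},
            scoring="roc_auc",
            cv=cv,
            n_jobs=1,
        )
        grid.fit(Xtr.to_numpy(), np.asarray(ytr, dtype=int))
        model = grid.best_estimator_

        rng = np.random.default_rng(seed)
        scores, auroc, auroc_ci, auprc, auprc_ci = {}, {}, {}, {}, {}
        splits = {"train": self.train, "validation": self.validation, "test": self.test}
        for split in ("validation", "test"):
            X, y = splits[split]
            s = model.predict_proba(X.to_numpy())[:, 1]
            yv = np.asarray(y, dtype=int)
            scores[split] = pd.Series(s, index=X.index, name="risk_score")
            auroc[split] = float(roc_auc_score(yv, s))
            auprc[split] = float(average_precision_score(yv, s))
            auroc_ci[split] = _auc_ci(yv, s, roc_auc_score, self.n_bootstrap, rng)
            auprc_ci[split] = _auc_ci(yv, s, average_precision_score, self.n_bootstrap, rng)
        yd = youden_threshold(scores["test"], np.asarray(splits["test"][1], dtype=int))
        return RiskModelReport(
            best_mtry=int(grid.best_params_["max_features"]),
            cv_auroc=float(grid.best_score_),
            scores=scores,
            auroc=auroc,
            auroc_ci=auroc_ci,
            auprc=auprc,
            auprc_ci=auprc_ci,
            youden=yd,
            threshold_split="test",
            roles={"train": "external", "validation": "internal", "test": "discovery"},
        )
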