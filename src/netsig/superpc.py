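"""Supervised principal components for survival (statsmodels-style API).

The model screens features (network modules, or genes) by a univariate Cox
score statistic, keeps those whose |score| passes a threshold chosen by
cross-validation, extracts principal components of the standardized retained
submatrix, and relates each component to survival through a Cox model. New
cohorts are scored by projecting onto the stored loadings after
standardizing with the *training* center and scale, either continuously
(per-sample component scores) or discretely (two groups split at the
training-score median of a chosen component).

Usage::

    model = SuperPC(module_matrix, time, event)
    theta, cv = model.select_threshold_cv(seed=0)
    res = model.fit(threshold=theta)
    print(res.summary())
    scores = res.predict_continuous(validation_matrix)
    groups = res.predict_discrete(validation_matrix, component=2)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .modules import ModuleExpressionMatrix
from .survival import CoxFit, cox_fit
from .survival import _breslow_quantities, _prepare

__all__ = ["SuperPC", "SuperPCResults", "cox_univariate_score"]


def cox_univariate_score(x, time, event) -> float:
    """Standardized Cox score statistic U(0)/sqrt(I(0)) for one covariate.

    Breslow handling of ties. The sign is positive when larger ``x``
    associates with earlier events (higher hazard). Requires >= 2 events and
    a nonconstant ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant covariate: score undefined")
    X, t, e, _ = _prepare(x, time, event)
    if e.sum() < 2:
        raise ValueError("need at least 2 observed events")
    _, U, I = _breslow_quantities(X, t, e, np.zeros(1))
    if I[0, 0] <= 0:
        raise ValueError("zero information: score undefined")
    return float(U[0] / np.sqrt(I[0, 0]))


def _scores_at_zero(values: np.ndarray, time, event) -> np.ndarray:
    """Vectorized U(0)/sqrt(I(0)) for every row of a features x samples matrix.

    Breslow ties. Constant rows (or rows with zero information) get NaN.
    """
    X = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = X.shape[1]
    order = np.argsort(time, kind="stable")
    X = X[:, order]
    time = time[order]
    event = event[order]
    # suffix sums over the risk sets (time >= t)
    rev1 = np.cumsum(X[:, ::-1], axis=1)[:, ::-1]
    rev2 = np.cumsum((X ** 2)[:, ::-1], axis=1)[:, ::-1]
    event_times = np.unique(time[event == 1])
    starts = np.searchsorted(time, event_times, side="left")
    U = np.zeros(X.shape[0])
    I = np.zeros(X.shape[0])
    for t, i0 in zip(event_times, starts):
        d_mask = (time == t) & (event == 1)
        d = int(d_mask.sum())
        S0 = n - i0
        m1 = rev1[:, i0] / S0
        m2 = rev2[:, i0] / S0
        U += X[:, d_mask].sum(axis=1) - d * m1
        I += d * (m2 - m1 ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = U / np.sqrt(I)
    scores[I <= 0] = np.nan
    constant = np.all(X == X[:, :1], axis=1)
    scores[constant] = np.nan
    return scores


def _as_feature_frame(M) -> pd.DataFrame:
    """Features x samples DataFrame from a ModuleExpressionMatrix or frame."""
    if isinstance(M, ModuleExpressionMatrix):
        return M.to_frame()
    if isinstance(M, pd.DataFrame):
        return M
    raise TypeError("expected ModuleExpressionMatrix or features x samples DataFrame")


def _stratified_folds(event: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by event status (>= 1 event per fold)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if int(event.sum()) < folds:
        raise ValueError("fewer events than folds: cannot stratify")
    assign = np.empty(len(event), dtype=int)
    for value in (1, 0):
        idx = np.where(event == value)[0]
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


@dataclass
class SuperPCResults:
    """Fitted supervised-PC survival model.

    ``loadings`` has one orthonormal column per component over the retained
    features; ``train_scores`` are the training samples projected onto them;
    ``component_fits`` holds one univariate Cox fit per component.
    """

    feature_ids: list[str]
    feature_scores: np.ndarray
    threshold: float
    retained: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    n_components: int
    train_scores: np.ndarray
    component_fits: list[CoxFit]
    discrete_cutpoints: np.ndarray
    cv_table: pd.DataFrame | None = None

    # ------------------------------------------------------------------
    def predict_continuous(self, M_new) -> pd.DataFrame:
        """Project new samples onto the training loadings.

        New features are standardized with the *training* center/scale. All
        retained features must be present; missing ones raise an error that
        lists them.
        """
        frame = _as_feature_frame(M_new)
        missing = [f for f in self.retained if f not in frame.index]
        if missing:
            raise ValueError(f"missing retained features: {missing}")
        X = frame.loc[self.retained].to_numpy(dtype=float)
        Xs = (X - self.center[:, None]) / self.scale[:, None]
        scores = Xs.T @ self.loadings
        cols = [f"PC{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(scores, index=frame.columns, columns=cols)

    def predict_discrete(self, M_new, component: int = 1) -> pd.Series:
        """Two-group prediction on one component.

        The continuous score is dichotomized at the stored training-median
        cutpoint; scores exactly at the cutpoint go to "low".
        """
        if not 1 <= component <= self.n_components:
            raise ValueError(f"component must be in 1..{self.n_components}")
        scores = self.predict_continuous(M_new).iloc[:, component - 1]
        cut = self.discrete_cutpoints[component - 1]
        return pd.Series(np.where(scores > cut, "high", "low"),
                         index=scores.index, name=f"PC{component}_group")

    def component_table(self) -> pd.DataFrame:
        """Per-component HR, 95% CI and Wald P of the training Cox fits."""
        rows = []
        for k, fit in enumerate(self.component_fits, start=1):
            ci = fit.ci95[0]
            rows.append({
                "component": f"PC{k}",
                "coef": fit.coef[0],
                "HR": fit.hr[0],
                "CI95_low": ci[0],
                "CI95_high": ci[1],
                "P": fit.wald_p[0],
            })
        return pd.DataFrame(rows).set_index("component")

    def summary(self) -> str:
        lines = [
            "Supervised principal components survival model",
            f"  features scored: {len(self.feature_ids)}",
            f"  threshold: {self.threshold:.4g}  "
            f"(retained {len(self.retained)}: {', '.join(self.retained)})",
            f"  components: {self.n_components}",
            "",
            self.component_table().to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "feature_ids": self.feature_ids,
            "feature_scores": self.feature_scores.tolist(),
            "threshold": self.threshold,
            "retained": self.retained,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "n_components": self.n_components,
            "discrete_cutpoints": self.discrete_cutpoints.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SuperPCResults":
        d = json.loads(text)
        return cls(
            feature_ids=d["feature_ids"],
            feature_scores=np.asarray(d["feature_scores"], dtype=float),
            threshold=float(d["threshold"]),
            retained=d["retained"],
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            n_components=int(d["n_components"]),
            train_scores=np.empty((0, int(d["n_components"]))),
            component_fits=[],
            discrete_cutpoints=np.asarray(d["discrete_cutpoints"], dtype=float),
        )


class SuperPC:
    """Supervised principal components model for right-censored survival.

    Parameters
    ----------
    M : ModuleExpressionMatrix or DataFrame
        Features x samples matrix (module scores, or genes for a gene-level
        analysis).
    time, event : arrays aligned to the samples.
    """

    def __init__(self, M, time, event):
        self.frame = _as_feature_frame(M)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if len(self.time) != self.frame.shape[1] or len(self.event) != len(self.time):
            raise ValueError("time/event length must match the number of samples")
        self.feature_ids = [str(i) for i in self.frame.index]

    # ------------------------------------------------------------------
    def feature_scores(self, frame: pd.DataFrame | None = None,
                       time=None, event=None) -> np.ndarray:
        """Univariate Cox score per feature; NaN for constant features."""
        frame = self.frame if frame is None else frame
        time = self.time if time is None else time
        event = self.event if event is None else event
        if np.asarray(event).sum() < 2:
            raise ValueError("need at least 2 observed events")
        return _scores_at_zero(frame.to_numpy(dtype=float), time, event)

    @staticmethod
    def _pca(frame: pd.DataFrame, retained: list[str], n_components: int):
        """Center/scale retained rows and return (center, scale, loadings)."""
        X = frame.loc[retained].to_numpy(dtype=float)
        center = X.mean(axis=1)
        scale = X.std(axis=1, ddof=1)
        if np.any(scale <= 0):
            raise ValueError("retained feature with zero variance")
        Xs = (X - center[:, None]) / scale[:, None]
        # samples x features SVD; right singular vectors = feature loadings
        U, s, Vt = np.linalg.svd(Xs.T, full_matrices=False)
        k = min(n_components, Vt.shape[0], Xs.shape[1] - 1)
        if k < 1:
            raise ValueError("degenerate matrix: no principal component available")
        loadings = Vt[:k].T
        # deterministic sign: largest-|loading| entry positive per component
        for c in range(k):
            j = int(np.argmax(np.abs(loadings[:, c])))
            if loadings[j, c] < 0:
                loadings[:, c] = -loadings[:, c]
        return center, scale, loadings

    # ------------------------------------------------------------------
    def select_threshold_cv(self, folds: int = 10, grid=None,
                            cv_components: int = 1, seed: int = 0):
        """Choose the screening threshold by stratified k-fold CV.

        For each candidate threshold the model is refitted on the training
        folds, held-out samples are projected, and the partial-likelihood-
        ratio statistic of the held-out Cox fit on the leading
        ``cv_components`` component(s) is recorded; the threshold maximizing
        the mean CV statistic wins, ties
        going to the smaller threshold (more features). The default grid is
        20 values equally spaced between the smallest and largest |feature
        score| (the spacing the reference supervised-PC implementation
        uses); candidates retaining no feature in some training fold are
        skipped.

        Returns ``(threshold, cv_table)``.
        """
        rng = np.random.default_rng(seed)
        scores = self.feature_scores()
        finite = np.abs(scores[np.isfinite(scores)])
        if finite.size == 0:
            raise ValueError("no scorable features")
        if grid is None:
            grid = np.unique(np.linspace(finite.min(), finite.max(), 20))
        grid = np.sort(np.asarray(grid, dtype=float))
        assign = _stratified_folds(self.event, folds, rng)

        # per-fold feature scores do not depend on the threshold: compute once
        fold_data = []
        for f in range(folds):
            train = assign != f
            test = ~train
            tr_frame = self.frame.iloc[:, np.where(train)[0]]
            te_frame = self.frame.iloc[:, np.where(test)[0]]
            tr_scores = self.feature_scores(tr_frame, self.time[train],
                                            self.event[train])
            fold_data.append((train, test, tr_frame, te_frame, tr_scores))

        results = []
        for theta in grid:
            fold_stats = []
            usable = True
            for train, test, tr_frame, te_frame, tr_scores in fold_data:
                retained = [self.feature_ids[i] for i in range(len(tr_scores))
                            if np.isfinite(tr_scores[i]) and abs(tr_scores[i]) >= theta]
                if not retained:
                    usable = False
                    break
                try:
                    center, scale, loadings = self._pca(tr_frame, retained,
                                                        cv_components)
                    Xte = te_frame.loc[retained].to_numpy(dtype=float)
                    Zte = ((Xte - center[:, None]) / scale[:, None]).T @ loadings
                    fit = cox_fit(Zte, self.time[test], self.event[test])
                    fold_stats.append(fit.lr_stat)
                except (ValueError, np.linalg.LinAlgError):
                    continue  # degenerate fold: contributes nothing
            if not usable or not fold_stats:
                continue
            results.append((float(theta), len(fold_stats),
                            float(np.mean(fold_stats))))
        if not results:
            raise ValueError("no candidate threshold retained features in every fold")
        cv_table = pd.DataFrame(results, columns=["threshold", "folds_used", "cv_stat"])
        # argmax with ties to the smaller threshold: strict improvement only
        best = cv_table.iloc[0]
        for _, row in cv_table.iterrows():
            if row["cv_stat"] > best["cv_stat"]:
                best = row
        return float(best["threshold"]), cv_table

    # ------------------------------------------------------------------
    def fit(self, threshold: float, n_components: int = 3) -> SuperPCResults:
        """Fit at a fixed screening threshold.

        Retains features with |score| >= threshold (inclusive), standardizes
        them by their training mean/SD, extracts the top right-singular
        vectors, and fits one univariate Cox model per component on the
        training component scores.
        """
        scores = self.feature_scores()
        retained = [self.feature_ids[i] for i in range(len(scores))
                    if np.isfinite(scores[i]) and abs(scores[i]) >= threshold]
        if not retained:
            raise ValueError(f"no feature passes |score| >= {threshold}")
        center, scale, loadings = self._pca(self.frame, retained, n_components)
        k = loadings.shape[1]
        if k < n_components:
            warnings.warn(f"only {k} component(s) available; requested {n_components}")
        X = self.frame.loc[retained].to_numpy(dtype=float)
        Xs = (X - center[:, None]) / scale[:, None]
        train_scores = Xs.T @ loadings
        fits = [cox_fit(train_scores[:, c], self.time, self.event)
                for c in range(k)]
        cutpoints = np.median(train_scores, axis=0)
        return SuperPCResults(
            feature_ids=list(self.feature_ids),
            feature_scores=scores,
            threshold=float(threshold),
            retained=retained,
            center=center,
            scale=scale,
            loadings=loadings,
            n_components=k,
            train_scores=train_scores,
            component_fits=fits,
            discrete_cutpoints=cutpoints,
        )
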