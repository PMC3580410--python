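"""Cox proportional hazards, Kaplan-Meier estimation and the log-rank test.

The Cox model is fitted by Newton-Raphson maximization of the Breslow
partial likelihood (ties contribute the full risk-set denominator once per
event). Breslow handling is the package default because the score test of a
two-group covariate then coincides exactly with the log-rank statistic on
tie-free data, which cross-validates the two implementations; Efron tie
handling is available behind a flag.

Reported per covariate: coefficient, SE (inverse observed information),
HR = exp(coef), 95% Wald CI = exp(coef +/- 1.96 SE), and the two-sided Wald
P-value. Note that a "hazard ratio" is always positive; a negative value in
that position in legacy reports can only be a coefficient, so both are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CoxFit", "KMResult", "cox_fit", "cox_score_test",
           "kaplan_meier", "kaplan_meier_logrank", "median_split"]

Z95 = 1.959963984540054  # normal 97.5% quantile for Wald intervals


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n: int
    n_events: int
    warning: str | None = None

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.coef - Z95 * self.se)
        hi = np.exp(self.coef + Z95 * self.se)
        return np.column_stack([lo, hi])

    @property
    def wald_z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.wald_z))

    @property
    def lr_stat(self) -> float:
        """Partial-likelihood-ratio statistic vs the null model."""
        return 2 * (self.loglik - self.loglik_null)

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame({
            "coef": self.coef,
            "se": self.se,
            "HR": self.hr,
            "CI95_low": ci[:, 0],
            "CI95_high": ci[:, 1],
            "P": self.wald_p,
        }, index=self.names)


def _prepare(X, time, event):
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(time) == len(event) == X.shape[0]):
        raise ValueError("X, time and event must have matching lengths")
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order], names


def _breslow_quantities(X, time, event, beta):
    """Log partial likelihood, score vector and observed information.

    Inputs must be sorted by ascending time. Risk sets are accumulated from
    the largest time downward so each distinct event time is O(p^2).
    """
    n, p = X.shape
    eta = X @ beta
    # guard against overflow in degenerate (monotone-likelihood) fits
    w = np.exp(np.clip(eta, -500, 500))
    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = n - 1
    while i >= 0:
        t = time[i]
        j = i
        while j >= 0 and time[j] == t:
            S0 += w[j]
            S1 += w[j] * X[j]
            S2 += w[j] * np.outer(X[j], X[j])
            j -= 1
        # events at this time
        ev = [k for k in range(j + 1, i + 1) if event[k] == 1]
        d = len(ev)
        if d:
            xs = X[ev].sum(axis=0)
            ll += float(eta[ev].sum() - d * np.log(S0))
            m1 = S1 / S0
            U += xs - d * m1
            I += d * (S2 / S0 - np.outer(m1, m1))
        i = j
    return ll, U, I


def _efron_quantities(X, time, event, beta):
    """Efron tie-corrected log partial likelihood, score and information."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(np.clip(eta, -500, 500))
    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    for t in np.unique(time[event == 1]):
        risk = time >= t
        ev = (time == t) & (event == 1)
        d = int(ev.sum())
        S0 = w[risk].sum()
        S1 = (w[risk, None] * X[risk]).sum(axis=0)
        S2 = np.einsum("i,ij,ik->jk", w[risk], X[risk], X[risk])
        s0d = w[ev].sum()
        s1d = (w[ev, None] * X[ev]).sum(axis=0)
        s2d = np.einsum("i,ij,ik->jk", w[ev], X[ev], X[ev])
        ll += float(eta[ev].sum())
        for r in range(d):
            f = r / d
            a0 = S0 - f * s0d
            a1 = S1 - f * s1d
            a2 = S2 - f * s2d
            ll -= float(np.log(a0))
            U -= a1 / a0
            I += a2 / a0 - np.outer(a1 / a0, a1 / a0)
        U += X[ev].sum(axis=0)
    return ll, U, I


def cox_fit(X, time, event, ties: str = "breslow",
            max_iter: int = 50, tol: float = 1e-8) -> CoxFit:
    """Fit a Cox proportional hazards model by Newton-Raphson.

    Convergence when max |delta coef| < ``tol`` (default 1e-8) or after
    ``max_iter`` (default 50) iterations. Monotone partial likelihood
    (perfect separation) yields a non-converged fit flagged with a warning.
    Requires >= 2 observed events and a full-rank design.
    """
    X, time, event, names = _prepare(X, time, event)
    n, p = X.shape
    if event.sum() < 2:
        raise ValueError("need at least 2 observed events")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < p:
        raise ValueError("design matrix is rank deficient (constant or collinear covariate)")
    quantities = _breslow_quantities if ties == "breslow" else _efron_quantities
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    beta = np.zeros(p)
    ll, U, I = quantities(X, time, event, beta)
    ll_null = ll
    converged = False
    warning = None
    for _ in range(max_iter):
        try:
            delta = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            warning = "singular information matrix"
            break
        # step-halving keeps the likelihood monotone
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, U_new, I_new = quantities(X, time, event, cand)
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        beta, ll, U, I = cand, ll_new, U_new, I_new
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    if not converged and warning is None:
        warning = "did not converge (possible monotone likelihood / separation)"
    if np.max(np.abs(beta)) > 50:
        warning = "extreme coefficients: likely perfect separation"
        converged = False
    if warning:
        warnings.warn(f"cox_fit: {warning}")
    cov = np.linalg.pinv(I)
    se = np.sqrt(np.maximum(np.diag(cov), 0))
    return CoxFit(names=names, coef=beta, se=se, loglik=ll, loglik_null=ll_null,
                  converged=converged, n=n, n_events=int(event.sum()),
                  warning=warning)


def cox_score_test(X, time, event) -> tuple[float, float]:
    """Cox score (Rao) test at beta = 0, Breslow ties.

    Returns ``(chi2, p)`` with ``chi2 = U' I^-1 U`` on p degrees of freedom.
    For a two-group indicator covariate on tie-free data this equals the
    log-rank chi-square exactly.
    """
    X, time, event, names = _prepare(X, time, event)
    _, U, I = _breslow_quantities(X, time, event, np.zeros(X.shape[1]))
    chi2 = float(U @ np.linalg.solve(I, U))
    return chi2, float(stats.chi2.sf(chi2, X.shape[1]))


@dataclass
class KMResult:
    """Per-group Kaplan-Meier step functions with a 2-group log-rank test."""

    curves: dict  # group -> DataFrame(time, survival, at_risk, events)
    logrank_chi2: float
    logrank_p: float

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for g, df in self.curves.items():
            df = df.copy()
            df.insert(0, "group", g)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit estimator. Rows at each distinct event time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    for t in np.unique(time[event == 1]):
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1 - d / n_at_risk
        rows.append((t, s, n_at_risk, d))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk", "events"])


def kaplan_meier_logrank(time, event, group) -> KMResult:
    """KM curves per group plus the two-group log-rank test (1 df).

    The log-rank variance uses the standard hypergeometric form
    ``d (n1/n)(n2/n)(n-d)/(n-1)`` summed over distinct event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = sorted(pd.unique(group).tolist())
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {len(labels)}")
    for lab in labels:
        if (group == lab).sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
    curves = {
        lab: kaplan_meier(time[group == lab], event[group == lab])
        for lab in labels
    }
    g1 = group == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e ** 2 / var
        p = float(stats.chi2.sf(chi2, 1))
    return KMResult(curves=curves, logrank_chi2=float(chi2), logrank_p=max(p, np.finfo(float).tiny))


def median_split(score) -> np.ndarray:
    """Split samples at the median score: > median -> "high", <= median -> "low"."""
    score = np.asarray(score, dtype=float)
    if len(score) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(np.median(score))
    if np.all(score == score[0]):
        raise ValueError("all scores identical: no split possible")
    return np.where(score > med, "high", "low")


def plot_km(result: KMResult, path=None, title: str = ""):
    """Step plot of the KM curves (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, df in result.curves.items():
        t = np.concatenate([[0.0], df["time"].to_numpy()])
        s = np.concatenate([[1.0], df["survival"].to_numpy()])
        ax.step(t, s, where="post", label=str(lab))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(title or f"log-rank chi2={result.logrank_chi2:.2f}, "
                          f"p={result.logrank_p:.2e}")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
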