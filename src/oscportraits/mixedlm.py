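"""Gaussian random-intercept linear model: the shared estimation engine.

Every predictive analysis in this package (effective connectivity, pairwise
category discrimination, behavior prediction) fits the same model

    y_ij = beta0 + beta1 . x_ij + u_j + e_ij,
    e_ij ~ N(0, sigma_e^2),   u_j ~ N(0, tau^2),

with one random intercept u_j per subject j.  The implementation profiles
the likelihood over the variance ratio rho = tau^2 / sigma_e^2: for fixed
rho the generalized least squares problem reduces, via the classical
within-subject partial-demeaning transform, to ordinary least squares on
transformed data, and all sufficient statistics are Gram matrices that can
be updated in O(n_subjects * p^2) per candidate rho.  This makes the
thousands of 47-predictor fits of the connectivity stage cheap while
remaining an exact (restricted) maximum-likelihood estimator; tests verify
agreement with statsmodels' MixedLM.

Notation: for subject j with n_j observations the transform subtracts
theta_j = 1 - 1/sqrt(1 + n_j rho) times the subject mean from every column;
the transformed model is homoscedastic with variance sigma_e^2 and
log|V| picks up sum_j log(1 + n_j rho).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg
from scipy.optimize import minimize_scalar

__all__ = ["MixedModelFit", "fit_lmm", "predict_lmm", "GramLMM"]

_RIDGE = 1e-6  # relative ridge added when the normal equations are singular
_LOG_RHO_BOUNDS = (-14.0, 14.0)


@dataclass
class MixedModelFit:
    """Result of a random-intercept fit.

    ``beta1`` is on the scale the model was fitted on: if ``standardize``
    was requested, predictors were z-scored with the stored ``x_mean`` /
    ``x_sd`` (training statistics) and coefficients are per-SD effects,
    comparable across predictors.  Predictions for subjects never seen in
    training use u = 0 (the population intercept).
    """

    beta0: float
    beta1: np.ndarray
    predictor_names: list[str]
    subject_intercepts: dict
    residual_variance: float
    intercept_variance: float
    n_obs: int
    beta_se: np.ndarray
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    ridged: bool = False
    reml: bool = True

    @property
    def tau(self) -> float:
        return float(np.sqrt(self.intercept_variance))

    def confint(self, level: float = 0.95) -> np.ndarray:
        """Normal-approximation confidence intervals for beta1, (p, 2)."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        lo = self.beta1 - z * self.beta_se
        hi = self.beta1 + z * self.beta_se
        return np.column_stack([lo, hi])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "beta0": self.beta0,
            "beta1": self.beta1.tolist(),
            "predictor_names": list(self.predictor_names),
            "subject_intercepts": {str(k): float(v) for k, v in self.subject_intercepts.items()},
            "residual_variance": self.residual_variance,
            "intercept_variance": self.intercept_variance,
            "n_obs": self.n_obs,
            "beta_se": self.beta_se.tolist(),
            "x_mean": None if self.x_mean is None else self.x_mean.tolist(),
            "x_sd": None if self.x_sd is None else self.x_sd.tolist(),
            "ridged": self.ridged,
            "reml": self.reml,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MixedModelFit":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            beta0=d["beta0"],
            beta1=np.asarray(d["beta1"], dtype=float),
            predictor_names=d["predictor_names"],
            subject_intercepts=d["subject_intercepts"],
            residual_variance=d["residual_variance"],
            intercept_variance=d["intercept_variance"],
            n_obs=d["n_obs"],
            beta_se=np.asarray(d["beta_se"], dtype=float),
            x_mean=None if d["x_mean"] is None else np.asarray(d["x_mean"], dtype=float),
            x_sd=None if d["x_sd"] is None else np.asarray(d["x_sd"], dtype=float),
            ridged=d["ridged"],
            reml=d["reml"],
        )


class GramLMM:
    """Sufficient statistics for random-intercept fits over shared columns.

    Holds U = [1 | columns] for one data subset and the per-subject Gram
    corrections; any (response column, predictor columns) pair can then be
    fitted without touching the raw data again.  Used directly by the
    connectivity stage, which fits 48 targets against each other on the
    same bootstrap subsample.
    """

    def __init__(self, columns: np.ndarray, subject_ids) -> None:
        columns = np.asarray(columns, dtype=float)
        if columns.ndim != 2:
            raise ValueError("columns must be 2-D (observations x variables)")
        n = columns.shape[0]
        if n < 2:
            raise ValueError("need at least 2 observations")
        if not np.isfinite(columns).all():
            raise ValueError("non-finite values in design")
        subject_ids = np.asarray(subject_ids)
        if subject_ids.shape != (n,):
            raise ValueError("subject_ids length must match observations")
        self.n = n
        self.U = np.column_stack([np.ones(n), columns])
        self.subjects, inverse = np.unique(subject_ids, return_inverse=True)
        self.inverse = inverse
        self.n_j = np.bincount(inverse).astype(float)
        # Per-subject column sums -> outer-product corrections S_j = n_j m_j m_j^T
        p2 = self.U.shape[1]
        sums = np.zeros((len(self.subjects), p2))
        np.add.at(sums, inverse, self.U)
        means = sums / self.n_j[:, None]
        self.S = np.einsum("j,jp,jq->jpq", self.n_j, means, means)
        self.G0 = self.U.T @ self.U
        self.means = means  # per-subject means of [1 | columns]

    # -- internal ---------------------------------------------------------
    def _gram(self, rho: float) -> np.ndarray:
        c = self.n_j * rho / (1.0 + self.n_j * rho)
        return self.G0 - np.tensordot(c, self.S, axes=1)

    def _solve(self, A, didx, yidx):
        D = A[np.ix_(didx, didx)]
        d = A[didx, yidx]
        yy = A[yidx, yidx]
        ridged = False
        try:
            cf = linalg.cho_factor(D, check_finite=False)
            diag = np.diag(cf[0])
            # near-singular designs factor "successfully" with a tiny pivot
            if diag.min() <= 1e-7 * diag.max():
                raise linalg.LinAlgError("ill-conditioned normal equations")
            logdet_D = 2.0 * np.sum(np.log(diag))
            beta = linalg.cho_solve(cf, d, check_finite=False)
        except linalg.LinAlgError:
            ridged = True
            D = D + _RIDGE * np.trace(D) / len(didx) * np.eye(len(didx))
            cf = linalg.cho_factor(D, check_finite=False)
            logdet_D = 2.0 * np.sum(np.log(np.diag(cf[0])))
            beta = linalg.cho_solve(cf, d, check_finite=False)
        rss = max(float(yy - d @ beta), 1e-300)
        return beta, rss, logdet_D, cf, ridged

    def _criterion(self, rho, didx, yidx, reml):
        A = self._gram(rho)
        beta, rss, logdet_D, _, _ = self._solve(A, didx, yidx)
        pen = float(np.sum(np.log1p(self.n_j * rho)))
        p = len(didx)
        if reml:
            return (self.n - p) * np.log(rss) + pen + logdet_D
        return self.n * np.log(rss) + pen

    # -- public -----------------------------------------------------------
    def fit(self, y_index: int, design_indices, reml: bool = True):
        """Fit column ``y_index`` of U on ``design_indices`` plus intercept.

        Indices are into the *variable* columns (0-based, excluding the
        intercept, which is always included).  Returns a dict of estimates.
        """
        didx = np.concatenate([[0], np.asarray(design_indices, dtype=int) + 1])
        yidx = y_index + 1
        if yidx in didx[1:]:
            raise ValueError("response column cannot also be a predictor")

        if len(self.subjects) > 1:
            obj = lambda lr: self._criterion(np.exp(lr), didx, yidx, reml)
            res = minimize_scalar(obj, bounds=_LOG_RHO_BOUNDS, method="bounded",
                                  options={"xatol": 1e-4})
            rho = float(np.exp(res.x))
            # the tau^2 = 0 boundary: keep it if it beats the interior optimum
            if self._criterion(0.0, didx, yidx, reml) <= res.fun:
                rho = 0.0
        else:
            rho = 0.0

        A = self._gram(rho)
        beta, rss, _, cf, ridged = self._solve(A, didx, yidx)
        p = len(didx)
        dof = self.n - p if reml else self.n
        sigma2 = rss / max(dof, 1)
        tau2 = rho * sigma2
        # BLUP intercepts from raw per-subject residual means
        shrink = self.n_j * rho / (1.0 + self.n_j * rho)
        resid_means = self.means[:, yidx] - self.means[:, didx] @ beta
        u = shrink * resid_means
        cov = linalg.cho_solve(cf, np.eye(p), check_finite=False) * sigma2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return {
            "beta0": float(beta[0]),
            "beta1": beta[1:].copy(),
            "beta_se": se[1:].copy(),
            "sigma2": float(sigma2),
            "tau2": float(tau2),
            "u": {s: float(ui) for s, ui in zip(self.subjects, u)},
            "ridged": ridged,
        }


def fit_lmm(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids,
    predictor_names: list[str] | None = None,
    reml: bool = True,
    standardize: bool = False,
) -> MixedModelFit:
    """Fit the random-intercept model y ~ X with one intercept per subject.

    With a single subject the model degenerates to ordinary least squares
    (tau^2 = 0).  A singular design falls back to a small ridge penalty.
    ``standardize`` z-scores predictors with training statistics so the
    coefficients are per-SD effects.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        X = np.empty((y.size, 0))
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size:
        raise ValueError("X and y have different numbers of observations")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("missing or non-finite values in X or y")
    if predictor_names is None:
        predictor_names = [f"x{i}" for i in range(X.shape[1])]
    if len(predictor_names) != X.shape[1]:
        raise ValueError("predictor_names length mismatch")

    x_mean = x_sd = None
    if standardize and X.shape[1]:
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0, ddof=0)
        x_sd = np.where(x_sd > 0, x_sd, 1.0)
        X = (X - x_mean) / x_sd

    engine = GramLMM(np.column_stack([X, y]), subject_ids)
    p = X.shape[1]
    res = engine.fit(y_index=p, design_indices=np.arange(p), reml=reml)
    return MixedModelFit(
        beta0=res["beta0"],
        beta1=res["beta1"],
        predictor_names=list(predictor_names),
        subject_intercepts=res["u"],
        residual_variance=res["sigma2"],
        intercept_variance=res["tau2"],
        n_obs=y.size,
        beta_se=res["beta_se"],
        x_mean=x_mean,
        x_sd=x_sd,
        ridged=res["ridged"],
        reml=reml,
    )


def predict_lmm(fit: MixedModelFit, X: np.ndarray, subject_ids=None) -> np.ndarray:
    """Predict y-hat = beta0 + beta1 . x + u_j; u = 0 for unseen subjects."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        X = np.empty((0 if X.ndim == 0 else X.shape[0], 0))
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(fit.predictor_names):
        raise ValueError(
            f"expected {len(fit.predictor_names)} predictors, got {X.shape[1]}"
        )
    if fit.x_mean is not None:
        X = (X - fit.x_mean) / fit.x_sd
    yhat = fit.beta0 + X @ fit.beta1
    if subject_ids is not None:
        u = np.array([fit.subject_intercepts.get(s, 0.0) for s in np.asarray(subject_ids)])
        yhat = yhat + u
    return yhat
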