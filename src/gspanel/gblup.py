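"""Linear-kernel GBLUP: REML fitting and held-out prediction.

The model is ``y = X b + u + e`` with ``u ~ N(0, sigma2_u K)`` for a
marker-derived kernel ``K`` and ``e ~ N(0, sigma2_e I)``.  With the
correlation-type kernel ``K = W W' / m`` this is exactly ridge regression on
the standardized markers (RR-BLUP) with penalty ``lambda = m * delta``,
``delta = sigma2_e / sigma2_u`` — an equivalence the test suite checks.

Variance components are estimated by REML on the spectral decomposition of
the training kernel: after rotating by the eigenvectors of ``K`` the
covariance is diagonal in ``delta``, so the restricted likelihood is a cheap
one-dimensional profile in ``log delta`` and is optimized by bounded scalar
search.  Held-out lines are predicted by the conditional mean

    y_hat = X_test b + K_cross (K_train + delta I)^-1 (y - X b),

which coincides with the masked-response joint solve of Henderson's
equations.  Fixed effects are the intercept plus (optionally) one
standardized marker dosage — the route by which stable GWAS hits enter the
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import LineMeans

__all__ = ["ScaledTrait", "GblupModel", "scale_trait", "fit", "fit_with_hit", "predict"]


@dataclass
class ScaledTrait:
    """Line-indexed response centered to mean 0 and scaled to variance 1."""

    values: np.ndarray
    line_ids: list[str]
    center: float
    scale: float

    def back_transform(self, z) -> np.ndarray:
        return np.asarray(z) * self.scale + self.center


def scale_trait(means: LineMeans | "np.ndarray", line_ids=None) -> ScaledTrait:
    """Center to mean 0 and scale to sample variance 1, keeping the constants.

    Accepts a :class:`~gspanel.data.LineMeans` or a plain vector with
    ``line_ids``.  Lines with missing means are dropped.  A constant trait is
    an error (nothing to scale).
    """
    if isinstance(means, LineMeans):
        s = means.means.dropna()
        vals, ids = s.to_numpy(dtype=float), list(s.index)
    else:
        vals = np.asarray(means, dtype=float)
        ids = list(line_ids) if line_ids is not None else [str(i) for i in range(len(vals))]
        keep = ~np.isnan(vals)
        vals, ids = vals[keep], [i for i, k in zip(ids, keep) if k]
    if len(vals) < 2 or np.unique(vals).size < 2:
        raise ValueError("trait is constant (or has < 2 values); cannot scale")
    center = float(vals.mean())
    scale = float(vals.std(ddof=1))
    return ScaledTrait(values=(vals - center) / scale, line_ids=ids,
                       center=center, scale=scale)


@dataclass
class GblupModel:
    """A fitted GBLUP model on a set of training lines."""

    line_ids: list[str]
    sigma2_u: float
    sigma2_e: float
    delta: float  # sigma2_e / sigma2_u
    beta: np.ndarray  # intercept [+ marker coefficient]
    u: np.ndarray  # BLUP breeding values for the training lines
    alpha: np.ndarray = field(repr=False)  # (K + delta I)^-1 (y - X beta)
    marker_center: float | None = None  # standardization constants of the
    marker_scale: float | None = None  # optional fixed-effect marker


def _reml_neg2(log_delta: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = d + delta
    n, p = Xt.shape
    XtWX = Xt.T @ (Xt / w[:, None])
    XtWy = Xt.T @ (yt / w)
    try:
        c = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(XtWX, XtWy)
    rss = yt @ (yt / w) - XtWy @ beta
    if rss <= 0:
        return np.inf
    s2u = rss / (n - p)
    return ((n - p) * np.log(s2u) + np.log(w).sum()
            + 2.0 * np.log(np.diag(c)).sum())


def fit(
    K: np.ndarray,
    y: ScaledTrait,
    line_ids=None,
    covariate: np.ndarray | None = None,
    delta: float | None = None,
) -> GblupModel:
    """Fit GBLUP on the training kernel and response.

    ``K`` must be the training-lines kernel aligned with ``y`` (pass
    ``line_ids`` if ``y`` is a plain :class:`ScaledTrait` whose order already
    matches).  ``covariate`` adds one fixed-effect column (already
    standardized).  ``delta`` fixes the ridge ratio instead of estimating it
    by REML — useful for degenerate checks.
    """
    ids = list(line_ids) if line_ids is not None else list(y.line_ids)
    yv = np.asarray(y.values, dtype=float)
    n = len(yv)
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError(f"kernel shape {K.shape} does not match {n} training lines")
    X = np.ones((n, 1))
    mc = ms = None
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if np.unique(cov).size < 2:
            raise ValueError("fixed-effect marker is constant in the training set")
        X = np.column_stack([X, cov])

    d, U = np.linalg.eigh((K + K.T) / 2.0)
    if d.min() < -1e-8 * max(1.0, d.max()):
        raise ValueError(f"kernel is not PSD (min eigenvalue {d.min():.3e})")
    d = np.maximum(d, 0.0)
    yt, Xt = U.T @ yv, U.T @ X

    if delta is None:
        res = optimize.minimize_scalar(
            _reml_neg2, bounds=(np.log(1e-6), np.log(1e6)), args=(d, yt, Xt),
            method="bounded", options={"xatol": 1e-10},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError(
                "GBLUP REML failed: no finite restricted likelihood on the "
                "delta search interval"
            )
        delta = float(np.exp(res.x))

    w = d + delta
    XtWX = Xt.T @ (Xt / w[:, None])
    XtWy = Xt.T @ (yt / w)
    beta = np.linalg.solve(XtWX, XtWy)
    resid_t = yt - Xt @ beta
    rss = resid_t @ (resid_t / w)
    s2u = float(rss / (n - X.shape[1]))
    alpha = U @ (resid_t / w)  # (K + delta I)^-1 (y - X beta)
    u = K @ alpha
    return GblupModel(
        line_ids=ids, sigma2_u=s2u, sigma2_e=float(s2u * delta), delta=float(delta),
        beta=beta, u=u, alpha=alpha, marker_center=mc, marker_scale=ms,
    )


def fit_with_hit(
    K: np.ndarray,
    y: ScaledTrait,
    marker_dosages: np.ndarray,
    line_ids=None,
) -> GblupModel:
    """Fit GBLUP with one GWAS-hit marker as an extra fixed effect.

    Dosages are standardized by the training-set mean and standard deviation;
    the constants are stored on the model so held-out lines are standardized
    identically at prediction time.
    """
    dos = np.asarray(marker_dosages, dtype=float)
    if np.isnan(dos).any():
        dos = dos.copy()
        dos[np.isnan(dos)] = np.nanmean(dos)
    center, scale = float(dos.mean()), float(dos.std(ddof=1))
    if scale <= 0:
        raise ValueError("fixed-effect marker is monomorphic in the training set")
    model = fit(K, y, line_ids=line_ids, covariate=(dos - center) / scale)
    model.marker_center, model.marker_scale = center, scale
    return model


def predict(
    model: GblupModel,
    K_cross: np.ndarray,
    marker_dosages: np.ndarray | None = None,
) -> np.ndarray:
    """Predict held-out lines from their kernel rows against the training set.

    ``K_cross`` has one row per test line and one column per training line
    (training order must match the fitted model).  When the model carries a
    fixed-effect marker, ``marker_dosages`` for the test lines are required
    and are standardized with the training constants.
    """
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != len(model.line_ids):
        raise ValueError(
            f"K_cross has {K_cross.shape[1]} columns but the model was trained "
            f"on {len(model.line_ids)} lines"
        )
    yhat = np.full(K_cross.shape[0], model.beta[0]) + K_cross @ model.alpha
    if len(model.beta) > 1:
        if marker_dosages is None:
            raise ValueError("model has a fixed-effect marker: pass marker_dosages")
        dos = np.asarray(marker_dosages, dtype=float)
        if np.isnan(dos).any():
            dos = np.where(np.isnan(dos), model.marker_center, dos)
        z = (dos - model.marker_center) / model.marker_scale
        yhat = yhat + model.beta[1] * z
    return yhat
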