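"""Calibration from estimated TGF to tumor fraction (TF).

The estimated tumor genome fraction systematically depends on how aberrant
the underlying genome is and on sequencing coverage.  A titration experiment
with cell lines of different ploidies provides paired (true TF, estimated
TGF) observations; these are modelled on the logit scale with a random
intercept per cell line and per-observation weights derived from a
coverage-to-mean-absolute-error curve:

    logit(tgf*) = a + b * logit(tf*) + u_cellline + eps,
    u ~ N(0, sigma_u^2),    eps_i ~ N(0, sigma_e^2 / w_i),
    w_i = 1 / mae(coverage_i)   (or 1 / mae^2, configurable)

where ``p* = clamp(p, eps, 1 - eps)`` guards the boundary proportions.  The
fit is restricted maximum likelihood (profile REML over the variance ratio
``theta = sigma_u^2 / sigma_e^2``).

Prediction of the TF of a new sample (a CTM that belongs to no calibration
cell line) inverts the population-level line (u = 0): the point estimate is
``x = (logit(tgf) - a) / b`` back-transformed, and intervals invert the
two-sided confidence/prediction band of the forward model numerically
(Fieller-style), falling back to the delta method when the band does not
bracket.  The prediction band folds in ``sigma_u^2`` (the new sample's
unknown cell-line-like offset) and the new observation's residual variance
``sigma_e^2 / w``.

The default MAE anchors bundled here are synthetic package defaults chosen
to span the low-pass coverage regime (0.02-0.09x); replace them with an
empirically measured error table for production use.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit, logit
from scipy.stats import norm

DEFAULT_LOGIT_EPS = 0.005

# Synthetic default anchors (coverage x, mean absolute error); PLACEHOLDER
# shape: error shrinks with depth.  Not taken from any published error table.
DEFAULT_MAE_ANCHORS = ((0.01, 0.10), (0.025, 0.08), (0.05, 0.06), (0.10, 0.04))


@dataclass(frozen=True)
class MAECurve:
    """Piecewise-linear mean-absolute-error vs coverage curve."""

    anchors: tuple[tuple[float, float], ...] = DEFAULT_MAE_ANCHORS

    def __post_init__(self):
        if not self.anchors:
            raise ValueError("empty MAE curve")
        cov = [a[0] for a in self.anchors]
        mae = [a[1] for a in self.anchors]
        if any(c <= 0 for c in cov) or any(m <= 0 for m in mae):
            raise ValueError("coverages and MAE values must be positive")
        if any(b <= a for a, b in zip(cov, cov[1:])):
            raise ValueError("coverages must be strictly increasing")


def interpolate_mae(coverage: float, curve: MAECurve) -> float:
    """Linear interpolation between anchors; clamped outside the range."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    cov = np.array([a[0] for a in curve.anchors])
    mae = np.array([a[1] for a in curve.anchors])
    return float(np.interp(coverage, cov, mae))


def _weights(coverages: np.ndarray, curve: MAECurve, rule: str) -> np.ndarray:
    mae = np.array([interpolate_mae(c, curve) for c in coverages])
    if rule == "inv":
        return 1.0 / mae
    if rule == "inv_sq":
        return 1.0 / mae**2
    raise ValueError(f"unknown weight rule {rule!r}")


@dataclass
class CalibrationModel:
    """Fitted logit-scale weighted mixed calibration."""

    intercept: float
    slope: float
    sigma_u2: float
    sigma_e2: float
    cov_beta: np.ndarray          # 2x2 covariance of (intercept, slope)
    blups: dict[str, float]
    logit_eps: float
    weight_rule: str
    mae_curve: MAECurve
    n: int
    converged: bool
    reml_loglik: float = float("nan")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "intercept": self.intercept,
            "slope": self.slope,
            "sigma_u2": self.sigma_u2,
            "sigma_e2": self.sigma_e2,
            "cov_beta": np.asarray(self.cov_beta).tolist(),
            "blups": self.blups,
            "logit_eps": self.logit_eps,
            "weight_rule": self.weight_rule,
            "mae_anchors": [list(a) for a in self.mae_curve.anchors],
            "n": self.n,
            "converged": self.converged,
            "reml_loglik": self.reml_loglik,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            slope=d["slope"],
            sigma_u2=d["sigma_u2"],
            sigma_e2=d["sigma_e2"],
            cov_beta=np.array(d["cov_beta"]),
            blups=d["blups"],
            logit_eps=d["logit_eps"],
            weight_rule=d["weight_rule"],
            mae_curve=MAECurve(tuple(tuple(a) for a in d["mae_anchors"])),
            n=d["n"],
            converged=d["converged"],
            reml_loglik=d.get("reml_loglik", float("nan")),
        )


@dataclass(frozen=True)
class TFPrediction:
    tf_hat: float
    ci_low: float
    ci_high: float
    pi_low: float
    pi_high: float
    tgf: float
    weight: float


def clamp_proportion(p, eps: float = DEFAULT_LOGIT_EPS):
    return np.clip(p, eps, 1.0 - eps)


def _reml_profile(theta: float, y, X, groups_idx, n_groups, w):
    """Profiled REML pieces for variance ratio theta = sigma_u^2 / sigma_e^2.

    V0 = diag(1/w) + theta * Z Z' is inverted via Woodbury on the group
    indicator Z, which keeps everything O(n) for the random-intercept model.
    """
    n, p = X.shape
    # Woodbury on the group indicator Z: V0 = diag(1/w) + theta Z Z', so
    # V0^{-1} x = w*x - w * (theta / (1 + theta * sum_g w)) * sum_g(w*x)
    group_w = np.bincount(groups_idx, weights=w, minlength=n_groups)
    m_diag = 1.0 + theta * group_w
    minv = theta / m_diag

    def v0inv(x):
        if x.ndim == 2:
            return np.column_stack([v0inv(x[:, k]) for k in range(x.shape[1])])
        wx = w * x
        s = np.bincount(groups_idx, weights=wx, minlength=n_groups)
        return wx - w * minv[groups_idx] * s[groups_idx]

    ViX = v0inv(X)
    Viy = v0inv(y)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    beta = np.linalg.solve(XtViX, XtViy)
    resid = y - X @ beta
    quad = float(resid @ v0inv(resid))
    sigma_e2 = max(quad / (n - p), 0.0)
    # log|V0| = -sum(log w) + sum(log m_diag); the log of sigma_e2 is floored
    # so an exactly-interpolating (zero-residual) fit stays finite
    logdet_v0 = -np.sum(np.log(w)) + np.sum(np.log(m_diag))
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    reml = -0.5 * (
        (n - p) * np.log(max(sigma_e2, 1e-300))
        + logdet_v0
        + logdet_xvx
        + (n - p)
    )
    return reml, beta, sigma_e2, XtViX, v0inv, resid


def fit_calibration(
    samples,
    curve: MAECurve | None = None,
    logit_eps: float = DEFAULT_LOGIT_EPS,
    weight_rule: str = "inv",
) -> CalibrationModel:
    """Fit the weighted logit-scale random-intercept calibration.

    ``samples`` is an iterable of ``(true_tf, tgf, coverage, cell_line)``
    tuples or a DataFrame with those columns.  Requires at least two cell
    lines and three distinct TF levels; with a single cell line the model
    degrades to weighted least squares (sigma_u^2 = 0) with a warning.
    """
    import pandas as pd

    curve = curve or MAECurve()
    if hasattr(samples, "columns"):
        df = samples
        tf = df["true_tf"].to_numpy(float)
        tgf = df["tgf"].to_numpy(float)
        coverage = df["coverage"].to_numpy(float)
        lines = df["cell_line"].astype(str).to_numpy()
    else:
        rows = list(samples)
        tf = np.array([r[0] for r in rows], dtype=float)
        tgf = np.array([r[1] for r in rows], dtype=float)
        coverage = np.array([r[2] for r in rows], dtype=float)
        lines = np.array([str(r[3]) for r in rows])
    if np.any((tf < 0) | (tf > 1)) or np.any((tgf < 0) | (tgf > 1)):
        raise ValueError("tf and tgf must be in [0, 1]")
    if len(np.unique(np.round(tf, 10))) < 3:
        raise ValueError("need >= 3 distinct TF levels")

    x = logit(clamp_proportion(tf, logit_eps))
    y = logit(clamp_proportion(tgf, logit_eps))
    w = _weights(coverage, curve, weight_rule)
    X = np.column_stack([np.ones_like(x), x])

    uniq, groups_idx = np.unique(lines, return_inverse=True)
    n_groups = uniq.size

    if n_groups < 2:
        warnings.warn(
            "single cell line: falling back to weighted least squares "
            "(sigma_u^2 = 0)",
            stacklevel=2,
        )
        import statsmodels.api as sm

        fit = sm.WLS(y, X, weights=w).fit()
        return CalibrationModel(
            intercept=float(fit.params[0]),
            slope=float(fit.params[1]),
            sigma_u2=0.0,
            sigma_e2=float(fit.scale),
            cov_beta=np.asarray(fit.cov_params()),
            blups={str(uniq[0]): 0.0},
            logit_eps=logit_eps,
            weight_rule=weight_rule,
            mae_curve=curve,
            n=int(y.size),
            converged=True,
        )

    def neg_reml(log_theta: float) -> float:
        reml, *_ = _reml_profile(np.exp(log_theta), y, X, groups_idx, n_groups, w)
        return -reml

    with np.errstate(all="ignore"):
        res = minimize_scalar(neg_reml, bounds=(-14.0, 8.0), method="bounded",
                              options={"xatol": 1e-8})
    theta = float(np.exp(res.x))
    # compare against the theta -> 0 boundary
    reml0, *_ = _reml_profile(1e-14, y, X, groups_idx, n_groups, w)
    if reml0 > -res.fun:
        theta = 0.0
    reml, beta, sigma_e2, XtViX, v0inv, resid = _reml_profile(
        max(theta, 1e-14), y, X, groups_idx, n_groups, w
    )
    if not np.isfinite(reml) or not np.all(np.isfinite(beta)):
        raise RuntimeError(
            f"calibration fit did not converge (REML={reml!r}, beta={beta!r})"
        )
    sigma_u2 = theta * sigma_e2
    # BLUPs: u = theta Z' V0^{-1} (y - X beta)
    vr = v0inv(resid)
    u = theta * np.bincount(groups_idx, weights=vr, minlength=n_groups)
    cov_beta = sigma_e2 * np.linalg.inv(XtViX)
    return CalibrationModel(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        cov_beta=cov_beta,
        blups={str(g): float(ui) for g, ui in zip(uniq, u)},
        logit_eps=logit_eps,
        weight_rule=weight_rule,
        mae_curve=curve,
        n=int(y.size),
        converged=bool(res.success),
        reml_loglik=float(reml),
    )


def predict_tf(
    model: CalibrationModel,
    tgf_observed: float,
    coverage: float | None = None,
    level: float = 0.95,
) -> TFPrediction:
    """Inverse estimation: the TF whose calibrated TGF matches the observation.

    The point estimate inverts the population-level line (u = 0); the
    prediction interval inverts the forward prediction band, whose variance
    at predictor x is ``var(a) + x^2 var(b) + 2 x cov(a,b) + sigma_u^2 +
    sigma_e^2 / w`` for a new sample of weight w; the confidence interval
    drops the new-observation terms.
    """
    if model.slope <= 0:
        raise ValueError("calibration not invertible: slope <= 0")
    eps = model.logit_eps
    if tgf_observed <= eps or tgf_observed >= 1.0 - eps:
        warnings.warn(
            "observed TGF at the eps-clamping boundary; bounds reported at limits",
            stacklevel=2,
        )
    y0 = float(logit(clamp_proportion(tgf_observed, eps)))
    a, b = model.intercept, model.slope
    C = np.asarray(model.cov_beta, dtype=float)
    if coverage is not None:
        mae = interpolate_mae(coverage, model.mae_curve)
        w_new = 1.0 / mae if model.weight_rule == "inv" else 1.0 / mae**2
    else:
        w_new = 1.0
    x_hat = (y0 - a) / b

    def band_var(x: float, predictive: bool) -> float:
        v = C[0, 0] + 2.0 * x * C[0, 1] + x * x * C[1, 1]
        if predictive:
            v += model.sigma_u2 + model.sigma_e2 / w_new
        return max(v, 0.0)

    z = float(norm.ppf(0.5 + level / 2.0))
    lim = max(abs(x_hat) + 10.0, 60.0)

    def invert(predictive: bool) -> tuple[float, float]:
        def s(x):
            return np.sqrt(band_var(x, predictive))

        if s(x_hat) == 0.0:
            return x_hat, x_hat
        lo_f = lambda x: a + b * x + z * s(x) - y0   # crosses y0 at the lower bound
        hi_f = lambda x: a + b * x - z * s(x) - y0   # crosses y0 at the upper bound
        try:
            lo = brentq(lo_f, -lim, x_hat)
            hi = brentq(hi_f, x_hat, lim)
        except ValueError:
            half = z * s(x_hat) / b   # delta-method fallback
            lo, hi = x_hat - half, x_hat + half
        return lo, hi

    ci = invert(predictive=False)
    pi = invert(predictive=True)
    return TFPrediction(
        tf_hat=float(expit(x_hat)),
        ci_low=float(expit(ci[0])),
        ci_high=float(expit(ci[1])),
        pi_low=float(expit(pi[0])),
        pi_high=float(expit(pi[1])),
        tgf=float(tgf_observed),
        weight=float(w_new),
    )
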