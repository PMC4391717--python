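"""Presence-background maximum-entropy species distribution model.

The model is the Gibbs distribution over background cells

    q(x) = exp(sum_j lambda_j f_j(x)) / Z(lambda),

whose feature weights ``lambda`` maximize the L1-penalized log-likelihood

    sum_j lambda_j fbar_j  -  log Z(lambda)  -  sum_j beta_j |lambda_j|,

where ``fbar_j`` is the mean of feature j over presence sites and ``Z``
normalizes over the background sample.  This is the maximum-entropy
distribution subject to the relaxed moment constraints
``|E_q[f_j] - fbar_j| <= beta_j``.  Features are linear and quadratic terms
(optionally pairwise products) of covariates affinely scaled to [0, 1] over
the background; the per-feature penalty scales as
``beta_j = beta0 * s_j / sqrt(n_presences)`` with ``s_j`` the presence
standard deviation of feature j.

The concave objective is solved exactly by L-BFGS-B after the standard
split ``lambda = lambda+ - lambda-`` (both non-negative), which renders the
L1 term linear.  Fits are deterministic: cold start at ``lambda = 0`` and a
fixed data order.

Outputs come on two monotone-equivalent scales: *raw* (the probabilities
``q``, summing to 1 over the training background) and *logistic*,
``c*q / (1 + c*q)`` with ``c = exp(H_q)``, the exponential of the entropy
of the fitted raw distribution — the conventional (0, 1) suitability index
for this model family.  When projecting onto new conditions, scaled
covariates are clamped to the [0, 1] training range by default so feature
responses are never extrapolated.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .exceptions import ConfigurationError, InputError
from .io import BACKGROUND_LABEL, EnvStack, swd_covariates, swd_split

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "product")


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str  # linear | quadratic | product
    covariate: str
    partner: str | None = None  # second covariate of a product feature


@dataclass
class FeatureSet:
    """Feature definitions plus the background scaling/clamping bounds."""

    features: list[Feature]
    bounds: dict[str, tuple[float, float]]  # covariate -> (train min, train max)

    @property
    def covariates(self) -> list[str]:
        return list(self.bounds)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def scale(self, table, clamp: bool = True) -> dict[str, np.ndarray]:
        """Affinely map each covariate to [0, 1] over its training bounds."""
        out = {}
        for cov, (lo, hi) in self.bounds.items():
            z = (np.asarray(table[cov], dtype=float) - lo) / (hi - lo)
            if clamp:
                z = np.clip(z, 0.0, 1.0)
            out[cov] = z
        return out

    def design_matrix(self, table, clamp: bool = True) -> np.ndarray:
        """Feature matrix (n, n_features) for a covariate table.

        ``table`` is anything indexable by covariate name yielding 1-D
        arrays (a DataFrame or a dict of grids raveled to 1-D).
        """
        z = self.scale(table, clamp=clamp)
        cols = []
        for f in self.features:
            if f.kind == "linear":
                cols.append(z[f.covariate])
            elif f.kind == "quadratic":
                cols.append(z[f.covariate] ** 2)
            else:
                cols.append(z[f.covariate] * z[f.partner])
        return np.column_stack(cols)


def build_features(swd_background, classes=("linear", "quadratic")) -> FeatureSet:
    """Derive a feature set and scaling bounds from background SWD rows.

    Covariates constant over the background carry no information and are
    dropped with a warning; if all are constant no model is possible.
    """
    classes = set(classes)
    unknown = classes - set(FEATURE_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown feature class(es): {sorted(unknown)}")
    if len(swd_background) < 2:
        raise InputError("need at least 2 background rows to build features")
    covs = swd_covariates(swd_background)
    bounds: dict[str, tuple[float, float]] = {}
    for cov in covs:
        vals = np.asarray(swd_background[cov], dtype=float)
        lo, hi = float(np.min(vals)), float(np.max(vals))
        if hi <= lo:
            log.warning("covariate '%s' is constant on background; dropped", cov)
            continue
        bounds[cov] = (lo, hi)
    if not bounds:
        raise InputError("all covariates are constant on the background")
    kept = list(bounds)
    features: list[Feature] = []
    if "linear" in classes:
        features += [Feature(c, "linear", c) for c in kept]
    if "quadratic" in classes:
        features += [Feature(f"{c}^2", "quadratic", c) for c in kept]
    if "product" in classes:
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                features.append(Feature(f"{a}*{b}", "product", a, b))
    return FeatureSet(features=features, bounds=bounds)


@dataclass
class MaxentModel:
    """A fitted maximum-entropy presence-background model."""

    lmbda: np.ndarray  # one weight per feature
    log_partition: float  # log Z over the training background
    entropy_raw: float  # H_q of the fitted raw distribution (nats)
    betas: np.ndarray  # per-feature L1 scales actually used
    feature_set: FeatureSet
    background_size: int
    converged: bool = True
    objective: float = field(default=np.nan)

    def raw_scores(self, F: np.ndarray) -> np.ndarray:
        """Raw-scale values exp(F @ lambda - log Z) for a feature matrix."""
        return np.exp(F @ self.lmbda - self.log_partition)

    def logistic_from_raw(self, raw: np.ndarray) -> np.ndarray:
        c = np.exp(self.entropy_raw)
        cr = c * raw
        return cr / (1.0 + cr)

    def score_table(self, table, scale: str = "logistic", clamp: bool = True) -> np.ndarray:
        """Suitability at arbitrary covariate rows (DataFrame-like)."""
        F = self.feature_set.design_matrix(table, clamp=clamp)
        raw = self.raw_scores(F)
        if scale == "raw":
            return raw
        if scale == "logistic":
            return self.logistic_from_raw(raw)
        raise ConfigurationError(f"unknown scale {scale!r}")


@dataclass
class SuitabilityGrid:
    """A suitability surface on one scale for one taxon and epoch."""

    values: np.ndarray  # NaN off-mask
    scale: str
    taxon_id: str | None = None
    scenario_id: str | None = None
    epoch: str | None = None


def fit_maxent(
    swd,
    fs: FeatureSet,
    beta0: float = 0.25,
    tol: float = 1e-6,
    max_iter: int = 500,
    betas=None,
) -> MaxentModel:
    """Fit the L1-penalized Gibbs model to an SWD table.

    ``betas`` overrides the default per-feature penalty
    ``beta0 * s_j / sqrt(n_presences)`` (scalar or per-feature array);
    presence feature SDs are floored at 1e-3 so no constraint is enforced
    exactly.  The default multiplier ``beta0 = 0.25`` follows the tuned
    regularization scale conventional for linear+quadratic feature sets at
    a hundred or more presences; a multiplier of 1 on ``s/sqrt(n)``
    over-smooths sharply unimodal responses.  Non-convergence within
    ``max_iter`` L-BFGS iterations returns the best iterate with a warning.
    """
    pres, bg = swd_split(swd)
    if len(pres) < 1:
        raise InputError("SWD table has no presence rows")
    if len(bg) < 2:
        raise InputError("SWD table needs at least 2 background rows")
    F_bg = fs.design_matrix(bg, clamp=False)
    F_pr = fs.design_matrix(pres, clamp=True)
    k = fs.n_features
    m = len(bg)
    n = len(pres)
    fbar = F_pr.mean(axis=0)
    if betas is None:
        s = np.maximum(F_pr.std(axis=0, ddof=0), 1e-3)
        beta = beta0 * s / np.sqrt(n)
    else:
        beta = np.broadcast_to(np.asarray(betas, dtype=float), (k,)).copy()

    # Split lambda = u[:k] - u[k:], u >= 0; the L1 term becomes linear.
    def negobj(u: np.ndarray):
        lam = u[:k] - u[k:]
        eta = F_bg @ lam
        logz = logsumexp(eta)
        val = -(lam @ fbar - logz) + beta @ (u[:k] + u[k:])
        w = np.exp(eta - logz)
        eqf = F_bg.T @ w
        g_lam = -(fbar - eqf)
        grad = np.concatenate([g_lam + beta, -g_lam + beta])
        return val, grad

    u0 = np.zeros(2 * k)
    res = minimize(
        negobj,
        u0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * k),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        log.warning("maxent fit: optimizer reported %s", res.message)
    if res.status == 1:
        warnings.warn(
            f"maxent fit did not converge in {max_iter} iterations "
            f"(final objective {-res.fun:.6g})",
            stacklevel=2,
        )
    lam = res.x[:k] - res.x[k:]
    eta = F_bg @ lam
    logz = float(logsumexp(eta))
    logq = eta - logz
    q = np.exp(logq)
    entropy = float(-(q @ logq))
    return MaxentModel(
        lmbda=lam,
        log_partition=logz,
        entropy_raw=entropy,
        betas=beta,
        feature_set=fs,
        background_size=m,
        converged=res.status != 1,
        objective=float(-res.fun),
    )


def predict(
    model: MaxentModel,
    stack: EnvStack,
    scale: str = "logistic",
    clamp: bool = True,
    taxon_id: str | None = None,
    scenario_id: str | None = None,
) -> SuitabilityGrid:
    """Project a fitted model onto an environmental stack.

    Covariates are rescaled by the training bounds and (by default) clamped
    to [0, 1] so projections never extrapolate feature responses.  Raw
    values are normalized by the *training* partition function, so they sum
    to 1 when evaluated over the model's own background.
    """
    missing = [c for c in model.feature_set.covariates if c not in stack.layers]
    if missing:
        raise ConfigurationError(f"stack lacks model covariate(s): {missing}")
    mask = stack.land_mask
    table = {c: stack.layers[c][mask] for c in model.feature_set.covariates}
    F = model.feature_set.design_matrix(table, clamp=clamp)
    raw = model.raw_scores(F)
    vals = raw if scale == "raw" else model.logistic_from_raw(raw)
    if scale not in ("raw", "logistic"):
        raise ConfigurationError(f"unknown scale {scale!r}")
    out = np.full(stack.meta.shape, np.nan)
    out[mask] = vals
    return SuitabilityGrid(
        values=out,
        scale=scale,
        taxon_id=taxon_id,
        scenario_id=scenario_id,
        epoch=stack.epoch,
    )
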