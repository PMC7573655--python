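"""Empirical-Bayes location/scale batch harmonization.

Per feature g and batch i, the model is

    y_ijg = alpha_g + x_ij' beta_g + gamma_ig + delta_ig * eps_ijg

with eps ~ N(0, sigma_g^2). Fitting standardizes each feature with a
batch-size-weighted grand mean and pooled variance, estimates per-batch
additive (gamma) and multiplicative (delta) effects on the standardized
scale, shrinks them toward parametric priors (normal for gamma,
inverse-gamma for delta^2) fitted across features by the method of
moments, and iterates the conditional posterior updates to a fixed
point. The adjusted value is

    y*_ijg = sigma_g / delta*_ig * (z_ijg - gamma*_ig) + alpha_g + x_ij' beta_g.

``stepwise_harmonize`` chains several instances — by default removing
sex effects, then age effects (integer age as the batch), then scanner
effects — and records per-step and cumulative corrections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import CohortTable

logger = logging.getLogger(__name__)


class UnseenBatchError(ValueError):
    """Transform received a batch label absent from the fitted model."""


@dataclass
class CombatModel:
    """Fitted harmonization state for one batch variable."""

    batch_variable: str
    batch_levels: list
    feature_names: list[str]
    covariate_names: list[str]
    grand_mean: np.ndarray          # (p,) alpha-hat per feature
    beta: np.ndarray                # (q, p) covariate coefficients
    var_pooled: np.ndarray          # (p,) sigma-hat^2
    gamma_hat: np.ndarray           # (b, p) raw additive effects (standardized scale)
    delta_sq_hat: np.ndarray        # (b, p) raw squared multiplicative effects
    gamma_star: np.ndarray          # (b, p) EB-adjusted additive effects
    delta_star: np.ndarray          # (b, p) EB-adjusted multiplicative effects (> 0)
    gamma_prior: np.ndarray         # (b, 2) normal prior (mean, var) per batch
    delta_prior: np.ndarray         # (b, 2) inverse-gamma prior (shape, scale) per batch
    eb: bool
    n_iterations: np.ndarray        # (b,) EB iterations per batch
    tol: float

    @property
    def gamma_star_data_units(self) -> np.ndarray:
        """Additive batch effects on the original data scale."""
        return self.gamma_star * np.sqrt(self.var_pooled)[None, :]


def _design(batch_codes: np.ndarray, n_levels: int, covariates: np.ndarray | None) -> np.ndarray:
    onehot = np.zeros((len(batch_codes), n_levels))
    onehot[np.arange(len(batch_codes)), batch_codes] = 1.0
    if covariates is None or covariates.size == 0:
        return onehot
    return np.column_stack([onehot, covariates])


def _postmean(gamma_hat, gamma_bar, n, delta_star_sq, tau_sq):
    return (n * tau_sq * gamma_hat + delta_star_sq * gamma_bar) / (n * tau_sq + delta_star_sq)


def _postvar(ssr, n, a, b):
    return (0.5 * ssr + b) / (n / 2.0 + a - 1.0)


def combat_fit(
    data: np.ndarray | pd.DataFrame,
    batch: Sequence,
    covariates: np.ndarray | pd.DataFrame | None = None,
    eb: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
    batch_variable: str = "batch",
) -> CombatModel:
    """Fit the location/scale harmonization model.

    Parameters
    ----------
    data:
        (n, p) feature matrix (subjects x features).
    batch:
        length-n batch labels.
    covariates:
        optional (n, q) design of covariates whose variance is preserved.
    eb:
        apply empirical-Bayes shrinkage of the batch effects; with
        ``eb=False`` the raw per-batch estimates are used directly.
    """
    if isinstance(data, pd.DataFrame):
        feature_names = [str(c) for c in data.columns]
        X = data.to_numpy(float)
    else:
        X = np.asarray(data, float)
        if X.ndim == 1:
            X = X[:, None]
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    n, p = X.shape

    batch = np.asarray(batch)
    levels, codes = np.unique(batch, return_inverse=True)
    counts = np.bincount(codes, minlength=len(levels))
    for lvl, cnt in zip(levels, counts):
        if cnt < 2:
            raise ValueError(f"batch level {lvl!r} has {cnt} subject(s); at least 2 required")

    covariate_names: list[str] = []
    C: np.ndarray | None = None
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            covariate_names = [str(c) for c in covariates.columns]
            C = covariates.to_numpy(float)
        else:
            C = np.asarray(covariates, float)
            if C.ndim == 1:
                C = C[:, None]
            covariate_names = [f"x{i}" for i in range(C.shape[1])]

    design = _design(codes, len(levels), C)
    B_hat, *_ = np.linalg.lstsq(design, X, rcond=None)
    batch_means = B_hat[: len(levels)]                  # (b, p)
    beta = B_hat[len(levels):]                          # (q, p)
    weights = counts / n
    grand_mean = weights @ batch_means                  # (p,)

    resid = X - design @ B_hat
    var_pooled = (resid ** 2).mean(axis=0)              # (p,)
    if np.any(var_pooled <= 0):
        bad = feature_names[int(np.argmin(var_pooled))]
        raise ValueError(f"feature {bad!r} has zero pooled variance")

    stand_mean = grand_mean[None, :] + (C @ beta if C is not None else 0.0)
    Z = (X - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.vstack([Z[codes == i].mean(axis=0) for i in range(len(levels))])
    delta_sq_hat = np.vstack([Z[codes == i].var(axis=0, ddof=0) for i in range(len(levels))])

    gamma_prior = np.zeros((len(levels), 2))
    delta_prior = np.zeros((len(levels), 2))
    gamma_star = gamma_hat.copy()
    delta_star_sq = delta_sq_hat.copy()
    n_iterations = np.zeros(len(levels), dtype=int)

    if eb and p >= 2:
        for i in range(len(levels)):
            g_hat, d_hat = gamma_hat[i], delta_sq_hat[i]
            g_bar = g_hat.mean()
            tau_sq = g_hat.var(ddof=1)
            m, s2 = d_hat.mean(), d_hat.var(ddof=1)
            # method-of-moments inverse-gamma hyperparameters
            a = (2.0 * s2 + m ** 2) / s2 if s2 > 0 else math.inf
            b = (m * s2 + m ** 3) / s2 if s2 > 0 else math.inf
            gamma_prior[i] = (g_bar, tau_sq)
            delta_prior[i] = (a, b)
            if tau_sq <= 0 or not math.isfinite(a):
                # degenerate prior (e.g. identical effects across features):
                # shrinkage has nothing to do; keep raw estimates
                n_iterations[i] = 0
                continue
            n_i = counts[i]
            Zi = Z[codes == i]
            g_new, d_new = g_hat.copy(), d_hat.copy()
            for it in range(1, max_iter + 1):
                g_prev, d_prev = g_new, d_new
                g_new = _postmean(g_hat, g_bar, n_i, d_new, tau_sq)
                ssr = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
                d_new = _postvar(ssr, n_i, a, b)
                change = max(
                    np.abs(g_new - g_prev).max() / max(np.abs(g_prev).max(), 1e-30),
                    np.abs(d_new - d_prev).max() / max(np.abs(d_prev).max(), 1e-30),
                )
                if change < tol:
                    break
            n_iterations[i] = it
            gamma_star[i] = g_new
            delta_star_sq[i] = d_new
    elif eb and p < 2:
        logger.warning("EB shrinkage needs >= 2 features; falling back to raw estimates")

    delta_star = np.sqrt(delta_star_sq)
    if np.any(delta_star <= 0):
        raise ValueError("non-positive multiplicative effect estimated")

    return CombatModel(
        batch_variable=batch_variable,
        batch_levels=list(levels),
        feature_names=feature_names,
        covariate_names=covariate_names,
        grand_mean=grand_mean,
        beta=beta,
        var_pooled=var_pooled,
        gamma_hat=gamma_hat,
        delta_sq_hat=delta_sq_hat,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_prior=gamma_prior,
        delta_prior=delta_prior,
        eb=eb,
        n_iterations=n_iterations,
        tol=tol,
    )


def combat_transform(
    model: CombatModel,
    data: np.ndarray | pd.DataFrame,
    batch: Sequence,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Harmonize ``data`` given its batch labels.

    Returns ``(harmonized, corrections)`` with
    ``corrections = harmonized - data``.
    """
    X = data.to_numpy(float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    if X.ndim == 1:
        X = X[:, None]
    batch = np.asarray(batch)
    level_index = {lvl: i for i, lvl in enumerate(model.batch_levels)}
    unseen = sorted({str(b) for b in batch if b not in level_index})
    if unseen:
        raise UnseenBatchError(
            f"batch label(s) {', '.join(unseen)} were not seen at fit time; "
            "harmonizing data from unseen batches requires the learner module "
            "(train/apply), which predicts corrections from image quality metrics"
        )
    codes = np.array([level_index[b] for b in batch])

    if covariates is not None:
        C = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        cov_term = C @ model.beta
    else:
        if model.beta.shape[0] > 0:
            raise ValueError("model was fitted with covariates; covariates required for transform")
        cov_term = 0.0

    sd = np.sqrt(model.var_pooled)[None, :]
    stand_mean = model.grand_mean[None, :] + cov_term
    Z = (X - stand_mean) / sd
    Zadj = (Z - model.gamma_star[codes]) / model.delta_star[codes]
    harmonized = Zadj * sd + stand_mean
    return harmonized, harmonized - X


# ---------------------------------------------------------------------------
# stepwise application over cohort tables

@dataclass
class CorrectionTable:
    """Signed corrections (harmonized minus raw relative volume), per step
    and cumulative, subject-indexed with plain ROI column names."""

    steps: dict[str, pd.DataFrame] = field(default_factory=dict)
    cumulative: pd.DataFrame | None = None

    def check(self, atol: float = 1e-10) -> None:
        total = sum(self.steps.values())
        if not np.allclose(total.to_numpy(), self.cumulative.to_numpy(), atol=atol):
            raise AssertionError("cumulative correction != sum of step corrections")


def age_to_category(age: np.ndarray | float) -> np.ndarray | int:
    """Nearest-integer age category, rounding half away from zero."""
    a = np.asarray(age, float)
    cat = np.sign(a) * np.floor(np.abs(a) + 0.5)
    cat = cat.astype(int)
    return int(cat) if np.isscalar(age) else cat


def merge_small_categories(categories: np.ndarray, min_size: int = 2) -> np.ndarray:
    """Merge ordinal categories with fewer than ``min_size`` members into the
    nearest populated category (ties broken toward the lower value)."""
    cats = np.asarray(categories).copy()
    while True:
        values, counts = np.unique(cats, return_counts=True)
        if len(values) <= 1:
            return cats
        small = values[counts < min_size]
        if small.size == 0:
            return cats
        v = small[0]
        others = values[values != v]
        dist = np.abs(others - v)
        best = others[dist == dist.min()].min()  # tie -> lower
        cats[cats == v] = best


def _step_batch(table: CohortTable, role: str, min_age_category: int) -> np.ndarray:
    if role == "scanner":
        return table.data["scanner"].to_numpy()
    if role == "sex":
        return table.data["sex"].to_numpy()
    if role == "age":
        cats = age_to_category(table.data["age"].to_numpy())
        return merge_small_categories(cats, min_age_category)
    raise ValueError(f"unknown step role {role!r}")


def _covariate_design(table: CohortTable, roles: Sequence[str]) -> pd.DataFrame | None:
    if not roles:
        return None
    cols = {}
    for r in roles:
        if r == "age":
            cols["age"] = table.data["age"].to_numpy(float)
        elif r == "sex":
            cols["sex"] = table.data["sex"].to_numpy(float)
        else:
            raise ValueError(f"unknown preserved covariate {r!r}")
    return pd.DataFrame(cols)


def stepwise_harmonize(
    table: CohortTable,
    steps: Sequence[str] = ("sex", "age", "scanner"),
    preserve: dict[str, Sequence[str]] | None = None,
    eb: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
    min_age_category: int = 2,
) -> tuple[CohortTable, CorrectionTable, list[CombatModel]]:
    """Apply one harmonization instance per step, each on the previous
    step's output.

    ``steps`` lists the variables whose effects are removed, in order;
    each step treats that variable as the batch. ``preserve`` maps a
    step name to covariate roles whose variance is kept during that
    step (default: none).
    """
    if not table.has_relative:
        raise ValueError("relative volumes required; run qc.compute_relative_volumes first")
    preserve = preserve or {}
    current = table.relative_volumes()   # subject-indexed, plain ROI names
    raw = current.copy()
    corrections = CorrectionTable()
    models: list[CombatModel] = []

    for role in steps:
        batch = _step_batch(table, role, min_age_category)
        cov = _covariate_design(table, preserve.get(role, ()))
        model = combat_fit(
            current, batch, covariates=cov, eb=eb, tol=tol, max_iter=max_iter,
            batch_variable=role,
        )
        harmonized, corr = combat_transform(model, current, batch, covariates=cov)
        corrections.steps[role] = pd.DataFrame(corr, index=current.index, columns=current.columns)
        current = pd.DataFrame(harmonized, index=current.index, columns=current.columns)
        models.append(model)

    corrections.cumulative = current - raw
    corrections.check()
    out = table.with_relative_volumes(current)
    return out, corrections, models
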