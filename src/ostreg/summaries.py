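"""Latent-scale summaries: R-squared, standardized coefficients, the
trait-only model, and the lagged-response extension."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import FitResult, ModelSpec, fit, select_lambda
from .panel import KeySet, OrdinalPanel, TraitSummary, key_set
from .penalty import build_penalty_spec, coef_layout, trait_only_layout

logger = logging.getLogger(__name__)

__all__ = [
    "R2Report",
    "latent_r2",
    "standardize",
    "fit_trait_only",
    "fit_lagged",
    "scaled_aic",
    "LOGISTIC_VARIANCE",
]

# the standard logistic error has variance pi^2/3; the R^2 convention used by
# default takes the error-variance constant as 1 (see docs/methods.md)
LOGISTIC_VARIANCE = np.pi**2 / 3.0


def latent_r2(
    fit_result: FitResult,
    panel: OrdinalPanel,
    traits: TraitSummary,
    *,
    error_variance: float = 1.0,
) -> dict:
    """Latent-scale R^2 for one model:

        R^2 = Var(f_hat) / (Var(f_hat + u_hat) + error_variance)

    with sample variances over all observations (u_hat repeated within
    subject).  ``error_variance`` defaults to 1; pass
    :data:`LOGISTIC_VARIANCE` for the pi^2/3 convention.
    """
    f_obs = fit_result.f_hat_obs
    u_obs = panel.data["subject"].map(fit_result.u_hat).to_numpy(dtype=float)
    var_f = float(np.var(f_obs, ddof=1))
    var_total = float(np.var(f_obs + u_obs, ddof=1)) + error_variance
    return {
        "r2": var_f / var_total,
        "latent_sd": float(np.sqrt(var_total)),
        "var_fixed": var_f,
        "var_latent": var_total,
    }


@dataclass(frozen=True)
class R2Report:
    """R^2 of the state-trait model vs. its trait-only reduction.

    The ratio RT^2 / RTS^2 is an informal index of how trait-driven the
    relationship is (near 1: the current state adds little beyond the
    person's typical level)."""

    r2_state_trait: float
    r2_trait_only: float
    ratio: float
    latent_sd: float

    @staticmethod
    def from_fits(
        full: FitResult,
        trait_only: FitResult,
        panel: OrdinalPanel,
        traits: TraitSummary,
        *,
        error_variance: float = 1.0,
    ) -> "R2Report":
        a = latent_r2(full, panel, traits, error_variance=error_variance)
        b = latent_r2(trait_only, panel, traits, error_variance=error_variance)
        return R2Report(
            r2_state_trait=a["r2"],
            r2_trait_only=b["r2"],
            ratio=b["r2"] / a["r2"] if a["r2"] > 0 else np.nan,
            latent_sd=a["latent_sd"],
        )


def standardize(fit_result: FitResult, latent_sd: float) -> np.ndarray:
    """Coefficients divided by the estimated latent-response SD, making
    estimates comparable across models with different cutpoints."""
    if latent_sd <= 0:
        raise ValueError("latent_sd must be positive")
    return np.asarray(fit_result.zeta_hat, dtype=float) / latent_sd


def fit_trait_only(
    panel: OrdinalPanel,
    traits: TraitSummary,
    keys: KeySet | None = None,
    *,
    mode: str = "penalized",
    lambda_grid: np.ndarray | None = None,
    fit_nodes: int = 21,
) -> FitResult:
    """Fit the trait-only model (state term deleted): every observation reads
    f(trait, trait) = alpha + tau_trait.

    The penalty reduces to second differences of tau along the diagonal,
    shrinking the trait profile toward linearity; lambda is selected by the
    same marginal criterion as for the full model.
    """
    if keys is None:
        keys = key_set(panel, traits)
    layout = trait_only_layout(coef_layout(keys, traits.global_median))
    if mode == "penalized":
        pen = build_penalty_spec(keys, layout, trait_only=True)
        if pen.rank == 0:  # too few trait levels for a second difference
            mode = "unpenalized"
    if mode == "penalized":
        spec = ModelSpec(
            m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen,
            fit_nodes=fit_nodes,
        )
        _, res = select_lambda(spec, panel, traits, keys, lambda_grid)
        return res
    spec = ModelSpec(m_y=panel.m_y, mode="unpenalized", layout=layout, fit_nodes=fit_nodes)
    return fit(spec, panel, traits, keys, 0.0)


def _lagged_panel(panel: OrdinalPanel) -> OrdinalPanel:
    """Drop each subject's (or subject-day's) first observation and attach the
    previous response as the numeric column ``y_lag``."""
    df = panel.data.copy()
    group_cols = ["subject", "day"] if "day" in df.columns else ["subject"]
    df["y_lag"] = df.groupby(group_cols)["y"].shift(1)
    kept = df.dropna(subset=["y_lag"]).copy()
    lost = set(df["subject"].unique()) - set(kept["subject"].unique())
    if lost:
        logger.warning("subjects with no lagged rows excluded: %s", sorted(lost))
    kept["y_lag"] = kept["y_lag"].astype(float)
    return OrdinalPanel(
        data=kept.reset_index(drop=True),
        m_x=panel.m_x,
        m_y=panel.m_y,
        level_spec=panel.level_spec,
    )


def fit_lagged(
    panel: OrdinalPanel,
    traits: TraitSummary,
    keys: KeySet | None = None,
    *,
    mode: str = "penalized",
    lambda_grid: np.ndarray | None = None,
    min_count: int = 0,
    fit_nodes: int = 21,
) -> FitResult:
    """Augment the state-trait model with the previous response as a numeric
    predictor (serial-dependence adjustment).

    The first observation per subject -- per subject-day when a ``day``
    column is present -- is dropped; person medians are those of the full
    panel.  Compare with an unlagged fit via :func:`scaled_aic`, since the
    sample sizes differ.
    """
    lagged = _lagged_panel(panel)
    lag_keys = key_set(lagged, traits, min_count)
    layout = coef_layout(lag_keys, traits.global_median)
    if mode == "linear":
        spec = ModelSpec(m_y=panel.m_y, mode="linear", lagged=True, fit_nodes=fit_nodes)
        return fit(spec, lagged, traits)
    if mode == "penalized":
        pen = build_penalty_spec(lag_keys, layout)
        spec = ModelSpec(
            m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen,
            lagged=True, fit_nodes=fit_nodes,
        )
        _, res = select_lambda(spec, lagged, traits, lag_keys, lambda_grid)
        return res
    spec = ModelSpec(
        m_y=panel.m_y, mode="unpenalized", layout=layout, lagged=True,
        fit_nodes=fit_nodes,
    )
    return fit(spec, lagged, traits, lag_keys, 0.0)


def scaled_aic(fit_result: FitResult) -> float:
    """AIC divided by the number of observations used, for comparing models
    fitted to different subsets (e.g. with vs. without the lagged response)."""
    return fit_result.aic / fit_result.n_obs
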