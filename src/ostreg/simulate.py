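"""Synthetic experience-sampling panels and the three-method comparison study.

The generator reproduces the structure of the simulation design used to
evaluate the penalized state-trait model: 400 subjects with 15 observations
each (6000 rows); person-median predictor levels 1..7 with frequencies
(16, 46, 85, 106, 85, 46, 16), hence overall median 4; latent responses

    l_ij = 0.17 - 0.15 sgn(t_i - 4)|t_i - 4|^p - 0.72 sgn(x_ij - t_i)|x_ij - t_i|^p
           + u_i + eps_ij

with u_i ~ N(0, 1), standard logistic eps, and cutpoints (-1, 1, 3, 5, 7, 9)
mapping l to y in 1..7.  Setting 1 (p = 1) makes the latent surface exactly
linear; setting 2 (p = 1/3) makes it nonlinear in both trait and state.

The conditional law of the states x_ij around the person median is not part
of the published design; here states are drawn from a shifted binomial
centered near the target median, with the sample median enforced exactly by
rejection (deterministic repair as a last resort).  See docs/methods.md for
what this does and does not emulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DEFAULT_LAMBDA_GRID, FitResult, ModelSpec, fit, select_lambda
from .panel import LevelSpec, OrdinalPanel, key_set, lower_median, person_medians
from .penalty import build_penalty_spec, coef_layout

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "StudyReport",
    "signed_power_surface",
    "gen_medians",
    "gen_states",
    "gen_response",
    "simulate_panel",
    "trim_response_levels",
    "run_study",
    "STUDY_LAMBDA_GRID",
]

# replicated studies use the same half-decade grid as single fits; the
# criterion path is abandoned early once it is clearly past its peak
STUDY_LAMBDA_GRID = DEFAULT_LAMBDA_GRID


@dataclass(frozen=True)
class SimConfig:
    """Full generating configuration for one study setting."""

    p: float = 1.0
    coefs: tuple = (0.17, -0.15, -0.72)  # intercept, trait, state
    median_freqs: tuple = (16, 46, 85, 106, 85, 46, 16)  # medians 1..7
    j_per_subject: int = 15
    theta: tuple = (-1.0, 1.0, 3.0, 5.0, 7.0, 9.0)
    sigma_u: float = 1.0
    n_reps: int = 100
    seed: int = 0
    x_sampler: str = "binomial"
    m_x: int = 7
    m_y: int = 7

    @property
    def n_subjects(self) -> int:
        return int(sum(self.median_freqs))

    @property
    def global_median(self) -> int:
        # median level implied by the frequency table
        reps = np.repeat(np.arange(1, len(self.median_freqs) + 1), self.median_freqs)
        return lower_median(reps)


def signed_power_surface(r, s, config: SimConfig):
    """True fixed-effect latent surface g(r, s) of the generating model."""
    c0, c1, c2 = config.coefs
    g = config.global_median
    dr = np.asarray(r, dtype=float) - g
    ds = np.asarray(s, dtype=float) - np.asarray(r, dtype=float)
    sp = lambda d: np.sign(d) * np.abs(d) ** config.p
    return c0 + c1 * sp(dr) + c2 * sp(ds)


def gen_medians(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Assign person medians with exactly the configured frequencies,
    in an order shuffled by the generator."""
    med = np.repeat(np.arange(1, len(config.median_freqs) + 1), config.median_freqs)
    rng.shuffle(med)
    return med


def _binomial_q(median: int, m_x: int) -> float:
    # proposal success probability placing the binomial mode near the target
    return (median - 0.5) / m_x


def gen_states(median: int, j: int, rng: np.random.Generator, m_x: int = 7) -> np.ndarray:
    """Draw j predictor values in 1..m_x whose sample median equals ``median``.

    Proposal: 1 + Binomial(m_x - 1, q) with q centering the mode near the
    target; batches are rejected until the sample median matches (at most 200
    resamples), then repaired deterministically by overwriting central order
    statistics with the target level.
    """
    if not 1 <= median <= m_x:
        raise ValueError(f"median {median} outside 1..{m_x}")
    q = _binomial_q(median, m_x)
    for _ in range(200):
        x = 1 + rng.binomial(m_x - 1, q, size=j)
        if lower_median(x) == median:
            return x
    # deterministic repair: force central order statistics to the target
    x = np.sort(x)
    mid = (j - 1) // 2
    lo = hi = mid
    x[mid] = median
    while lower_median(x) != median:
        if lower_median(x) < median:
            lo = max(lo - 1, 0)
            x[lo] = median
        else:
            hi = min(hi + 1, j - 1)
            x[hi] = median
    return x


def gen_response(
    x: np.ndarray, median: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Latent-model responses for one subject: u ~ N(0, sigma_u), logistic
    errors, cutpoint thresholding."""
    u = rng.normal(0.0, config.sigma_u)
    eps = rng.logistic(0.0, 1.0, size=x.size)
    lat = signed_power_surface(median, x, config) + u + eps
    theta = np.asarray(config.theta)
    return 1 + np.searchsorted(theta, lat)


def simulate_panel(config: SimConfig, rng: np.random.Generator) -> OrdinalPanel:
    """One full synthetic panel (n_subjects x j_per_subject rows)."""
    medians = gen_medians(config, rng)
    rows_x = np.empty((config.n_subjects, config.j_per_subject), dtype=np.int64)
    rows_y = np.empty_like(rows_x)
    for i, m in enumerate(medians):
        xs = gen_states(int(m), config.j_per_subject, rng, config.m_x)
        rows_x[i] = xs
        rows_y[i] = gen_response(xs, int(m), config, rng)
    n, j = config.n_subjects, config.j_per_subject
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(1, n + 1), j),
            "obs": np.tile(np.arange(1, j + 1), n),
            "x": rows_x.ravel(),
            "y": rows_y.ravel(),
        }
    )
    return OrdinalPanel(
        data=df,
        m_x=config.m_x,
        m_y=config.m_y,
        level_spec=LevelSpec(m_x=config.m_x, m_y=config.m_y),
    )


def trim_response_levels(panel: OrdinalPanel) -> OrdinalPanel:
    """Collapse empty leading/trailing response categories in place.

    Cutpoints for unobserved extreme categories are unidentified; finite
    replicates of the generating model can leave the top category empty.
    Returns the panel for chaining.
    """
    y = panel.data["y"]
    if y.max() < panel.m_y or y.min() > 1:
        panel.data["y"] = y - (y.min() - 1)
        panel.m_y = int(panel.data["y"].max())
    return panel


@dataclass
class StudyReport:
    """Per-replicate fit summaries and coefficient errors for one setting."""

    config: SimConfig
    fits: pd.DataFrame  # rep, method, loglik, edf_fixed, aic, lambda, converged
    coefs: pd.DataFrame  # rep, term, r, s, true, est_penalized, est_unpenalized
    n_excluded: int = 0

    @property
    def n_effective(self) -> int:
        return self.fits.loc[self.fits["method"] == "linear", "rep"].nunique()

    def _aic_wide(self) -> pd.DataFrame:
        return self.fits.pivot(index="rep", columns="method", values="aic")

    def win_counts(self) -> dict:
        """AIC comparisons among the three methods, per replicate."""
        aic = self._aic_wide().dropna()
        n = len(aic)
        lowest = aic.idxmin(axis=1)
        highest = aic.idxmax(axis=1)
        return {
            "n": n,
            "linear_lowest": int((lowest == "linear").sum()),
            "penalized_lowest": int((lowest == "penalized").sum()),
            "unpenalized_lowest": int((lowest == "unpenalized").sum()),
            "linear_highest": int((highest == "linear").sum()),
            "unpenalized_above_penalized": int(
                (aic["unpenalized"] > aic["penalized"]).sum()
            ),
        }

    def mse_table(self) -> pd.DataFrame:
        """Bias, MSE, and percentage MSE difference per coefficient."""
        rows = []
        for term, g in self.coefs.groupby("term", sort=False):
            err_p = g["est_penalized"] - g["true"]
            err_u = g["est_unpenalized"] - g["true"]
            mse_p = float((err_p**2).mean())
            mse_u = float((err_u**2).mean())
            rows.append(
                {
                    "term": term,
                    "n_reps": len(g),
                    "true": float(g["true"].iloc[0]),
                    "bias_penalized": float(err_p.mean()),
                    "bias_unpenalized": float(err_u.mean()),
                    "mse_penalized": mse_p,
                    "mse_unpenalized": mse_u,
                    "pct_mse_reduction": 100.0 * (1.0 - mse_p / mse_u)
                    if mse_u > 0
                    else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def edf_values(self) -> np.ndarray:
        sel = self.fits["method"] == "penalized"
        return self.fits.loc[sel, "edf_fixed"].to_numpy()


def _fit_row(rep: int, method: str, res: FitResult) -> dict:
    return {
        "rep": rep,
        "method": method,
        "loglik": res.loglik,
        "edf_fixed": res.edf_fixed,
        "aic": res.aic,
        "lambda": res.lambda_,
        "converged": res.converged,
    }


def run_study(
    config: SimConfig,
    methods: tuple = ("linear", "unpenalized", "penalized"),
    *,
    lambda_grid: np.ndarray | None = None,
    min_count: int = 0,
    fit_nodes: int = 21,
) -> StudyReport:
    """Simulate ``config.n_reps`` panels and fit the competing models to each.

    Per replicate the same data are fitted by the 3-coefficient linear model,
    the unpenalized state-trait model, and the penalized model with
    grid-selected lambda; AIC, EDF and coefficient errors are recorded.
    Replicates where any requested fit fails to converge are excluded from
    the comparison counts (tallied in ``n_excluded``).  Fully reproducible
    from ``config.seed``.
    """
    grid = STUDY_LAMBDA_GRID if lambda_grid is None else lambda_grid
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    fit_rows: list = []
    coef_rows: list = []
    n_excluded = 0
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        panel = trim_response_levels(simulate_panel(config, rng))
        traits = person_medians(panel)
        keys = key_set(panel, traits, min_count)
        layout = coef_layout(keys, traits.global_median)
        pen = build_penalty_spec(keys, layout)

        try:
            lin_spec = ModelSpec(m_y=panel.m_y, mode="linear", fit_nodes=fit_nodes)
            lin = fit(lin_spec, panel, traits)
            pen_spec = ModelSpec(
                m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen,
                fit_nodes=fit_nodes,
            )
            _, pen_fit, path = select_lambda(
                pen_spec, panel, traits, keys, grid, linear_init=lin,
                return_path=True, early_stop=2,
            )
            # warm-start the unpenalized fit from the weakest-shrinkage fit
            small_lam = path[-1][2]
            unp_init = np.concatenate(
                [
                    small_lam.zeta_hat,
                    np.log(np.diff(small_lam.theta_hat)),
                    [np.log(max(small_lam.sigma_u_hat, 1e-8))],
                ]
            )
            unp_spec = ModelSpec(
                m_y=panel.m_y, mode="unpenalized", layout=layout, fit_nodes=fit_nodes
            )
            unp = fit(unp_spec, panel, traits, keys, 0.0, init=unp_init)
        except (ValueError, FloatingPointError, RuntimeError) as e:
            # e.g. an empty middle response category in a degenerate replicate
            logger.warning("replicate %d excluded: %s", rep, e)
            n_excluded += 1
            continue

        results = {"linear": lin, "unpenalized": unp, "penalized": pen_fit}
        if not all(results[m].converged for m in methods):
            n_excluded += 1
            continue
        for m in methods:
            fit_rows.append(_fit_row(rep, m, results[m]))

        # coefficient errors vs the generating surface mapped to (alpha, tau, gamma)
        true_f = {
            (r, s): float(signed_power_surface(r, s, config)) for r, s in layout.cells
        }
        ref = layout.ref_trait
        true_zeta = {"alpha": true_f[(ref, ref)]}
        for r in layout.tau_levels:
            true_zeta[f"tau[{r}]"] = true_f[(r, r)] - true_f[(ref, ref)]
        for r, s in layout.gamma_cells:
            true_zeta[f"gamma[{r},{s}]"] = true_f[(r, s)] - true_f[(r, r)]
        for name, tv in true_zeta.items():
            idx = layout.names.index(name)
            coef_rows.append(
                {
                    "rep": rep,
                    "term": name,
                    "true": tv,
                    "est_penalized": float(pen_fit.zeta_hat[idx]),
                    "est_unpenalized": float(unp.zeta_hat[idx]),
                }
            )
    return StudyReport(
        config=config,
        fits=pd.DataFrame(fit_rows),
        coefs=pd.DataFrame(coef_rows),
        n_excluded=n_excluded,
    )
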