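"""Shared fixtures: small hand-built panels and simulated study replicates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

import ostreg

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")


def build_panel(records, m_x, m_y):
    """Panel from (subject, x, y) tuples, already internally coded."""
    df = pd.DataFrame(records, columns=["subject", "x", "y"])
    df["obs"] = df.groupby("subject").cumcount() + 1
    df = df.sort_values(["subject", "obs"]).reset_index(drop=True)
    return ostreg.OrdinalPanel(data=df, m_x=m_x, m_y=m_y)


def full_grid_panel(m_x=7, m_y=4, seed=5):
    """Panel whose key set is the complete m_x x m_x grid.

    Each trait level r gets two subjects with 15 observations: 9 copies of r
    (pinning the median at r) plus one of every other level, so every (r, s)
    cell occurs.  Responses come from a mildly nonlinear latent surface with
    narrow cutpoints so all m_y categories are populated.
    """
    rng = np.random.default_rng(seed)
    theta = -1.0 + 0.9 * np.arange(m_y - 1)
    records = []
    sid = 0
    for r in range(1, m_x + 1):
        for _ in range(2):
            sid += 1
            xs = [r] * 9 + [s for s in range(1, m_x + 1) if s != r]
            u = rng.normal(0.0, 1.0)
            for x in xs:
                lat = (
                    0.1
                    - 0.12 * (r - 4)
                    - 0.3 * (x - r)
                    + 0.05 * (x - r) ** 2
                    + u
                    + rng.logistic()
                )
                y = 1 + int(np.searchsorted(theta, lat))
                records.append((sid, x, y))
    panel = build_panel(records, m_x, m_y)
    # ensure every response category is populated (tiny panels can miss one)
    present = set(panel.data["y"])
    for m in range(1, m_y + 1):
        assert m in present, "fixture must populate all response categories"
    return panel


@pytest.fixture(scope="session")
def grid_panel():
    return full_grid_panel()


@pytest.fixture(scope="session")
def grid_model(grid_panel):
    traits = ostreg.person_medians(grid_panel)
    keys = ostreg.key_set(grid_panel, traits)
    layout = ostreg.coef_layout(keys, traits.global_median)
    pen = ostreg.build_penalty_spec(keys, layout)
    return grid_panel, traits, keys, layout, pen


def small_sim_config(p=1.0, seed=0, n_reps=1):
    """Scaled-down generating configuration for machinery tests (70 subjects)."""
    return ostreg.SimConfig(
        p=p,
        median_freqs=(3, 8, 15, 18, 15, 8, 3),
        seed=seed,
        n_reps=n_reps,
    )


@pytest.fixture(scope="session")
def sim_panel_s1():
    """One full-size setting-1 replicate with derived model objects."""
    cfg = ostreg.SimConfig(p=1.0, seed=20240901)
    rng = np.random.default_rng(cfg.seed)
    panel = ostreg.trim_response_levels(ostreg.simulate_panel(cfg, rng))
    traits = ostreg.person_medians(panel)
    keys = ostreg.key_set(panel, traits)
    layout = ostreg.coef_layout(keys, traits.global_median)
    pen = ostreg.build_penalty_spec(keys, layout)
    return panel, traits, keys, layout, pen
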