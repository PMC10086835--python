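"""Long-format ordinal panel data: validation, person medians, and the key set.

An intensive longitudinal (experience sampling) data set consists of repeated
ordinal measurements nested in subjects.  The state-trait model needs, besides
the raw observations, each subject's median predictor level ("trait"), the
global median, and the set ``K`` of trait-state pairs ``(r, s)`` that actually
occur in the data -- the domain of the latent-scale surface ``f(r, s)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LevelSpec",
    "OrdinalPanel",
    "TraitSummary",
    "KeySet",
    "load_panel",
    "person_medians",
    "key_set",
    "lower_median",
]


@dataclass(frozen=True)
class LevelSpec:
    """Declared level ranges and external-label maps for x and y.

    ``x_labels``/``y_labels`` map external labels (e.g. -3..+3 or 0..6) to the
    internal coding 1..M.  If omitted, values are assumed already coded 1..M.
    """

    m_x: int
    m_y: int
    x_labels: Mapping | None = None
    y_labels: Mapping | None = None

    @staticmethod
    def from_range(x_lo: int, x_hi: int, y_lo: int, y_hi: int) -> "LevelSpec":
        """Build a spec for consecutive-integer external labels."""
        return LevelSpec(
            m_x=x_hi - x_lo + 1,
            m_y=y_hi - y_lo + 1,
            x_labels={v: v - x_lo + 1 for v in range(x_lo, x_hi + 1)},
            y_labels={v: v - y_lo + 1 for v in range(y_lo, y_hi + 1)},
        )


@dataclass
class OrdinalPanel:
    """Validated long-format panel, internally coded with x, y in 1..M.

    ``data`` is sorted by (subject, day, obs) and has columns
    ``subject, obs, x, y`` plus optionally ``day``.
    """

    data: pd.DataFrame
    m_x: int
    m_y: int
    n_dropped: int = 0
    level_spec: LevelSpec | None = None

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject"].unique()

    @property
    def n_subjects(self) -> int:
        return self.data["subject"].nunique()


@dataclass(frozen=True)
class TraitSummary:
    """Person medians (traits) and the global median of the predictor."""

    person_median: Mapping
    global_median: int


@dataclass
class KeySet:
    """The set K of trait-state pairs occurring in the data.

    ``pairs`` holds every ``(r, s)`` with at least one observation, ``counts``
    the per-cell observation counts, and ``merge_map`` the (idempotent) map
    from each cell to its representative after optional merging of rare cells.
    """

    pairs: list
    counts: dict
    merge_map: dict

    def representative(self, cell) -> tuple:
        return self.merge_map[cell]

    @property
    def merged_cells(self) -> list:
        """Sorted distinct representative cells."""
        return sorted(set(self.merge_map.values()))


def lower_median(values: Sequence[int]) -> int:
    """Median with the lower-of-two-middles tie rule, so the result is always
    an attained ordinal level: for sorted v of length n, returns v[(n-1)//2]."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("median of empty sequence")
    return int(v[(v.size - 1) // 2])


def load_panel(
    table: pd.DataFrame,
    level_spec: LevelSpec,
    *,
    subject_col: str = "subject",
    x_col: str = "x",
    y_col: str = "y",
    obs_col: str = "obs",
    day_col: str = "day",
) -> OrdinalPanel:
    """Validate a long-format table and return an :class:`OrdinalPanel`.

    Rows with missing x or y are dropped (counted in ``n_dropped``); external
    labels are remapped to 1..M; unknown labels raise with a row reference;
    subjects left with zero rows are dropped with a warning.
    """
    df = table.copy()
    rename = {subject_col: "subject", x_col: "x", y_col: "y"}
    if obs_col in df.columns:
        rename[obs_col] = "obs"
    if day_col in df.columns:
        rename[day_col] = "day"
    df = df.rename(columns=rename)
    for col in ("subject", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"input table lacks required column {col!r}")

    missing = df["x"].isna() | df["y"].isna()
    n_dropped = int(missing.sum())
    if n_dropped:
        logger.info("dropped %d rows with missing x or y", n_dropped)
    before = set(df["subject"].unique())
    df = df.loc[~missing].copy()
    lost = before - set(df["subject"].unique())
    if lost:
        logger.warning("subjects dropped with zero retained rows: %s", sorted(lost))

    for col, labels, m in (
        ("x", level_spec.x_labels, level_spec.m_x),
        ("y", level_spec.y_labels, level_spec.m_y),
    ):
        vals = df[col]
        if labels is not None:
            unknown = ~vals.isin(list(labels))
            if unknown.any():
                row = df.index[unknown][0]
                raise ValueError(
                    f"unknown {col} label {vals[unknown].iloc[0]!r} at row {row}"
                )
            df[col] = vals.map(labels).astype(np.int64)
        else:
            df[col] = vals.astype(np.int64)
        out = (df[col] < 1) | (df[col] > m)
        if out.any():
            row = df.index[out][0]
            raise ValueError(
                f"{col} value {df[col][out].iloc[0]} outside 1..{m} at row {row}"
            )

    if "obs" not in df.columns:
        df["obs"] = df.groupby("subject").cumcount() + 1
    sort_cols = ["subject"] + (["day"] if "day" in df.columns else []) + ["obs"]
    df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)

    if df["subject"].nunique() < 2:
        raise ValueError("panel needs at least 2 subjects")

    return OrdinalPanel(
        data=df,
        m_x=level_spec.m_x,
        m_y=level_spec.m_y,
        n_dropped=n_dropped,
        level_spec=level_spec,
    )


def person_medians(panel: OrdinalPanel) -> TraitSummary:
    """Per-subject medians of x (the trait levels) and the pooled global median.

    Both use the lower-median tie rule so every median is an attained level.
    """
    med = {
        subj: lower_median(g.to_numpy())
        for subj, g in panel.data.groupby("subject", sort=True)["x"]
    }
    return TraitSummary(
        person_median=med, global_median=lower_median(panel.data["x"].to_numpy())
    )


def _chebyshev(a: tuple, b: tuple) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def key_set(panel: OrdinalPanel, traits: TraitSummary, min_count: int = 0) -> KeySet:
    """Enumerate K = {(trait, state)} with counts; optionally merge rare cells.

    A cell with count < ``min_count`` is merged into the nearest (Chebyshev
    distance) cell whose count is >= ``min_count``, preferring a cell on the
    same off-diagonal band s - r (where a linear surface is constant), then
    cells nearer the main diagonal; remaining ties go to smaller r, then s.
    """
    trait_per_row = panel.data["subject"].map(traits.person_median)
    pairs_series = list(zip(trait_per_row.to_numpy(), panel.data["x"].to_numpy()))
    counts: dict = {}
    for cell in pairs_series:
        cell = (int(cell[0]), int(cell[1]))
        counts[cell] = counts.get(cell, 0) + 1
    pairs = sorted(counts)

    merge_map = {c: c for c in pairs}
    if min_count > 0:
        keep = [c for c in pairs if counts[c] >= min_count]
        for cell in pairs:
            if counts[cell] >= min_count or not keep:
                continue
            band = cell[1] - cell[0]

            def rank(cand, cell=cell, band=band):
                return (
                    _chebyshev(cand, cell),
                    0 if cand[1] - cand[0] == band else 1,
                    abs(cand[1] - cand[0]),
                    cand[0],
                    cand[1],
                )

            merge_map[cell] = min(keep, key=rank)

    return KeySet(pairs=pairs, counts=counts, merge_map=merge_map)
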