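"""Fixed-effect parametrization and the linearity penalty.

The latent-scale surface f on the key set K is parametrized as
``f(r, s) = alpha + tau_r + gamma_{r,s}`` with the identifiability constraints
``tau_{ref} = 0`` (ref is the global median level) and ``gamma_{r,r} = 0``,
implemented structurally: constrained parameters simply have no column.

The penalty functional is the sum of squared discrete second-order differences
of f over the grid -- row-wise, column-wise, and (with weight 2) mixed -- which
vanishes exactly when f is linear in (r, s), i.e. when the model reduces to
the classical 3-coefficient between/within-person disaggregation.  It is
realized as a coefficient-space quadratic form ``zeta' P zeta`` with
``P = A' D' D A``: D stacks one row per admissible difference window over the
f values (mixed rows pre-scaled by sqrt(2)), and A is the linear map from the
coefficient vector zeta to those f values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import KeySet

__all__ = [
    "CoefLayout",
    "PenaltySpec",
    "coef_layout",
    "trait_only_layout",
    "zeta_to_f",
    "f_to_zeta",
    "build_difference_rows",
    "build_trait_difference_rows",
    "build_penalty",
    "build_penalty_spec",
]


@dataclass
class CoefLayout:
    """Ordering of the coefficient vector zeta = (alpha, taus, gammas).

    ``cells`` lists the representative cells of the merged key set in the
    order used by the zeta -> f map; diagonal cells correspond to attained
    trait levels, off-diagonal cells to gamma parameters.
    """

    ref_trait: int
    tau_levels: list  # attained trait levels r != ref_trait, ascending
    gamma_cells: list  # off-diagonal representative cells, lexicographic
    cells: list  # all representative cells (diagonal + off-diagonal), sorted

    @property
    def n_params(self) -> int:
        return 1 + len(self.tau_levels) + len(self.gamma_cells)

    @property
    def names(self) -> list:
        return (
            ["alpha"]
            + [f"tau[{r}]" for r in self.tau_levels]
            + [f"gamma[{r},{s}]" for r, s in self.gamma_cells]
        )

    def tau_index(self, r: int) -> int:
        return 1 + self.tau_levels.index(r)

    def gamma_index(self, cell) -> int:
        return 1 + len(self.tau_levels) + self.gamma_cells.index(cell)

    @property
    def tau_slice(self) -> slice:
        return slice(1, 1 + len(self.tau_levels))

    @property
    def gamma_slice(self) -> slice:
        return slice(1 + len(self.tau_levels), self.n_params)

    def a_matrix(self) -> np.ndarray:
        """Linear map A with f(cells) = A @ zeta."""
        a = np.zeros((len(self.cells), self.n_params))
        a[:, 0] = 1.0
        for i, (r, s) in enumerate(self.cells):
            if r != self.ref_trait:
                a[i, self.tau_index(r)] = 1.0
            if r != s:
                a[i, self.gamma_index((r, s))] = 1.0
        return a


@dataclass
class PenaltySpec:
    """Difference rows D (over f space), map A (zeta -> f), and P = A'D'DA."""

    d_rows: np.ndarray
    a_matrix: np.ndarray
    p_matrix: np.ndarray
    layout: CoefLayout

    @property
    def rank(self) -> int:
        if self.p_matrix.size == 0:
            return 0
        ev = np.linalg.eigvalsh(self.p_matrix)
        tol = max(ev.max(), 0.0) * self.p_matrix.shape[0] * np.finfo(float).eps
        return int((ev > max(tol, 1e-12)).sum())


def coef_layout(keys: KeySet, global_median: int) -> CoefLayout:
    """Deterministic coefficient layout for a (possibly merged) key set.

    The reference trait (whose tau is structurally zero) is the global median
    when it is an attained trait level; otherwise the nearest attained level
    (ties to the lower level), keeping alpha identified.
    """
    cells = keys.merged_cells
    if not cells:
        raise ValueError("empty key set")
    trait_levels = sorted({r for r, s in cells if r == s})
    if not trait_levels:
        raise ValueError("key set has no diagonal (trait) cells")
    if global_median in trait_levels:
        ref = global_median
    else:
        ref = min(trait_levels, key=lambda r: (abs(r - global_median), r))
    return CoefLayout(
        ref_trait=ref,
        tau_levels=[r for r in trait_levels if r != ref],
        gamma_cells=[(r, s) for r, s in cells if r != s],
        cells=cells,
    )


def trait_only_layout(layout: CoefLayout) -> CoefLayout:
    """Layout with the gamma block deleted (trait-only model)."""
    diag = [(r, r) for r in sorted([layout.ref_trait] + layout.tau_levels)]
    return CoefLayout(
        ref_trait=layout.ref_trait,
        tau_levels=list(layout.tau_levels),
        gamma_cells=[],
        cells=diag,
    )


def zeta_to_f(zeta: np.ndarray, layout: CoefLayout) -> dict:
    """f(r, s) = alpha + tau_r + gamma_{r,s} on the representative cells."""
    f = layout.a_matrix() @ np.asarray(zeta, dtype=float)
    return dict(zip(layout.cells, f))


def f_to_zeta(f: dict, layout: CoefLayout) -> np.ndarray:
    """Invert zeta_to_f: tau_r = f(r,r) - f(ref,ref), gamma = f(r,s) - f(r,r)."""
    ref = layout.ref_trait
    if (ref, ref) not in f:
        raise ValueError(f"missing diagonal cell ({ref}, {ref}) for reference trait")
    zeta = np.empty(layout.n_params)
    zeta[0] = f[(ref, ref)]
    for r in layout.tau_levels:
        if (r, r) not in f:
            raise ValueError(f"missing diagonal cell ({r}, {r}) for attained trait {r}")
        zeta[layout.tau_index(r)] = f[(r, r)] - f[(ref, ref)]
    for cell in layout.gamma_cells:
        r = cell[0]
        if (r, r) not in f:
            raise ValueError(f"missing diagonal cell ({r}, {r}) for attained trait {r}")
        zeta[layout.gamma_index(cell)] = f[cell] - f[(r, r)]
    return zeta


_WINDOWS = {
    # offsets (dr, ds) and coefficients; mixed rows carry weight sqrt(2)
    "rr": (((-1, 0), (0, 0), (1, 0)), (1.0, -2.0, 1.0), 1.0),
    "rs": (((0, 0), (0, 1), (1, 0), (1, 1)), (1.0, -1.0, -1.0, 1.0), np.sqrt(2.0)),
    "ss": (((0, -1), (0, 0), (0, 1)), (1.0, -2.0, 1.0), 1.0),
}


def build_difference_rows(keys: KeySet, layout: CoefLayout) -> np.ndarray:
    """One row per admissible second-difference window over the key set.

    A window is admissible iff every referenced cell occurs in the data; its
    f values are read through the merge map, so coefficients accumulate on
    representative cells.  Returns an array of shape (n_rows, n_cells) in the
    order of ``layout.cells``.
    """
    cell_index = {c: i for i, c in enumerate(layout.cells)}
    present = set(keys.pairs)
    rows = []
    lo = min(min(r, s) for r, s in present)
    hi = max(max(r, s) for r, s in present)
    for kind, (offsets, coefs, scale) in _WINDOWS.items():
        for r in range(lo, hi + 1):
            for s in range(lo, hi + 1):
                refs = [(r + dr, s + ds) for dr, ds in offsets]
                if not all(c in present for c in refs):
                    continue
                row = np.zeros(len(layout.cells))
                for c, coef in zip(refs, coefs):
                    row[cell_index[keys.representative(c)]] += scale * coef
                rows.append(row)
    if not rows:
        return np.zeros((0, len(layout.cells)))
    return np.asarray(rows)


def build_trait_difference_rows(layout: CoefLayout) -> np.ndarray:
    """Second differences of tau along the diagonal (trait-only penalty).

    Windows require three consecutive attained trait levels; the null space is
    then {surfaces linear in r}, the trait-only analogue of the linear model.
    """
    levels = sorted(r for r, s in layout.cells if r == s)
    cell_index = {c: i for i, c in enumerate(layout.cells)}
    rows = []
    for r in levels:
        if r - 1 in levels and r + 1 in levels:
            row = np.zeros(len(layout.cells))
            row[cell_index[(r - 1, r - 1)]] += 1.0
            row[cell_index[(r, r)]] += -2.0
            row[cell_index[(r + 1, r + 1)]] += 1.0
            rows.append(row)
    if not rows:
        return np.zeros((0, len(layout.cells)))
    return np.asarray(rows)


def build_penalty(d_rows: np.ndarray, a_matrix: np.ndarray) -> np.ndarray:
    """P = A' D' D A, symmetric PSD, with zeta' P zeta = J*(f)."""
    da = d_rows @ a_matrix
    p = da.T @ da
    return 0.5 * (p + p.T)


def build_penalty_spec(
    keys: KeySet, layout: CoefLayout, *, trait_only: bool = False
) -> PenaltySpec:
    """Convenience constructor bundling D, A and P for a key set."""
    a = layout.a_matrix()
    d = (
        build_trait_difference_rows(layout)
        if trait_only
        else build_difference_rows(keys, layout)
    )
    return PenaltySpec(d_rows=d, a_matrix=a, p_matrix=build_penalty(d, a), layout=layout)
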