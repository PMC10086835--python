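"""Independent oracles used by several test modules.

These deliberately re-derive quantities from first principles (direct
summation, dense numerical integration) without reusing the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def j_star_direct(f: dict, pairs: set, merge_map: dict | None = None) -> float:
    """Sum of squared second differences of f over the key set, weight 2 on
    the mixed difference; each window requires all referenced cells to occur.

    ``f`` maps representative cells to values; raw cells are read through
    ``merge_map`` when given.
    """
    merge_map = merge_map or {c: c for c in pairs}

    def val(c):
        return f[merge_map[c]]

    lo = min(min(r, s) for r, s in pairs)
    hi = max(max(r, s) for r, s in pairs)
    total = 0.0
    for r in range(lo, hi + 1):
        for s in range(lo, hi + 1):
            if all((rr, s) in pairs for rr in (r - 1, r, r + 1)):
                total += (val((r + 1, s)) - 2 * val((r, s)) + val((r - 1, s))) ** 2
            if all((r, ss) in pairs for ss in (s - 1, s, s + 1)):
                total += (val((r, s + 1)) - 2 * val((r, s)) + val((r, s - 1))) ** 2
            if all(c in pairs for c in [(r, s), (r, s + 1), (r + 1, s), (r + 1, s + 1)]):
                total += (
                    2.0
                    * (val((r + 1, s + 1)) - val((r + 1, s)) - val((r, s + 1)) + val((r, s)))
                    ** 2
                )
    return total


def loglik_bruteforce(panel, traits, layout_or_mode, zeta, theta, sigma_u, n_grid=100_001):
    """Marginal log-likelihood by dense trapezoid integration over u in [-8, 8].

    Independent of the package's quadrature: conditional category
    probabilities are computed directly from the logistic CDF.
    """
    from scipy.special import expit

    theta = np.asarray(theta, dtype=float)
    pad = np.concatenate([[-np.inf], theta, [np.inf]])
    u = np.linspace(-8.0, 8.0, n_grid)
    phi = np.exp(-0.5 * (u / sigma_u) ** 2) / (sigma_u * np.sqrt(2 * np.pi))
    total = 0.0
    df = panel.data
    for _, g in df.groupby("subject", sort=True):
        lik = np.ones_like(u)
        for _, row in g.iterrows():
            if layout_or_mode == "linear":
                eta = (
                    zeta[0]
                    + zeta[1] * (traits.person_median[row["subject"]] - traits.global_median)
                    + zeta[2] * (row["x"] - traits.person_median[row["subject"]])
                )
            else:
                layout = layout_or_mode
                r = traits.person_median[row["subject"]]
                s = row["x"]
                eta = zeta[0]
                if r != layout.ref_trait:
                    eta += zeta[layout.tau_index(r)]
                if r != s:
                    eta += zeta[layout.gamma_index((r, s))]
            m = int(row["y"])
            p = expit(pad[m] - eta - u) - expit(pad[m - 1] - eta - u)
            lik = lik * p
        total += np.log(np.trapezoid(lik * phi, u))
    return total
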