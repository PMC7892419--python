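"""Small shared statistical helpers.

The only non-library piece here is an exact two-sided null for the Spearman
rank correlation at small n, obtained by enumerating every permutation of
one margin (this also handles ties correctly, because average ranks are
recomputed under each permutation of the observed values).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats

#: below this sample size the Spearman p-value is computed by enumeration
EXACT_SPEARMAN_MAX_N = 9


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Spearman rho with a two-sided p-value.

    Exact (full permutation enumeration) for n <= 9, large-sample
    t-approximation otherwise.  Ties receive average ranks.  Returns
    ``(rho, p, method)``.  Raises ``ValueError`` when either input is
    constant (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    rho = float(np.mean(zx * zy))

    if n <= EXACT_SPEARMAN_MAX_N:
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        # re-rank the permuted y values so ties are handled identically
        ry_perm = ry[perms]
        z = (ry_perm - ry.mean()) / ry.std()
        rhos = z @ zx / n
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p, "exact"

    # t approximation, as in classical large-sample theory
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p), "t-approximation"


def holm_adjust(pvals: list[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        return []
    if len(pvals) == 1:
        return [float(pvals[0])]
    _, adj, _, _ = multipletests(pvals, method="holm")
    return [float(p) for p in adj]
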