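"""Lin's concordance correlation between co-fluctuation patterns.

C(x, y) = 2 Cov(x, y) / (Var x + Var y + (mean x - mean y)^2), with
population (1/n) moments.  Unlike the Pearson correlation, concordance is
penalized when the two patterns differ in mean or amplitude; it equals the
correlation only when the first two moments match, and |C| <= |r| always.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "lin_concordance",
    "concordance_matrix",
    "concordance_matrix_from_array",
]


def lin_concordance(x, y, ddof: int = 0) -> float:
    """Concordance of two equal-length vectors.

    ``ddof=0`` (population moments) is the default; the Pearson upper
    bound holds under either convention.  Degenerate conventions: both
    vectors constant and equal -> 1; both constant and unequal -> 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.shape[0] < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=ddof)
    vy = y.var(ddof=ddof)
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return 1.0  # both constant with equal means
    n = x.shape[0]
    cov = ((x - mx) * (y - my)).sum() / (n - ddof)
    return float(np.clip(2.0 * cov / denom, -1.0, 1.0))


def concordance_matrix_from_array(x: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Pairwise concordance over the rows of a P x E array.

    Vectorized equivalent of calling :func:`lin_concordance` on every row
    pair; diagonal is set to 1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a P x E array with P >= 2")
    p, e = x.shape
    mu = x.mean(axis=1)
    var = x.var(axis=1, ddof=ddof)
    xc = x - mu[:, None]
    cov = (xc @ xc.T) / (e - ddof)
    denom = var[:, None] + var[None, :] + (mu[:, None] - mu[None, :]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        c = 2.0 * cov / denom
    c = np.where(denom == 0.0, 1.0, c)  # equal-constant rows
    c = np.clip(c, -1.0, 1.0)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c


def concordance_matrix(patterns, ddof: int = 0) -> np.ndarray:
    """Pairwise concordance between co-fluctuation patterns.

    Accepts a list of :class:`~cofluct.edges.CoFluctuationPattern` (or any
    objects with a ``vector`` attribute) or a P x E array.
    """
    if isinstance(patterns, np.ndarray):
        return concordance_matrix_from_array(patterns, ddof=ddof)
    vecs = [np.asarray(getattr(p, "vector", p), dtype=float) for p in patterns]
    if len(vecs) < 2:
        raise ValueError("need at least 2 patterns")
    dims = {v.shape[0] for v in vecs}
    if len(dims) != 1:
        raise ValueError(f"edge-dimension mismatch among patterns: {dims}")
    return concordance_matrix_from_array(np.vstack(vecs), ddof=ddof)
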