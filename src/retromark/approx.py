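"""Normal-approximation significance formulas and critical-value tables.

For large marker sets the exact binomial tails can be replaced by a
continuity-corrected normal approximation.  Writing ``z_alpha`` for the upper
``alpha`` quantile of the standard normal (``F0(z_alpha) = 1 - alpha``), the
critical boundaries become closed-form expressions that are rounded *up* to
the next integer:

* bifurcation (winning count Y out of n, null p = 1/3)::

      Y >= n/3 + 1/2 + z_alpha * sqrt(2 n) / 3

* asymmetry (two-sided difference of the two smallest counts at fixed sum)::

      |Y2 - Y3| >= 1 + z_{alpha/2} * sqrt(Y2 + Y3)

* one-directional comparison (counts Y1 >= Y2)::

      Y1 >= (Y1 + Y2 + 1 + z_alpha * sqrt(Y1 + Y2)) / 2

Note the asymmetry bound uses the two-sided quantile ``z_{alpha/2}`` (1.960
at alpha = 0.05) while the one-sided tests use ``z_alpha`` (1.645).
``build_critical_table`` regenerates reference tables with exact and
approximate values side by side; across all tested n the two differ by at
most one marker.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exact import critical_boundaries

__all__ = [
    "z_quantile",
    "normal_tail_approx",
    "approx_critical_y1",
    "approx_critical_diff",
    "approx_critical_one_dir",
    "approx_critical",
    "build_critical_table",
]

# guard against float noise just below an integral bound (13.999999999 -> 14)
_EPS = 1e-9


def _ceil(x: float) -> int:
    return math.ceil(x - _EPS)


def _check_alpha(alpha: float) -> float:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha


def z_quantile(alpha: float) -> float:
    """Upper quantile z with F0(z) = 1 - alpha for the standard normal."""
    _check_alpha(alpha)
    return float(norm.isf(alpha))


def normal_tail_approx(y: int, n: int, p: float) -> float:
    """Continuity-corrected normal approximation to P(X >= y), X ~ Binom(n, p)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1): the tail has zero variance otherwise")
    z = (y - 0.5 - n * p) / math.sqrt(n * p * (1.0 - p))
    return float(norm.sf(z))


def approx_critical_y1(n: int, alpha: float) -> int:
    """Approximate critical winning count for the bifurcation test at level alpha."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z = z_quantile(_check_alpha(alpha))
    return _ceil(n / 3.0 + 0.5 + z * math.sqrt(2.0 * n) / 3.0)


def approx_critical_diff(pair_sum: int, alpha: float) -> int:
    """Approximate critical |Y2 - Y3| for the two-sided asymmetry test.

    Uses the two-sided quantile z_{alpha/2}.
    """
    if pair_sum < 0:
        raise ValueError("pair_sum must be >= 0")
    z = z_quantile(_check_alpha(alpha) / 2.0)
    return _ceil(1.0 + z * math.sqrt(pair_sum))


def approx_critical_one_dir(pair_sum: int, alpha: float) -> int:
    """Approximate critical larger count for the one-directional comparison."""
    if pair_sum < 1:
        raise ValueError("pair_sum must be >= 1")
    z = z_quantile(_check_alpha(alpha))
    return _ceil((pair_sum + 1.0 + z * math.sqrt(pair_sum)) / 2.0)


_APPROX = {
    "bifurcation": approx_critical_y1,
    "asymmetry": approx_critical_diff,
    "one_directional": approx_critical_one_dir,
}


def approx_critical(n: int, alpha: float, which: str) -> int:
    """Dispatch to the approximation matching ``which`` (same contract as
    :func:`retromark.exact.critical_boundaries`)."""
    try:
        fn = _APPROX[which]
    except KeyError:
        raise ValueError(f"unknown test type {which!r}") from None
    return fn(n, alpha)


def _alpha_tag(alpha: float) -> str:
    # 0.05 -> "05", 0.01 -> "01", 0.025 -> "025"
    return f"{alpha:g}".split(".")[1]


def build_critical_table(
    n_max: int,
    alphas: Iterable[float] = (0.05, 0.01),
    which: str = "bifurcation",
) -> pd.DataFrame:
    """Exact and approximate critical values for n = 1 .. n_max.

    Columns: ``n`` then, per significance level, ``exact_<tag>`` and
    ``approx_<tag>`` (e.g. ``exact_05``, ``approx_05``).  Exact entries are
    ``NaN`` where no count within range reaches significance.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    alphas = list(alphas)
    for a in alphas:
        _check_alpha(a)
    rows: dict[str, list] = {"n": list(range(1, n_max + 1))}
    for a in alphas:
        tag = _alpha_tag(a)
        exact_col: list[Optional[int]] = []
        approx_col: list[int] = []
        for n in range(1, n_max + 1):
            exact_col.append(critical_boundaries(n, a, which))
            approx_col.append(approx_critical(n, a, which))
        rows[f"exact_{tag}"] = exact_col
        rows[f"approx_{tag}"] = approx_col
    df = pd.DataFrame(rows)
    df.attrs["test_type"] = which
    return df


def write_critical_table(df: pd.DataFrame, path) -> None:
    """Serialize a critical table as TSV (header row, NA for unattainable)."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
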