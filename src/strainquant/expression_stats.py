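"""qPCR relative quantification and strain-expression correlation statistics.

Relative expression from threshold cycles uses the standard
2^(-DeltaCt) form with a single housekeeping reference gene
(amplification-efficiency correction is deliberately omitted; see the
methods note).  Expression values are normalized to the geometric mean of
a designated control group, and the association between normalized
expression and the per-sample applied strain level is measured with the
Spearman rank correlation.  For small samples (n <= 9) the two-sided
p-value is exact, by full enumeration of the rank permutations; larger
samples use the usual t-distribution approximation.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

#: significance threshold for the correlation test
ALPHA = 0.05
#: largest n for which the exact permutation p-value is enumerated
EXACT_P_MAX_N = 9


def relative_expression(ct_target: float, ct_housekeeping: float) -> float:
    """Relative expression 2^(-(Ct_target - Ct_housekeeping))."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_housekeeping = np.asarray(ct_housekeeping, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_housekeeping))):
        raise ValueError("Ct values must be finite")
    out = np.exp2(-(ct_target - ct_housekeeping))
    return float(out) if out.ndim == 0 else out


def normalize_to_control(
    values: np.ndarray, is_control: np.ndarray
) -> np.ndarray:
    """Divide all values by the geometric mean of the control group.

    After normalization the control group's geometric mean is exactly 1.

    Raises
    ------
    ValueError
        For an empty control group or non-positive values.
    """
    v = np.asarray(values, dtype=float)
    mask = np.asarray(is_control, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("control group is empty")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("expression ratios must be positive and finite")
    return v / stats.gmean(v[mask])


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two rank vectors."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom)


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with an exact small-sample p-value.

    rho is the Pearson correlation of the average-ranked data (ties get
    average ranks).  The two-sided p-value is exact for n <= 9 — the
    fraction of the n! equally likely rank orderings with |rho| at least
    as large as observed — and a t-approximation
    (t = rho sqrt((n-2)/(1-rho^2)), df = n-2) beyond.

    Raises
    ------
    ValueError
        For n < 4, unequal lengths, or zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("observations must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in the ranks of x or y")
    rho = _rank_rho(rx, ry)
    if n <= EXACT_P_MAX_N:
        p = _exact_p(rx, ry, rho)
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, np.finfo(float).tiny))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all permutations of the y ranks."""
    n = rx.size
    perms = np.array(list(permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc @ rxc) * np.einsum("ij,ij->i", pc, pc))
    rhos = pc @ rxc / denom
    # tolerance guards against ties lost to rounding
    hits = np.count_nonzero(np.abs(rhos) >= abs(rho_obs) - 1e-12)
    return hits / factorial(n)


def correlate_expression(
    table: pd.DataFrame,
    control_group: str,
    value_cols: tuple[str, str] = ("ct_target", "ct_housekeeping"),
) -> pd.DataFrame:
    """Full strain-correlation analysis of a tidy qPCR table.

    ``table`` needs columns sample_id, gene, group, ct_target,
    ct_housekeeping and strain_level (NaN for static samples).  Per gene,
    expression is computed by relative quantification, normalized to the
    geometric mean of ``control_group``, and the strained samples'
    normalized expression is correlated against their strain levels.

    Returns a DataFrame with columns gene, group, n, rho, p_value,
    direction ('up'/'down' for significant correlations, '' otherwise).
    """
    required = {"sample_id", "gene", "group", *value_cols, "strain_level"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table lacks columns: {sorted(missing)}")
    rows = []
    for gene, sub in table.groupby("gene", sort=True):
        expr = relative_expression(
            sub[value_cols[0]].to_numpy(), sub[value_cols[1]].to_numpy()
        )
        is_ctrl = (sub["group"] == control_group).to_numpy()
        if is_ctrl.sum() == 0:
            raise ValueError(f"gene {gene!r}: control group {control_group!r} empty")
        norm = normalize_to_control(expr, is_ctrl)
        strained = (~is_ctrl) & np.isfinite(sub["strain_level"].to_numpy())
        xs = sub["strain_level"].to_numpy()[strained]
        ys = norm[strained]
        rho, p = spearman_correlation(xs, ys)
        direction = "" if p >= ALPHA else ("up" if rho > 0 else "down")
        rows.append((gene, control_group, int(strained.sum()), rho, p, direction))
    return pd.DataFrame(
        rows, columns=["gene", "group", "n", "rho", "p_value", "direction"]
    )
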