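"""Split-plot (mixed) ANOVA for designs with one between factor and one or
two two-level within factors.

Because every within-subject factor here has exactly two levels, each
within-subject effect reduces to a per-participant contrast score (a
difference of cell means), and the classical split-plot F tests are exact
OLS tests on those contrasts:

* within main effect        -> Type III test of the intercept in
                               ``contrast ~ 1 + group``
* within x group interaction -> Type III test of the group term in the same model
* between (group) effect    -> Type III test of group in ``subject mean ~ 1 + group``

Two-level within factors need no sphericity correction. Type III sums of
squares (computed via model-comparison with effect-coded groups) keep the
tests well defined for unbalanced group sizes, which is the norm here
(15 resistant vs 35 responsive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _effect_code(groups: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(groups.unique())
    g = len(levels)
    cols = np.zeros((len(groups), g - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(groups == lev, 1.0, np.where(groups == levels[-1], -1.0, 0.0))
    return cols, levels


def _type3_tests(y: np.ndarray, group_cols: np.ndarray) -> dict[str, tuple[float, int, int, float]]:
    """Type III F for intercept and group term of ``y ~ 1 + group``.

    Returns {"intercept": (SS, df1, df2, F), "group": ...} plus the full-model
    residual SS under key "_sse".
    """
    n = len(y)
    X_full = np.column_stack([np.ones(n), group_cols])

    def sse(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    sse_full = sse(X_full)
    df_resid = n - X_full.shape[1]
    out: dict[str, tuple[float, int, int, float]] = {}
    for name, keep in (("intercept", group_cols), ("group", np.ones((n, 1)))):
        ss = sse(keep) - sse_full
        df1 = X_full.shape[1] - keep.shape[1]
        ms_err = sse_full / df_resid
        f = (ss / df1) / ms_err if ms_err > 0 else (np.inf if ss > 0 else 0.0)
        out[name] = (max(ss, 0.0), df1, df_resid, max(f, 0.0))
    out["_sse"] = (sse_full, 0, df_resid, 0.0)  # type: ignore[assignment]
    return out


def _row(source: str, ss: float, df1: int, df2: int, f: float, sse: float) -> dict:
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    np2 = ss / (ss + sse) if (ss + sse) > 0 else 0.0
    return {"Source": source, "SS": ss, "df1": df1, "df2": df2, "F": f, "p": p, "np2": np2}


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
) -> pd.DataFrame:
    """Mixed ANOVA table for 1 between factor and 1-2 two-level within factors.

    ``data`` is long format. Participants with incomplete within-cell data
    are dropped (they cannot contribute to every contrast); the returned
    table carries attrs ``n_used`` and ``n_dropped``.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("supports exactly 1 or 2 within-subject factors")
    for w in within:
        if data[w].nunique() != 2:
            raise ValueError(f"within factor {w!r} must have exactly 2 levels")

    wide = data.pivot_table(index=[subject, between], columns=within, values=dv, aggfunc="mean")
    n_cells = 2 ** len(within)
    complete = wide.dropna()
    complete = complete[complete.notna().sum(axis=1) == n_cells]
    n_dropped = len(wide) - len(complete)

    groups = complete.index.get_level_values(between).to_series(index=complete.index)
    group_cols, levels = _effect_code(groups.reset_index(drop=True))
    if len(levels) < 2:
        raise ValueError("between factor needs at least 2 levels")

    cells = complete.to_numpy()
    rows: list[dict] = []

    # between effect on subject means
    res = _type3_tests(cells.mean(axis=1), group_cols)
    sse_b = res["_sse"][0]
    rows.append(_row(between, *res["group"], sse=sse_b))

    if len(within) == 1:
        w = within[0]
        lv = sorted(data[w].unique())
        c = wide_contrast(complete, within, {w: lv})
        res = _type3_tests(c, group_cols)
        sse = res["_sse"][0]
        rows.append(_row(w, *res["intercept"], sse=sse))
        rows.append(_row(f"{between} * {w}", *res["group"], sse=sse))
    else:
        w1, w2 = within
        lv1, lv2 = sorted(data[w1].unique()), sorted(data[w2].unique())
        cols = complete.columns  # MultiIndex (w1, w2)
        arr = {key: complete[key].to_numpy() for key in cols}
        # main-effect contrasts: differences of means over the other factor
        c1 = 0.5 * (arr[(lv1[1], lv2[0])] + arr[(lv1[1], lv2[1])]) - 0.5 * (
            arr[(lv1[0], lv2[0])] + arr[(lv1[0], lv2[1])]
        )
        c2 = 0.5 * (arr[(lv1[0], lv2[1])] + arr[(lv1[1], lv2[1])]) - 0.5 * (
            arr[(lv1[0], lv2[0])] + arr[(lv1[1], lv2[0])]
        )
        c12 = (arr[(lv1[1], lv2[1])] - arr[(lv1[1], lv2[0])]) - (
            arr[(lv1[0], lv2[1])] - arr[(lv1[0], lv2[0])]
        )
        for name, c in ((w1, c1), (w2, c2), (f"{w1} * {w2}", c12)):
            res = _type3_tests(c, group_cols)
            sse = res["_sse"][0]
            rows.append(_row(name, *res["intercept"], sse=sse))
            rows.append(_row(f"{between} * {name}", *res["group"], sse=sse))

    table = pd.DataFrame(rows)
    table.attrs["n_used"] = len(complete)
    table.attrs["n_dropped"] = n_dropped
    return table


def wide_contrast(wide: pd.DataFrame, within: list[str], levels: dict[str, list]) -> np.ndarray:
    """Level-2 minus level-1 contrast for a single within factor."""
    w = within[0]
    lv = levels[w]
    return wide[lv[1]].to_numpy().ravel() - wide[lv[0]].to_numpy().ravel()
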