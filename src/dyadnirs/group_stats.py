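"""Group-level statistics on per-period coherence values.

Two questions are asked of the dyad-level MSC profiles:

1. Within real dyads, does coherence differ between the live and static
   face conditions at each period?  (paired t-test per period)
2. Is any such condition difference specific to real partners, i.e.
   larger than in shuffled (re-paired) dyads?  (2x2 fixed-effects ANOVA
   with factors dyad type {real, shuffled} x condition {live, static},
   per period; the interaction term is the coupling test)

The ANOVA treats each dyad-by-condition value as one observation of a
between-cells design (df_error = N_obs - 4; with 20+20 dyads and two
conditions, F(1, 76)); a repeated-measures variant is out of scope by
design.  Period-wise p-values are reported uncorrected, with an optional
Benjamini-Hochberg column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .glm import fdr_correct


def per_period_condition_test(
    live: np.ndarray, static: np.ndarray
) -> pd.DataFrame:
    """Paired t-test (live vs static) at every period.

    ``live`` and ``static`` are ``(n_dyads, n_periods)`` with rows
    aligned by dyad.  Returns a frame with ``t``, ``p`` (two-sided) and
    ``dof`` per period; equal condition values give t = 0, p = 1.
    """
    live = np.atleast_2d(np.asarray(live, dtype=float))
    static = np.atleast_2d(np.asarray(static, dtype=float))
    if live.shape != static.shape:
        raise ValueError("condition arrays must share a shape")
    if live.shape[0] < 2:
        raise ValueError("paired test needs at least 2 dyads")
    res = stats.ttest_rel(live, static, axis=0)
    t = np.where(np.isnan(res.statistic), 0.0, res.statistic)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.DataFrame(
        {"period_index": np.arange(live.shape[1]), "t": t, "p": p,
         "dof": live.shape[0] - 1}
    )


def anova_2x2_single(values: pd.DataFrame) -> dict:
    """Two-way fixed-effects ANOVA with interaction for one period.

    ``values`` has columns ``msc``, ``dyad_type`` and ``condition``; every
    cell of the 2x2 layout must be non-empty.  Returns F/p for both main
    effects and the interaction plus the dfs.
    """
    for factor, levels in (("dyad_type", 2), ("condition", 2)):
        if values[factor].nunique() != levels:
            raise ValueError(f"factor {factor!r} must have {levels} levels")
    counts = values.groupby(["dyad_type", "condition"]).size()
    if len(counts) < 4 or (counts == 0).any():
        raise ValueError("every cell of the 2x2 design must be non-empty")
    model = ols("msc ~ C(dyad_type) * C(condition)", data=values).fit()
    table = anova_lm(model, typ=2)
    inter = "C(dyad_type):C(condition)"
    # degenerate scale: SS that is float noise relative to the data magnitude
    scale = float((values["msc"] ** 2).sum()) + 1e-300

    def f_p(effect):
        # a zero-variance effect is no effect: F = 0, p = 1 (not 0/0)
        if float(table.loc[effect, "sum_sq"]) <= 1e-20 * scale:
            return 0.0, 1.0
        return float(table.loc[effect, "F"]), float(table.loc[effect, "PR(>F)"])

    f_a, p_a = f_p("C(dyad_type)")
    f_b, p_b = f_p("C(condition)")
    f_i, p_i = f_p(inter)
    return {
        "F_dyad_type": f_a,
        "p_dyad_type": p_a,
        "F_condition": f_b,
        "p_condition": p_b,
        "F_interaction": f_i,
        "p_interaction": p_i,
        "df_effect": int(table.loc[inter, "df"]),
        "df_error": int(table.loc["Residual", "df"]),
    }


def anova_2x2(results: pd.DataFrame, fdr_q: float | None = None) -> pd.DataFrame:
    """Period-wise 2x2 (dyad type x condition) ANOVA table.

    ``results`` is long-format with columns ``msc``, ``dyad_type``
    (real/shuffled), ``condition`` (live/static) and ``period_s``.  One
    row per period is returned; ``fdr_q`` adds a Benjamini-Hochberg
    rejection column for the interaction p-values.
    """
    rows = []
    for period, chunk in results.groupby("period_s"):
        res = anova_2x2_single(chunk)
        res["period_s"] = float(period)
        rows.append(res)
    out = pd.DataFrame(rows).sort_values("period_s").reset_index(drop=True)
    cols = ["period_s"] + [c for c in out.columns if c != "period_s"]
    out = out[cols]
    if fdr_q is not None:
        out["interaction_fdr_significant"] = fdr_correct(
            out["p_interaction"].to_numpy(), q=fdr_q
        )
    return out
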