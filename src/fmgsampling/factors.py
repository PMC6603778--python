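"""Factorial analysis of reconstruction error: frequency binning, N-way
ANOVA, and Tukey HSD multiple comparisons.

Resampling frequencies between 10 and 100 Hz are grouped into nine 10 Hz
intervals (left-closed, right-open, top edge closed).  A fixed-effects linear
model with the study factors — frequency group, action type, placement
(signal type), participant, interpolation method — plus the interpolation
interactions is fit by OLS, and Type II F tests are reported.  Frequency
groups are then compared pairwise with Tukey's Honestly Significant
Difference procedure (studentized-range simultaneous intervals).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

FREQ_MIN = 10.0
FREQ_MAX = 100.0
GROUP_WIDTH = 10.0

#: The nine ordered frequency-group labels, "10-20" ... "90-100".
FREQ_GROUPS = tuple(
    f"{int(lo)}-{int(lo + GROUP_WIDTH)}"
    for lo in np.arange(FREQ_MIN, FREQ_MAX, GROUP_WIDTH)
)

DEFAULT_FACTORS = ("freq_group", "action_type", "participant", "placement", "method")
DEFAULT_INTERACTIONS = tuple(
    (f, "method") for f in ("freq_group", "action_type", "participant", "placement")
)


def bin_frequencies(records: pd.DataFrame) -> pd.DataFrame:
    """Assign RMSE records to 10 Hz frequency groups over [10, 100] Hz.

    A sub-frequency f lands in [10k, 10(k+1)) for k = 1..9, with the 100 Hz
    top edge closed; records outside [10, 100] Hz are excluded.  Returns the
    retained rows with an ordered categorical ``freq_group`` column.
    """
    f = records["sub_frequency"].to_numpy(dtype=float)
    keep = (f >= FREQ_MIN) & (f <= FREQ_MAX)
    if not keep.any():
        raise ValueError(
            f"no records with sub_frequency in [{FREQ_MIN:g}, {FREQ_MAX:g}] Hz"
        )
    out = records.loc[keep].copy()
    fk = out["sub_frequency"].to_numpy(dtype=float)
    idx = np.minimum(
        ((fk - FREQ_MIN) // GROUP_WIDTH).astype(int), len(FREQ_GROUPS) - 1
    )
    out["freq_group"] = pd.Categorical.from_codes(
        idx, categories=list(FREQ_GROUPS), ordered=True
    )
    # Drop unpopulated groups so sparse step sets stay full rank downstream.
    out["freq_group"] = out["freq_group"].cat.remove_unused_categories()
    return out


def _term_name(factors: Sequence[str]) -> str:
    return ":".join(f"C({f})" for f in factors)


def n_way_anova(
    table: pd.DataFrame,
    response: str = "rmse",
    factors: Sequence[str] = DEFAULT_FACTORS,
    interactions: Sequence[tuple[str, str]] = DEFAULT_INTERACTIONS,
) -> pd.DataFrame:
    """Fixed-effects N-way ANOVA with Type II F tests.

    Returns a frame indexed by term with columns ``F``, ``p``, ``df`` and
    ``df_resid``; ``.attrs["degenerate"]`` flags a zero-variance response
    (all F undefined).  Raises on missing columns, factors with fewer than
    two levels, or a rank-deficient (aliased) design.
    """
    for col in (response, *factors):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from factor table")
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    for a, b in interactions:
        if a not in factors or b not in factors:
            raise ValueError(f"interaction ({a}, {b}) references unknown factor")

    y = table[response].to_numpy(dtype=float)
    degenerate = bool(np.allclose(y, y[0]))

    terms = [_term_name([f]) for f in factors]
    terms += [_term_name(list(pair)) for pair in interactions]
    formula = f"{response} ~ " + " + ".join(terms)

    model = smf.ols(formula, data=table)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        aliased = _aliased_terms(model)
        raise ValueError(
            "rank-deficient design: aliased term(s) "
            + (", ".join(aliased) if aliased else "<undetermined>")
        )
    fit = model.fit()

    if degenerate:
        report = pd.DataFrame(
            {
                "F": 0.0,
                "p": np.nan,
                "df": [_term_df(fit, t) for t in terms],
                "df_resid": fit.df_resid,
            },
            index=terms,
        )
        report.attrs["degenerate"] = True
        return report

    anova = sm.stats.anova_lm(fit, typ=2)
    anova = anova.drop(index=[i for i in ("Residual",) if i in anova.index])
    report = pd.DataFrame(
        {
            "F": anova["F"],
            "p": anova["PR(>F)"],
            "df": anova["df"].astype(int),
            "df_resid": int(fit.df_resid),
        }
    )
    report = report.loc[[t for t in terms if t in report.index]]
    report.attrs["degenerate"] = False
    return report


def _term_df(fit, term: str) -> int:
    sl = fit.model.data.design_info.term_name_slices.get(term)
    return (sl.stop - sl.start) if sl is not None else 0


def _aliased_terms(model) -> list[str]:
    """Best-effort mapping of linearly dependent design columns to term names."""
    exog = model.exog
    _, r = np.linalg.qr(exog)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(exog.shape) * np.finfo(float).eps
    bad_cols = set(np.nonzero(diag <= tol)[0])
    names = []
    info = model.data.design_info
    for term, sl in info.term_name_slices.items():
        if any(c in bad_cols for c in range(sl.start, sl.stop)):
            names.append(term)
    return names


def tukey_hsd(
    table: pd.DataFrame,
    response: str = "rmse",
    factor: str = "freq_group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise group comparisons with Tukey HSD simultaneous intervals.

    Returns one row per group pair with the mean difference, the simultaneous
    confidence interval at family-wise level ``alpha``, and a significance
    flag (interval excludes zero).
    """
    if factor not in table.columns or response not in table.columns:
        raise ValueError(f"columns {response!r} and {factor!r} required")
    groups = table[factor].astype(str)
    if groups.nunique() < 2:
        raise ValueError(f"Tukey HSD needs at least 2 groups in {factor!r}")
    res = pairwise_tukeyhsd(
        table[response].to_numpy(dtype=float), groups.to_numpy(), alpha=alpha
    )
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )
    out = pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "mean_diff": res.meandiffs,
            "ci_lower": res.confint[:, 0],
            "ci_upper": res.confint[:, 1],
            "significant": res.reject,
        }
    )
    out.attrs["alpha"] = alpha
    return out
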