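"""Multinomial logistic odds-ratio tables against a reference pattern.

Default layout matches single-predictor OR tables: each covariate is fitted
in its own multinomial model (univariable), on its raw scale, with Wald 95%
confidence intervals exp(beta +/- 1.96 se).  A joint model over all
predictors is available behind a flag for sensitivity analysis.  With only
two patterns the multinomial logit reduces to ordinary binary logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["OddsEntry", "fit_multinomial_or", "odds_table"]

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass
class OddsEntry:
    """One covariate-by-contrast row of the OR table."""

    predictor: str
    contrast: object          # pattern compared against the reference
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coefficient: float
    std_error: float
    flagged: bool = False     # separation / non-finite diagnostics
    note: str = ""


def _encode_predictor(
    data: pd.DataFrame, name: str, reference_levels: Mapping[str, object]
) -> pd.DataFrame:
    """Numeric columns pass through; categoricals dummy-code against a stated
    reference level (default: first sorted level)."""
    col = data[name]
    if pd.api.types.is_numeric_dtype(col):
        return pd.DataFrame({name: col.astype(float)})
    levels = sorted(col.astype(str).unique())
    ref = str(reference_levels.get(name, levels[0]))
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} absent from {name!r}")
    out = {}
    for level in levels:
        if level == ref:
            continue
        out[f"{name}[{level}]"] = (col.astype(str) == level).astype(float)
    return pd.DataFrame(out, index=data.index)


def _fit_one(
    endog: np.ndarray,
    exog: pd.DataFrame,
    contrasts: Sequence,
) -> list[OddsEntry]:
    design = sm.add_constant(exog, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(endog, design)
        try:
            fit = model.fit(method="newton", maxiter=200, disp=False)
        except Exception:
            fit = model.fit(method="bfgs", maxiter=500, disp=False)
    params = np.asarray(fit.params)      # (n_exog, K-1)
    bse = np.asarray(fit.bse)
    entries: list[OddsEntry] = []
    names = list(design.columns)
    for k, contrast in enumerate(contrasts):
        for row, pname in enumerate(names):
            if pname == "const":
                continue
            beta = float(params[row, k])
            se = float(bse[row, k])
            finite = np.isfinite(beta) and np.isfinite(se) and se < 50
            if finite:
                entries.append(
                    OddsEntry(
                        predictor=pname,
                        contrast=contrast,
                        odds_ratio=float(np.exp(beta)),
                        ci_low=float(np.exp(beta - _Z95 * se)),
                        ci_high=float(np.exp(beta + _Z95 * se)),
                        p_value=float(2 * (1 - _norm_cdf(abs(beta / se)))) if se > 0 else np.nan,
                        coefficient=beta,
                        std_error=se,
                    )
                )
            else:
                entries.append(
                    OddsEntry(
                        predictor=pname,
                        contrast=contrast,
                        odds_ratio=np.nan,
                        ci_low=np.nan,
                        ci_high=np.nan,
                        p_value=np.nan,
                        coefficient=beta,
                        std_error=se,
                        flagged=True,
                        note="non-finite or unstable estimate (possible separation)",
                    )
                )
    return entries


def _norm_cdf(x: float) -> float:
    from scipy.stats import norm

    return float(norm.cdf(x))


def fit_multinomial_or(
    data: pd.DataFrame,
    labels: Sequence,
    predictors: Sequence[str],
    reference,
    reference_levels: Mapping[str, object] | None = None,
    joint: bool = False,
) -> list[OddsEntry]:
    """Odds ratios of pattern membership versus ``reference`` for each predictor.

    ``data`` holds one column per predictor (numeric, or categorical to be
    dummy-coded against ``reference_levels``); ``labels`` gives each row's
    pattern.  Default is one model per predictor (univariable); ``joint=True``
    fits a single model over all predictors.
    """
    labels = pd.Series(list(labels), index=data.index)
    patterns = sorted(labels.unique(), key=str)
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns")
    if reference not in patterns:
        raise ValueError(f"reference pattern {reference!r} not present")
    reference_levels = dict(reference_levels or {})
    # statsmodels MNLogit takes outcome 0 as base; put the reference first
    others = [p for p in patterns if p != reference]
    code = {reference: 0, **{p: i + 1 for i, p in enumerate(others)}}
    endog = labels.map(code).to_numpy()

    if joint:
        exog = pd.concat(
            [_encode_predictor(data, name, reference_levels) for name in predictors],
            axis=1,
        )
        return _fit_one(endog, exog, others)
    entries: list[OddsEntry] = []
    for name in predictors:
        exog = _encode_predictor(data, name, reference_levels)
        entries.extend(_fit_one(endog, exog, others))
    return entries


def odds_table(entries: Sequence[OddsEntry]) -> pd.DataFrame:
    """Flat table with one row per (predictor, contrast)."""
    return pd.DataFrame(
        [
            {
                "predictor": e.predictor,
                "contrast": e.contrast,
                "odds_ratio": e.odds_ratio,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "flagged": e.flagged,
                "note": e.note,
            }
            for e in entries
        ]
    )
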