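"""Mixed linear models on the per-cycle metrics table.

The default model is ``Y ~ discipline + leg + discipline:leg`` with a random
intercept on the skier-session (ID) grouping factor, fitted by REML.  Term
significance comes from Wald tests on the fixed effects; pairwise contrasts
of estimated marginal means carry a studentized-range (Tukey) multiplicity
adjustment and a mixed-model Cohen's d standardized by the total standard
deviation sqrt(ID variance + residual variance).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats as sps
from scipy.stats import studentized_range
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

EFFECT_THRESHOLDS = (0.20, 0.50, 0.80)  # small / medium / large, closed lower bounds


@dataclass
class Contrast:
    """One pairwise difference of estimated marginal means."""

    family: str
    level_a: str
    level_b: str
    estimate: float  # a - b, on the (possibly transformed) response scale
    se: float
    p_adj: float  # Tukey-adjusted
    cohens_d: float  # magnitude; the sign lives in `estimate`
    magnitude: str  # trivial / small / medium / large


@dataclass
class ModelResult:
    """Fitted mixed model plus derived tables."""

    response: str
    formula: str
    transform: str  # none / log
    params: pd.Series  # fixed effects
    cov_params: pd.DataFrame
    group_var: float  # ID random-intercept variance
    resid_var: float
    anova: pd.DataFrame  # term, statistic, df, pvalue
    n_obs: int
    n_groups: int
    df_resid: float
    converged: bool
    contrasts: List[Contrast] = field(default_factory=list)
    _sm_result: object = None
    _data: pd.DataFrame = None

    @property
    def total_sd(self) -> float:
        return float(np.sqrt(self.group_var + self.resid_var))

    def term_pvalue(self, term: str) -> float:
        row = self.anova.loc[self.anova["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in ANOVA table")
        return float(row["pvalue"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "formula": self.formula,
            "transform": self.transform,
            "params": self.params.to_dict(),
            "group_var": self.group_var,
            "resid_var": self.resid_var,
            "anova": self.anova.to_dict(orient="records"),
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "contrasts": [vars(c) for c in self.contrasts],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _is_normal(values: np.ndarray, alpha: float = 0.01, seed: int = 0,
               cap: int = 500) -> Optional[bool]:
    """Shapiro-type normality decision; None when degenerate (constant)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 8 or np.ptp(values) == 0:
        return None
    if values.size > cap:
        rng = np.random.default_rng(seed)
        values = rng.choice(values, size=cap, replace=False)
    _, p = sps.shapiro(values)
    return p >= alpha


def maybe_log_transform(values) -> Tuple[np.ndarray, str]:
    """Log-transform a sample iff normality is rejected (and values allow it).

    Returns ``(values', flag)`` with flag in {"none", "log"}.  Non-positive
    values block the log branch with a warning.
    """
    values = np.asarray(values, dtype=float)
    normal = _is_normal(values)
    if normal is None or normal:
        return values, "none"
    if np.nanmin(values) <= 0:
        warnings.warn("non-normal response contains non-positive values; not log-transformed")
        return values, "none"
    return np.log(values), "log"


def fit_mixed(
    data: pd.DataFrame,
    response: str,
    formula: Optional[str] = None,
    groups: str = "ID",
    transform: str = "auto",
) -> ModelResult:
    """REML fit of a random-intercept mixed model on a metrics table.

    ``formula`` defaults to ``response ~ C(discipline) * C(leg)``; pass e.g.
    ``"{y} ~ C(discipline)"`` (with the ``{y}`` placeholder) for the reduced
    per-extremum model.  ``transform="auto"`` applies the log rule to the
    response when the residuals of a first fit reject normality.
    """
    data = data.copy()
    for col in (response, groups):
        if col not in data.columns:
            raise ValueError(f"metrics table lacks column {col!r}")
    data = data.dropna(subset=[response])
    if data[groups].nunique() < 3:
        raise ValueError("need at least 3 ID groups")

    if formula is None:
        formula = "{y} ~ C(discipline) * C(leg)"
    fml = formula.format(y=response) if "{y}" in formula else formula

    for fac in ("discipline", "leg"):
        if f"C({fac})" in fml and data[fac].nunique() < 2:
            raise ValueError(f"fixed factor {fac!r} needs >= 2 levels")

    def _fit(df: pd.DataFrame):
        model = smf.mixedlm(fml, data=df, groups=df[groups])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                res = model.fit(reml=True)
            except np.linalg.LinAlgError:
                # gradient blows up when the variance component collapses to
                # the boundary; a derivative-free search still converges
                res = model.fit(reml=True, method="powell", maxiter=2000)
        return res

    applied = "none"
    res = _fit(data)
    if transform == "auto":
        normal = _is_normal(res.resid)
        if normal is False and data[response].min() > 0:
            data[response] = np.log(data[response])
            res = _fit(data)
            applied = "log"
    elif transform == "log":
        if data[response].min() <= 0:
            raise ValueError("log transform requires positive response values")
        data[response] = np.log(data[response])
        res = _fit(data)
        applied = "log"

    k_fe = len(res.fe_params)
    try:
        cov_fe = res.cov_params().iloc[:k_fe, :k_fe]
    except np.linalg.LinAlgError:
        # boundary fit (random-effect variance ~ 0): fall back to the GLS
        # covariance with the intercept variance dropped, i.e. OLS form
        X = res.model.exog
        cov_fe = pd.DataFrame(
            res.scale * np.linalg.pinv(X.T @ X),
            index=res.fe_params.index,
            columns=res.fe_params.index,
        )
    anova = _wald_anova(res, cov_fe)
    return ModelResult(
        response=response,
        formula=fml,
        transform=applied,
        params=res.fe_params,
        cov_params=cov_fe,
        group_var=float(np.asarray(res.cov_re)[0, 0]),
        resid_var=float(res.scale),
        anova=anova,
        n_obs=int(res.nobs),
        n_groups=data[groups].nunique(),
        df_resid=float(res.nobs - k_fe - data[groups].nunique() + 1),
        converged=bool(getattr(res, "converged", True)),
        _sm_result=res,
        _data=data,
    )


def _wald_anova(res, cov_fe: pd.DataFrame) -> pd.DataFrame:
    """Per-term Wald F tests on the fixed effects."""
    design_info = res.model.data.design_info
    k_fe = len(res.fe_params)
    beta = res.fe_params.values
    cov = cov_fe.values
    df_denom = float(res.nobs - k_fe)
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = list(range(sl.start, sl.stop))
        b = beta[idx]
        C = cov[np.ix_(idx, idx)]
        df_num = len(idx)
        stat = float(b @ np.linalg.solve(C, b)) / df_num
        rows.append(
            {
                "term": term,
                "statistic": stat,
                "df_num": df_num,
                "pvalue": float(sps.f.sf(stat, df_num, df_denom)),
            }
        )
    return pd.DataFrame(rows)


def _cell_design(result: ModelResult, cells: pd.DataFrame) -> np.ndarray:
    design_info = result._sm_result.model.data.design_info
    return np.asarray(dmatrix(design_info, cells, return_type="matrix"))


def estimated_marginal_means(
    result: ModelResult, factor: str, by: Optional[str] = None
) -> pd.DataFrame:
    """Model-based means per level of ``factor`` (optionally within ``by``).

    Means average fixed-effect predictions over the levels of the other
    factor with equal weights; the random intercept averages to zero.
    """
    data = result._data
    factors = [factor] + ([by] if by else [])
    other = [
        c for c in ("discipline", "leg")
        if c in data.columns and c not in factors and f"C({c})" in result.formula
    ]
    rows = []
    for lev in sorted(data[factor].astype(str).unique()):
        sub = {factor: lev}
        by_levels = sorted(data[by].astype(str).unique()) if by else [None]
        for bl in by_levels:
            cell = dict(sub)
            if by:
                cell[by] = bl
            grid = [dict(cell)]
            for oc in other:
                grid = [
                    {**g, oc: ol}
                    for g in grid
                    for ol in sorted(data[oc].astype(str).unique())
                ]
            X = _cell_design(result, pd.DataFrame(grid))
            x = X.mean(axis=0)
            emm = float(x @ result.params.values)
            rows.append({"factor": factor, "level": lev, "by": bl, "emm": emm, "_x": x})
    return pd.DataFrame(rows)


def tukey_contrasts(
    result: ModelResult, factor: str = "discipline", by: Optional[str] = None
) -> List[Contrast]:
    """All pairwise EMM differences with Tukey-adjusted p and Cohen's d.

    With ``by`` set, comparisons run within each level of ``by`` and each
    slice forms its own Tukey family.
    """
    emms = estimated_marginal_means(result, factor, by)
    cov = result.cov_params.values
    contrasts: List[Contrast] = []
    for bl, group in emms.groupby("by", dropna=False):
        k = len(group)
        if k < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels for contrasts")
        family = factor if bl is None else f"{factor}|{by}={bl}"
        for (_, ra), (_, rb) in combinations(group.iterrows(), 2):
            c = ra["_x"] - rb["_x"]
            est = float(c @ result.params.values)
            se = float(np.sqrt(c @ cov @ c))
            if se == 0:
                raise ValueError("zero standard error in contrast")
            q = np.sqrt(2.0) * abs(est) / se
            p = float(studentized_range.sf(q, k, max(result.df_resid, 2.0)))
            d = cohens_d_mixed(est, result.group_var, result.resid_var)
            contrasts.append(
                Contrast(
                    family=family,
                    level_a=str(ra["level"]),
                    level_b=str(rb["level"]),
                    estimate=est,
                    se=se,
                    p_adj=min(1.0, p),
                    cohens_d=d,
                    magnitude=classify_effect(d),
                )
            )
    result.contrasts.extend(contrasts)
    return contrasts


def cohens_d_mixed(estimate: float, group_var: float, resid_var: float) -> float:
    """|difference| standardized by the total SD of the variance components."""
    if group_var < 0 or resid_var < 0:
        raise ValueError("variance components must be non-negative")
    total = group_var + resid_var
    if total == 0:
        raise ValueError("zero total variance; effect size undefined")
    return abs(estimate) / np.sqrt(total)


def classify_effect(d: float) -> str:
    """Magnitude label with closed lower bounds 0.20 / 0.50 / 0.80."""
    if d < 0:
        raise ValueError("d must be non-negative")
    small, medium, large = EFFECT_THRESHOLDS
    if d >= large:
        return "large"
    if d >= medium:
        return "medium"
    if d >= small:
        return "small"
    return "trivial"


def contrasts_to_frame(contrasts: Sequence[Contrast]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in contrasts])
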