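"""Longitudinal mixed-model inference on concentrations and volumes.

Metabolite concentrations are modelled as

    value ~ region * day  (both categorical)

with random intercepts for animal and for animal x region, giving the
nested covariance structure of repeated measurements: observations from the
same animal are correlated, and observations from the same region of the
same animal more so.  Lesion volumes use day as the only fixed effect with
an animal random intercept.  Fitting is REML via statsmodels' MixedLM.

Degrees of freedom for contrast t-tests use the containment rule of the
balanced split-plot layout: contrasts that involve region main effects are
tested against the animal-x-region stratum with (a-1)(r-1) df, while pure
time and interaction contrasts use the residual stratum.  On balanced data
this reproduces the classical exact F/t partition; Satterthwaite would give
the same numbers there and is not exposed by the fitting backend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

ALPHA = 0.05


def _fit_reml(model):
    """REML fit with optimizer fallbacks; returns the first converged
    result, or the last attempt if none converges (caller flags it)."""
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", None, "cg"):
            kwargs = {"reml": True}
            if method:
                kwargs["method"] = method
            try:
                result = model.fit(**kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if result.converged:
                return result
    if result is None:
        raise RuntimeError("mixed-model fit failed with every optimizer")
    return result


@dataclass
class MixedModelFit:
    """REML fit summary plus what contrast tests need."""

    fixed: pd.Series  # fixed-effect estimates
    varcomp: dict[str, float]  # variances: animal, animal_region, residual
    contrasts: pd.DataFrame | None
    converged: bool
    singular: bool  # any variance pinned at/near the zero boundary
    df_within: float
    df_between: float
    reference: dict[str, object] = field(default_factory=dict)
    _result: object = None
    _cells: pd.DataFrame | None = None
    _row_cache: dict = field(default_factory=dict)

    def contrast(self, label: str, cell_plus: dict, cell_minus: dict,
                 cell_plus2: dict | None = None, cell_minus2: dict | None = None,
                 between: bool = False) -> dict:
        """t-test of a (difference of) cell-mean difference(s)."""
        res = self._result
        design = res.model.data.design_info
        from patsy import build_design_matrices

        def row(cell):
            key = tuple(sorted(cell.items()))
            if key not in self._row_cache:
                self._row_cache[key] = np.asarray(
                    build_design_matrices([design], pd.DataFrame([cell]))[0])[0]
            return self._row_cache[key]

        lvec = row(cell_plus) - row(cell_minus)
        if cell_plus2 is not None:
            lvec = lvec - (row(cell_plus2) - row(cell_minus2))
        k = len(res.fe_params)
        est = float(lvec @ res.fe_params)
        cov = np.asarray(res.cov_params())[:k, :k]
        se = float(np.sqrt(lvec @ cov @ lvec))
        df = self.df_between if between else self.df_within
        tval = est / se if se > 0 else np.nan
        pval = 2.0 * sps.t.sf(abs(tval), df) if np.isfinite(tval) else np.nan
        return {"contrast": label, "estimate": est, "se": se, "df": df,
                "t": tval, "p": pval, "significant": bool(pval < ALPHA)
                if np.isfinite(pval) else False}


def _containment_dfs(df_: pd.DataFrame, animal_col: str, region_col: str | None,
                     day_col: str) -> tuple[float, float]:
    n = len(df_)
    a = df_[animal_col].nunique()
    d = df_[day_col].nunique()
    if region_col is None:
        # single-stratum layout: residual after animal and day
        within = n - a - (d - 1)
        return max(within, 1), max(a - 1, 1)
    r = df_[region_col].nunique()
    cells_ar = df_.groupby([animal_col, region_col]).ngroups
    within = n - cells_ar - (d - 1) - (r - 1) * (d - 1)
    between = (a - 1) * (r - 1)
    return max(within, 1), max(between, 1)


def fit_lmm(cohort: pd.DataFrame, response: str = "value_mM",
            region_col: str = "region", day_col: str = "day",
            animal_col: str = "animal",
            reference_region: str = "CONTRA") -> MixedModelFit:
    """REML mixed model of one metabolite's concentrations.

    ``cohort`` is a long table with one row per animal x region x day for a
    single response.  A singular fit (a variance component estimated at the
    zero boundary) is flagged, never silent.
    """
    df_ = cohort.copy()
    if df_[animal_col].nunique() < 2:
        raise ValueError("need at least 2 animals")
    counts = df_.groupby([region_col, day_col]).size()
    if (counts == 0).any():  # pragma: no cover - groupby drops empty cells
        raise ValueError("every region x day cell must be non-empty")
    df_["_day"] = pd.Categorical(df_[day_col].astype(int))
    df_["_region"] = pd.Categorical(
        df_[region_col],
        categories=[reference_region] + sorted(c for c in df_[region_col].unique()
                                               if c != reference_region))
    formula = f"{response} ~ C(_region) * C(_day)"
    model = smf.mixedlm(formula, df_, groups=df_[animal_col],
                        re_formula="1", vc_formula={"region": "0 + C(_region)"})
    result = _fit_reml(model)
    var_animal = float(result.cov_re.iloc[0, 0])
    var_ar = float(np.mean(list(result.vcomp))) if len(result.vcomp) else 0.0
    var_resid = float(result.scale)
    singular = min(var_animal, var_ar) < 1e-8 * max(var_resid, 1e-12)
    df_within, df_between = _containment_dfs(df_, animal_col, region_col, day_col)
    fit = MixedModelFit(
        fixed=result.fe_params,
        varcomp={"animal": var_animal, "animal_region": var_ar,
                 "residual": var_resid},
        contrasts=None, converged=bool(result.converged), singular=singular,
        df_within=df_within, df_between=df_between,
        reference={"region": reference_region,
                   "regions": list(df_["_region"].cat.categories),
                   "days": sorted(df_["_day"].cat.categories)},
        _result=result, _cells=df_[["_region", "_day"]].drop_duplicates())
    fit.contrasts = region_time_contrasts(fit)
    return fit


def region_time_contrasts(fit: MixedModelFit) -> pd.DataFrame:
    """The standard comparison set: each lesional region vs the
    contralesional reference at each day, and last-day vs first-day within
    each region.  Two-sided p-values, no multiplicity correction (a Holm
    column can be added downstream if wanted)."""
    ref = fit.reference["region"]
    regions = [r for r in fit.reference["regions"] if r != ref]
    days = fit.reference["days"]
    rows = []
    for day in days:
        for region in regions:
            rows.append(fit.contrast(
                f"{region} vs {ref} @ day {day}",
                {"_region": region, "_day": day}, {"_region": ref, "_day": day},
                between=True))
    d0, d1 = days[0], days[-1]
    for region in [ref] + regions:
        rows.append(fit.contrast(
            f"{region} day {d1} vs day {d0}",
            {"_region": region, "_day": d1}, {"_region": region, "_day": d0}))
    for region in regions:
        rows.append(fit.contrast(
            f"({region} - {ref}) x (day {d1} - day {d0})",
            {"_region": region, "_day": d1}, {"_region": region, "_day": d0},
            {"_region": ref, "_day": d1}, {"_region": ref, "_day": d0}))
    return pd.DataFrame(rows)


def holm_adjust(pvals: pd.Series) -> pd.Series:
    """Holm step-down adjusted p-values (optional, off by default)."""
    from statsmodels.stats.multitest import multipletests
    ok = pvals.notna()
    adj = pd.Series(np.nan, index=pvals.index)
    if ok.any():
        adj.loc[ok] = multipletests(pvals[ok], method="holm")[1]
    return adj


def fit_volume_model(volumes: pd.DataFrame, outcome: str = "edema_ml",
                     day_col: str = "day", animal_col: str = "animal"
                     ) -> MixedModelFit:
    """Mixed model for one lesion-volume outcome: categorical day fixed
    effect, animal random intercept."""
    df_ = volumes.copy()
    if df_[animal_col].nunique() < 2:
        raise ValueError("need at least 2 animals")
    df_["_day"] = pd.Categorical(df_[day_col].astype(int))
    model = smf.mixedlm(f"{outcome} ~ C(_day)", df_, groups=df_[animal_col],
                        re_formula="1")
    result = _fit_reml(model)
    var_animal = float(result.cov_re.iloc[0, 0])
    var_resid = float(result.scale)
    df_within, df_between = _containment_dfs(df_, animal_col, None, day_col)
    days = sorted(df_["_day"].cat.categories)
    fit = MixedModelFit(
        fixed=result.fe_params,
        varcomp={"animal": var_animal, "residual": var_resid},
        contrasts=None, converged=bool(result.converged),
        singular=var_animal < 1e-8 * max(var_resid, 1e-12),
        df_within=df_within, df_between=df_between,
        reference={"days": days, "outcome": outcome}, _result=result)
    rows = [fit.contrast(f"day {d} vs day {days[0]}",
                         {"_day": d}, {"_day": days[0]})
            for d in days[1:]]
    fit.contrasts = pd.DataFrame(rows)
    return fit


def correlation_report(volumes: pd.DataFrame, cohort: pd.DataFrame,
                       vol_cols: tuple[str, ...] = ("hematoma_ml", "edema_ml"),
                       ) -> pd.DataFrame:
    """Descriptive Pearson correlations of lesion volumes with metabolite
    concentrations per region (correlation + p, no modelling)."""
    merged = cohort.merge(volumes, on=["animal", "day"], how="inner")
    rows = []
    for met in sorted(merged["metabolite"].unique()):
        for region in sorted(merged["region"].unique()):
            sub = merged[(merged["metabolite"] == met) & (merged["region"] == region)]
            for vc in vol_cols:
                r, p = sps.pearsonr(sub[vc], sub["value_mM"])
                rows.append({"metabolite": met, "region": region,
                             "volume": vc, "r": r, "p": p})
    return pd.DataFrame(rows)
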