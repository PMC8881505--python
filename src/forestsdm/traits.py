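"""Trait-level meta-analysis of model training gain.

Second-level inference across species: does roosting ecology (tree vs
non-tree) or flight morphology (wing loading, aspect ratio) explain how much
of each species' distribution model is driven by forest structure? Gains
enter untransformed; linear models include the number of occurrence records
as a covariate; families of per-variable ANOVAs are Holm-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DataError
from .forest_variables import VariableCatalog

__all__ = [
    "TraitTestResult",
    "anova_two_group",
    "anova_from_summary",
    "holm_adjust",
    "lm_gain_on_trait",
    "gain_by_group",
    "build_gain_profiles",
    "trait_test_table",
]


@dataclass
class TraitTestResult:
    """One trait-gain test: F statistic, degrees of freedom, R², p-values."""

    label: str
    F: float
    df1: int
    df2: int
    r2: float
    p: float
    p_adjusted: float | None = None
    overflow: bool = False  # zero within-group variance: F unbounded
    trait_p: float | None = None  # partial p of the trait term in linear models
    note: str = ""

    def as_row(self) -> dict:
        return {
            "test": self.label,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "R2": self.r2,
            "p": self.p,
            "p_adj": self.p_adjusted,
            "trait_p": self.trait_p,
            "overflow": self.overflow,
            "note": self.note,
        }


def anova_two_group(values, groups, label: str = "anova") -> TraitTestResult:
    """One-way ANOVA between two groups from raw values.

    F = SSB/df1 over SSW/df2 with df (1, n-2); R² = SSB/SST. Zero within-group
    variance with distinct means is reported as an overflow flag rather than a
    number.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise DataError(f"anova_two_group needs exactly two groups, got {len(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs at least two observations")
    n = len(values)
    grand = values.mean()
    ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    sst = ssb + ssw
    r2 = float(ssb / sst) if sst > 0 else 0.0
    df1, df2 = 1, n - 2
    if ssw <= 0:
        if ssb <= 0:
            return TraitTestResult(label, 0.0, df1, df2, 0.0, 1.0)
        return TraitTestResult(label, float("inf"), df1, df2, 1.0, 0.0, overflow=True)
    f = float((ssb / df1) / (ssw / df2))
    p = float(stats.f.sf(f, df1, df2))
    return TraitTestResult(label, f, df1, df2, r2, p)


def anova_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, label: str = "anova"
) -> TraitTestResult:
    """One-way two-group ANOVA recomputed from printed summaries (mean, SD, n)."""
    if s1 < 0 or s2 < 0:
        raise DataError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise DataError("each group needs at least two observations")
    n = n1 + n2
    grand = (n1 * m1 + n2 * m2) / n
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = (n1 - 1) * s1**2 + (n2 - 1) * s2**2
    df1, df2 = 1, n - 2
    msw = ssw / df2
    sst = ssb + ssw
    r2 = float(ssb / sst) if sst > 0 else 0.0
    if msw <= 0:
        if ssb <= 0:
            return TraitTestResult(label, 0.0, df1, df2, 0.0, 1.0)
        return TraitTestResult(label, float("inf"), df1, df2, 1.0, 0.0, overflow=True)
    f = float(ssb / msw)
    return TraitTestResult(label, f, df1, df2, r2, float(stats.f.sf(f, df1, df2)))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment: sort ascending, multiply p_(i) by (m-i),
    enforce monotonicity with a running maximum, cap at 1, restore order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def lm_gain_on_trait(
    profiles: pd.DataFrame,
    response: str,
    trait: str,
    covariate: str = "n_records",
    label: str | None = None,
) -> TraitTestResult:
    """Linear model ``response ~ trait + covariate`` across species.

    Reports the overall model F with (2, n-3) df, R², overall p, and the
    trait term's partial-t p-value. A trait collinear with the covariate is
    flagged and its partial p marked unreliable.
    """
    df = profiles[[response, trait, covariate]].dropna().copy()
    n = len(df)
    if df[response].nunique() <= 1:  # no variance to explain
        return TraitTestResult(
            label or f"{response}~{trait}", 0.0, 2, max(n - 3, 0), 0.0, 1.0, trait_p=1.0
        )
    is_cat = df[trait].dtype == object or isinstance(df[trait].dtype, pd.CategoricalDtype)
    if is_cat and df[trait].value_counts().min() < 2:
        raise DataError(f"trait {trait!r}: each level needs at least two species")
    term = f"C({trait})" if is_cat else trait
    model = smf.ols(f"{response} ~ {term} + {covariate}", data=df).fit()
    note = ""
    trait_cols = [c for c in model.params.index if c not in ("Intercept", covariate)]
    trait_p = float(model.pvalues[trait_cols[0]]) if trait_cols else float("nan")
    if not is_cat:
        r = df[trait].corr(df[covariate])
        if np.isfinite(r) and abs(r) > 0.99:
            note = "trait collinear with covariate; partial p unreliable"
    return TraitTestResult(
        label or f"{response}~{trait}",
        F=float(model.fvalue),
        df1=int(model.df_model),
        df2=int(model.df_resid),
        r2=float(model.rsquared),
        p=float(model.f_pvalue),
        trait_p=trait_p,
        note=note,
    )


def gain_by_group(
    per_variable_gain: dict[str, float], catalog: VariableCatalog
) -> pd.DataFrame:
    """Absolute and percentage training-gain shares per mechanistic group."""
    rows: dict[str, float] = {g: 0.0 for g in catalog.GROUPS}
    for var, g in per_variable_gain.items():
        rows[catalog.group_of(var)] += g  # raises DataError on unmapped variables
    total = sum(rows.values())
    return pd.DataFrame(
        {
            "group": list(rows),
            "gain": list(rows.values()),
            "share_pct": [100.0 * v / total if total > 0 else 0.0 for v in rows.values()],
        }
    )


FOREST_GROUPS = ("roost_availability", "heterogeneity", "clutter", "composition")


def build_gain_profiles(
    species_results: list[dict], catalog: VariableCatalog
) -> pd.DataFrame:
    """Assemble the species × gain-component table used by the trait tests.

    Each input dict needs: name, roosting, wing_loading, aspect_ratio,
    forager_class, n_records, gain, contributions (variable -> gain share).
    """
    rows = []
    for res in species_results:
        groups = gain_by_group(res["contributions"], catalog).set_index("group")["gain"]
        row = {
            "species": res["name"],
            "roosting": res["roosting"],
            "wing_loading": res["wing_loading"],
            "aspect_ratio": res["aspect_ratio"],
            "forager_class": res.get("forager_class", "within-forest"),
            "n_records": res["n_records"],
            "total_gain": res["gain"],
            "forest_gain": float(sum(groups[g] for g in FOREST_GROUPS)),
        }
        for g in catalog.GROUPS:
            row[f"gain_{g}"] = float(groups[g])
        for var, val in res["contributions"].items():
            row[f"var_{var}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def trait_test_table(profiles: pd.DataFrame, catalog: VariableCatalog) -> pd.DataFrame:
    """The full trait-analysis suite over a gain-profile table.

    Linear models (gain ~ trait + n_records) for roosting ecology, wing
    loading and aspect ratio; ANOVAs of forest-gain components by roosting
    group; per-roost-availability-variable ANOVAs with Holm correction.
    Wing-morphology tests use the within-forest foragers only.
    """
    results: list[TraitTestResult] = []
    results.append(
        lm_gain_on_trait(profiles, "total_gain", "roosting", label="lm total_gain ~ roosting + n")
    )
    foragers = profiles[profiles["forager_class"] == "within-forest"]
    for trait in ("wing_loading", "aspect_ratio"):
        try:
            results.append(
                lm_gain_on_trait(foragers, "forest_gain", trait, label=f"lm forest_gain ~ {trait} + n")
            )
        except Exception:
            pass
    results.append(
        anova_two_group(
            profiles["forest_gain"], profiles["roosting"], label="anova forest_gain ~ roosting"
        )
    )
    for g in FOREST_GROUPS + ("forest_proportion",):
        results.append(
            anova_two_group(
                profiles[f"gain_{g}"], profiles["roosting"], label=f"anova gain_{g} ~ roosting"
            )
        )
    # per-variable family over roost-availability variables, Holm-corrected
    family: list[TraitTestResult] = []
    for var in catalog.variables_in_group("roost_availability"):
        col = f"var_{var}"
        if col in profiles.columns:
            family.append(
                anova_two_group(profiles[col].fillna(0.0), profiles["roosting"], label=f"anova var {var} ~ roosting")
            )
    if family:
        adj = holm_adjust([t.p for t in family])
        for t, a in zip(family, adj):
            t.p_adjusted = float(a)
        results.extend(family)
    return pd.DataFrame([t.as_row() for t in results])
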