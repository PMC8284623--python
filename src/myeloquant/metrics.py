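"""Per-case population summaries and cross-group statistical comparisons.

Population abundances are reported both as proportions of total gated
cells and as densities (cells/mm² of stained tissue); the per-case
microglia:TAM count ratio is the study-level prognostic covariate handed
to the survival module.  Group comparisons wrap the standard tests used
for this kind of data: Mann-Whitney U for two groups, two-way ANOVA
(type-II sums of squares) with Tukey or Sidak multiple-comparison
post-hocs for grouped designs, and a paired t-test for matched cases,
gated by Shapiro-Wilk normality and F-test variance checks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, SchemaError, ValidationError
from .gating import PopulationCall, _check_alignment
from .segmentation import CellTable, intensity_column

__all__ = [
    "CaseSummary",
    "GroupComparison",
    "summarize_case",
    "summarize_cases",
    "collapse_replicates",
    "compare_populations",
    "two_way_anova",
    "normality_gate",
]


@dataclass
class CaseSummary:
    """Population counts, proportions, densities and intensity summaries for one case."""

    case_id: str
    tissue_type: str
    total_gated: int
    microglia_count: int
    tam_count: int
    prop_microglia: float
    prop_tam: float
    density_total: float
    density_microglia: float
    density_tam: float
    ratio_mg_tam: float
    ratio_degenerate: bool
    tissue_area_mm2: float
    mean_intensity: dict[str, dict[str, float]] = field(default_factory=dict)
    cd_high_count: int | None = None
    cd_low_count: int | None = None
    prop_cd_high: float | None = None
    cd_marker: str | None = None
    global_expression_index: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            k: getattr(self, k)
            for k in (
                "case_id",
                "tissue_type",
                "total_gated",
                "microglia_count",
                "tam_count",
                "prop_microglia",
                "prop_tam",
                "density_total",
                "density_microglia",
                "density_tam",
                "ratio_mg_tam",
                "ratio_degenerate",
                "tissue_area_mm2",
                "cd_high_count",
                "cd_low_count",
                "prop_cd_high",
                "cd_marker",
            )
        }
        for pop, markers in self.mean_intensity.items():
            for m, v in markers.items():
                row[f"mean_{m}_{pop}"] = v
        for m, v in self.global_expression_index.items():
            row[f"gei_{m}"] = v
        return row


def _ratio(mg: int, tam: int, zero_tam: str) -> tuple[float, bool]:
    """Microglia:TAM count ratio with the zero-TAM convention.

    zero_tam="inf"        — +inf sentinel, flagged so ratio statistics can
                             exclude it;
    zero_tam="continuity" — (mg + 0.5) / (tam + 0.5).
    """
    if zero_tam == "continuity":
        return (mg + 0.5) / (tam + 0.5), False
    if tam == 0:
        warnings.warn(f"zero TAM count: microglia:TAM ratio is +inf (mg={mg})")
        return float("inf"), True
    return mg / tam, False


def summarize_case(
    table: CellTable,
    calls: PopulationCall,
    zero_tam: str = "inf",
    microglial_markers: Sequence[str] = ("P2RY12", "TMEM119"),
) -> CaseSummary:
    """Summarise a single-case table; see summarize_cases for pooled tables."""
    cases = table.case_ids
    if len(cases) != 1:
        raise ValidationError(f"summarize_case expects one case, got {list(cases)}")
    return summarize_cases(table, calls, zero_tam, microglial_markers)[0]


def summarize_cases(
    table: CellTable,
    calls: PopulationCall,
    zero_tam: str = "inf",
    microglial_markers: Sequence[str] = ("P2RY12", "TMEM119"),
) -> list[CaseSummary]:
    """Per-case summaries from a (possibly pooled) gated cell table.

    total_gated counts non-debris cells; proportions are of total gated;
    densities divide counts by the case's stained-tissue area (mm²).  The
    global expression index for each microglial marker is the per-case
    integrated intensity (sum over non-debris cells of mean intensity x
    area_px) normalised to total myeloid density.
    """
    _check_alignment(table, calls)
    if zero_tam not in ("inf", "continuity"):
        raise ValidationError("zero_tam must be 'inf' or 'continuity'")
    df = table.df.copy()
    df["primary_label"] = calls.labels["primary_label"].to_numpy()
    has_secondary = "secondary_label" in calls.labels.columns
    if has_secondary:
        df["secondary_label"] = calls.labels["secondary_label"].to_numpy()
        cd_marker = calls.labels["secondary_marker"].iloc[0] if len(calls.labels) else None
    else:
        cd_marker = None
    out: list[CaseSummary] = []
    panel = table.markers
    gei_markers = [m for m in panel if m in microglial_markers]
    for case_id, sub in df.groupby("case_id", sort=True):
        area = float(sub["tissue_area_mm2"].iloc[0])
        if area <= 0:
            raise ValidationError(f"case {case_id}: tissue area must be > 0")
        nondebris = sub[sub["primary_label"] != "debris"]
        mg = int((nondebris["primary_label"] == "microglia").sum())
        tam = int((nondebris["primary_label"] == "tam").sum())
        total = len(nondebris)
        ratio, degenerate = _ratio(mg, tam, zero_tam)
        mean_intensity = {
            pop: {
                m: float(nondebris.loc[nondebris["primary_label"] == pop, intensity_column(m)].mean())
                for m in panel
            }
            for pop in ("microglia", "tam")
        }
        gei = {}
        for m in gei_markers:
            integrated = float(
                (nondebris[intensity_column(m)] * nondebris["area_px"]).sum()
            )
            gei[m] = integrated / (total / area) if total else float("nan")
        summary = CaseSummary(
            case_id=case_id,
            tissue_type=str(sub["tissue_type"].iloc[0]),
            total_gated=total,
            microglia_count=mg,
            tam_count=tam,
            prop_microglia=mg / total if total else float("nan"),
            prop_tam=tam / total if total else float("nan"),
            density_total=total / area,
            density_microglia=mg / area,
            density_tam=tam / area,
            ratio_mg_tam=ratio,
            ratio_degenerate=degenerate,
            tissue_area_mm2=area,
            mean_intensity=mean_intensity,
            global_expression_index=gei,
        )
        if has_secondary:
            sc = nondebris["secondary_label"].value_counts()
            summary.cd_high_count = int(sc.get("cd_high", 0))
            summary.cd_low_count = int(sc.get("cd_low", 0))
            summary.prop_cd_high = summary.cd_high_count / total if total else float("nan")
            summary.cd_marker = cd_marker
        out.append(summary)
    return out


def summaries_frame(summaries: Sequence[CaseSummary]) -> pd.DataFrame:
    """Flatten CaseSummary objects into one DataFrame row per case."""
    return pd.DataFrame([s.as_row() for s in summaries])


def collapse_replicates(
    summaries: pd.DataFrame, replicate_key: str = "base_case_id"
) -> pd.DataFrame:
    """Average repeated-staining replicates of one case before cross-case stats.

    ``replicate_key`` names the column identifying the underlying case; all
    numeric columns are averaged within it, non-numeric columns must be
    constant within a group.  Cross-case statistics must always run on the
    collapsed table so a case stained twice is not counted twice.
    """
    if replicate_key not in summaries.columns:
        raise SchemaError(f"replicate key column {replicate_key!r} missing")
    num = summaries.select_dtypes(include=[np.number, bool]).columns
    meta = [
        c for c in summaries.columns if c not in num and c not in (replicate_key, "case_id")
    ]
    grouped = summaries.groupby(replicate_key, sort=True)
    for c in meta:
        if (grouped[c].nunique() > 1).any():
            raise ValidationError(f"non-numeric column {c!r} varies within a replicate group")
    out = grouped[list(num)].mean().reset_index()
    for c in meta:
        out[c] = grouped[c].first().to_numpy()
    if "case_id" in summaries.columns:
        out["case_id"] = grouped["case_id"].agg("+".join).to_numpy()
    out["n_replicates"] = grouped.size().to_numpy()
    return out


@dataclass
class GroupComparison:
    """Result of one standard group comparison, with per-group descriptives."""

    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    per_group: dict[str, dict[str, float]]
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")


def _descriptives(groups: Mapping[str, np.ndarray]) -> dict[str, dict[str, float]]:
    return {
        str(k): {
            "n": int(len(v)),
            "mean": float(np.mean(v)) if len(v) else float("nan"),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
        }
        for k, v in groups.items()
    }


def compare_populations(
    summaries: pd.DataFrame,
    metric: str,
    design: str,
    group_col: str = "tissue_type",
    pair_col: str | None = None,
) -> GroupComparison:
    """Compare a per-case metric across groups with a named standard test.

    design="mann_whitney_u" — exactly two groups, exact p for small samples;
    design="paired_t"       — two matched groups, paired on ``pair_col``;
    design="two_way_anova_tukey" / "two_way_anova_sidak" — see two_way_anova,
    with ``metric`` as the value column and (group_col, "population") factors.
    """
    if metric not in summaries.columns:
        raise SchemaError(f"metric column {metric!r} missing")
    if design in ("two_way_anova_tukey", "two_way_anova_sidak"):
        raise ValidationError(
            "two-way designs need a long-format table; call two_way_anova directly"
        )
    groups = {
        str(k): sub[metric].dropna().to_numpy()
        for k, sub in summaries.groupby(group_col, sort=True)
    }
    if len(groups) != 2:
        raise ValidationError(f"{design} requires exactly 2 groups, got {len(groups)}")
    (ga, va), (gb, vb) = groups.items()
    for g, v in groups.items():
        if len(v) < 1:
            raise InsufficientDataError(f"group {g!r} has no cases")
    if design == "mann_whitney_u":
        res = stats.mannwhitneyu(va, vb, alternative="two-sided", method="auto")
        return GroupComparison(
            "mann_whitney_u", (ga, gb), float(res.statistic), float(res.pvalue), _descriptives(groups)
        )
    if design == "paired_t":
        if pair_col is None:
            raise ValidationError("paired_t requires pair_col to match cases across groups")
        a = summaries[summaries[group_col].astype(str) == ga].set_index(pair_col)[metric]
        b = summaries[summaries[group_col].astype(str) == gb].set_index(pair_col)[metric]
        common = a.index.intersection(b.index)
        if len(common) < 2:
            raise InsufficientDataError("paired_t needs >= 2 matched pairs")
        x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
        if np.allclose(x, y):
            stat, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(x, y)
            stat, p = float(res.statistic), float(res.pvalue)
        return GroupComparison(
            "paired_t", (ga, gb), stat, p, _descriptives({ga: x, gb: y}), {"n_pairs": len(common)}
        )
    raise ValidationError(f"unknown design {design!r}")


def two_way_anova(
    long: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    posthoc: str = "tukey",
) -> GroupComparison:
    """Two-way ANOVA (type-II SS, OLS with interaction) plus a post-hoc.

    ``long`` is one row per (case, population) observation.  posthoc="tukey"
    runs Tukey HSD on the factor_a x factor_b cell combinations;
    posthoc="sidak" runs all pairwise Welch t-tests with Sidak correction.
    The reported statistic/p are for the factor_a main effect; the full
    ANOVA table and post-hoc frame are in ``details``.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for c in (value, factor_a, factor_b):
        if c not in long.columns:
            raise SchemaError(f"column {c!r} missing")
    data = long.dropna(subset=[value]).copy()
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    if (counts < 2).any():
        raise InsufficientDataError(
            f"every {factor_a} x {factor_b} cell needs >= 2 observations; "
            f"smallest is {counts.idxmin()} with {int(counts.min())}"
        )
    model = ols(f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    data["_cell"] = data[factor_a].astype(str) + ":" + data[factor_b].astype(str)
    if posthoc == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        hsd = pairwise_tukeyhsd(data[value], data["_cell"])
        post = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    elif posthoc == "sidak":
        cells = sorted(data["_cell"].unique())
        rows = []
        m = len(cells) * (len(cells) - 1) // 2
        for a, b in itertools.combinations(cells, 2):
            x = data.loc[data["_cell"] == a, value]
            y = data.loc[data["_cell"] == b, value]
            t = stats.ttest_ind(x, y, equal_var=False)
            p_adj = 1.0 - (1.0 - min(t.pvalue, 1.0)) ** m
            rows.append({"group1": a, "group2": b, "p_raw": float(t.pvalue), "p_sidak": min(p_adj, 1.0)})
        post = pd.DataFrame(rows)
    else:
        raise ValidationError(f"unknown posthoc {posthoc!r}")
    a_row = table.index[0]
    groups = {
        str(k): sub[value].to_numpy() for k, sub in data.groupby(factor_a, sort=True)
    }
    return GroupComparison(
        f"two_way_anova_{posthoc}",
        tuple(sorted(map(str, data[factor_a].unique()))),
        float(table.loc[a_row, "F"]),
        float(table.loc[a_row, "PR(>F)"]),
        _descriptives(groups),
        details={"anova_table": table, "posthoc": post},
    )


def normality_gate(values_by_group: Mapping[str, Sequence[float]]) -> dict:
    """Shapiro-Wilk per group plus an equal-variance check; recommends a route.

    Returns {"shapiro_p": {group: p or None}, "variance_ratio_p": p or None,
    "recommendation": "parametric" | "nonparametric", "warnings": [...]}.
    Groups with n < 3 or zero variance skip Shapiro with a warning and force
    the nonparametric route.  The variance check is an F-test for two groups
    and Bartlett's test for more.
    """
    shapiro_p: dict[str, float | None] = {}
    notes: list[str] = []
    nonparametric = False
    arrays = {str(k): np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for g, v in arrays.items():
        if len(v) < 3:
            notes.append(f"group {g!r}: n < 3, Shapiro-Wilk skipped")
            shapiro_p[g] = None
            nonparametric = True
        elif np.ptp(v) == 0:
            notes.append(f"group {g!r}: constant values, Shapiro-Wilk undefined")
            shapiro_p[g] = None
            nonparametric = True
        else:
            p = float(stats.shapiro(v).pvalue)
            shapiro_p[g] = p
            if p < 0.05:
                nonparametric = True
    var_p: float | None = None
    usable = [v for v in arrays.values() if len(v) >= 2 and np.ptp(v) > 0]
    if len(usable) == len(arrays) and len(arrays) >= 2:
        if len(arrays) == 2:
            a, b = usable
            f = np.var(a, ddof=1) / np.var(b, ddof=1)
            dfa, dfb = len(a) - 1, len(b) - 1
            p_one = stats.f.sf(f, dfa, dfb) if f >= 1 else stats.f.cdf(f, dfa, dfb)
            var_p = float(min(1.0, 2 * p_one))
        else:
            var_p = float(stats.bartlett(*usable).pvalue)
        if var_p < 0.05:
            nonparametric = True
    else:
        notes.append("variance test skipped (degenerate or single group)")
    return {
        "shapiro_p": shapiro_p,
        "variance_ratio_p": var_p,
        "recommendation": "nonparametric" if nonparametric else "parametric",
        "warnings": notes,
    }
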