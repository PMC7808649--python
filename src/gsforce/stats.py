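"""Statistical battery for the stepped force-effectiveness model.

The cohort analysis is organized in four levels, each fitted on four
datasets (course averages plus the speed / overspeed / flat sections):

* Level 1 — stepwise regression of course time T on the sectional
  performance parameters (de_mech/v_in, L);
* Level 2 — Pearson correlations of sectional F_r with T and with
  sectional de_mech/v_in;
* Level 3 — stepwise regression of F_r on force magnitude (F_tot) and
  application effectiveness (RF);
* Level 4 — stepwise regression of F_tot on the outside-limb force
  (F_out) and the limb imbalance (F_diff).

Screening uses Shapiro-Wilk; section contrasts use one-way
repeated-measures ANOVA with Holm-corrected paired post-hocs and
Cohen's d.  Correlation magnitudes are labelled at |r| thresholds
0.1 / 0.3 / 0.5 / 0.8 and effect sizes at d thresholds 0.2 / 0.5 / 0.8
(trivial, small, moderate, strong, very strong).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import SECTIONS, StatsConfig
from .metrics import RunSummary

_LABELS = ("trivial", "small", "moderate", "strong", "very strong")


def correlation_magnitude(r: float) -> str:
    """Qualitative label for a correlation coefficient."""
    return _LABELS[int(np.searchsorted([0.1, 0.3, 0.5, 0.8], abs(r), side="right"))]


def effect_magnitude(d: float) -> str:
    """Qualitative label for a Cohen's d effect size."""
    return _LABELS[int(np.searchsorted([0.2, 0.5, 0.8], abs(d), side="right"))]


_effect_magnitude = effect_magnitude


@dataclass
class NormalityFlag:
    variable: str
    p: float | None
    degenerate: bool
    flagged: bool  # p < alpha: normality assumption questionable


def screen_normality(values: pd.DataFrame, alpha: float = 0.05) -> list[NormalityFlag]:
    """Shapiro-Wilk screen per variable (column); never auto-deletes.

    Constant columns are degenerate (the test is undefined) and flagged;
    exclusion of outlying athletes is an explicit configuration action.
    """
    out = []
    for name, col in values.items():
        x = np.asarray(col, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 3:
            raise ValueError(f"normality screen needs n >= 3, got {x.size} for {name!r}")
        if np.ptp(x) == 0:
            out.append(NormalityFlag(str(name), None, True, True))
            continue
        p = float(sps.shapiro(x).pvalue)
        out.append(NormalityFlag(str(name), p, False, p < alpha))
    return out


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    magnitude: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "r": self.r, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "n": self.n, "magnitude": self.magnitude,
            "degenerate": self.degenerate,
        }


def pearson_with_ci(x, y, ci: float = 0.95) -> CorrelationResult:
    """Pearson r with a Fisher-z confidence interval and magnitude label."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, x.size, "trivial", True)
    res = sps.pearsonr(x, y)
    lo, hi = res.confidence_interval(confidence_level=ci)
    r = float(res.statistic)
    return CorrelationResult(r, float(lo), float(hi), float(res.pvalue), x.size,
                             correlation_magnitude(r))


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS fit with intercept; returns (coef, R^2, coef_p_values)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-perfect fits trip condition warnings
        fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return fit.params[1:], float(fit.rsquared), fit.pvalues[1:]


@dataclass
class StepwiseResult:
    """Forward-selection (with backward check) regression summary."""

    response: str
    entered: list[str]  # predictors in final entry order
    std_beta: dict[str, float]
    p_values: dict[str, float]
    r2_change: dict[str, float]
    model_r2: float
    adj_r2: float
    f_stat: float
    p_model: float
    df: tuple[int, int]
    n: int
    warnings: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.entered  # "no clear model prediction"

    def to_dict(self) -> dict:
        return {
            "response": self.response, "entered": list(self.entered),
            "std_beta": dict(self.std_beta), "p_values": dict(self.p_values),
            "r2_change": dict(self.r2_change), "model_r2": self.model_r2,
            "adj_r2": self.adj_r2, "f_stat": self.f_stat, "p_model": self.p_model,
            "df": list(self.df), "n": self.n, "warnings": list(self.warnings),
        }


def stepwise_regression(
    y,
    candidates: pd.DataFrame,
    enter_p: float = 0.05,
    remove_p: float = 0.10,
    response: str = "y",
) -> StepwiseResult:
    """Stepwise multiple regression with standardized coefficients.

    Forward selection: at each step the candidate with the smallest
    partial p-value enters if p <= enter_p; after each entry any
    in-model predictor with p > remove_p leaves.  Betas come from the
    final model refitted on z-scored variables, so with one predictor
    the beta equals Pearson's r.  If nothing passes the entry criterion
    the result is an empty model ("no clear prediction").
    """
    y = np.asarray(y, dtype=float)
    names = list(candidates.columns)
    X = candidates.to_numpy(dtype=float)
    n = y.size
    if n <= len(names) + 2:
        warnings.warn("sample size too small for stepwise selection", stacklevel=2)
    usable = [j for j, name in enumerate(names) if np.ptp(X[:, j]) > 0]
    if np.ptp(y) == 0:
        usable = []

    selected: list[int] = []
    changed = True
    while changed:
        changed = False
        remaining = [j for j in usable if j not in selected]
        best_j, best_p = None, np.inf
        for j in remaining:
            _, _, pv = _ols(y, X[:, selected + [j]])
            if np.isfinite(pv[-1]) and pv[-1] < best_p:
                best_j, best_p = j, float(pv[-1])
        if best_j is not None and best_p <= enter_p:
            selected.append(best_j)
            changed = True
        if selected:
            _, _, pv = _ols(y, X[:, selected])
            worst = int(np.argmax(pv))
            if pv[worst] > remove_p:
                selected.pop(worst)
                changed = True

    entered = [names[j] for j in selected]
    if not selected:
        return StepwiseResult(response, [], {}, {}, {}, 0.0, 0.0, np.nan, np.nan,
                              (0, n - 1), n)
    # sequential R^2 decomposition in final entry order
    r2_change, prev = {}, 0.0
    for k in range(1, len(selected) + 1):
        _, r2_k, _ = _ols(y, X[:, selected[:k]])
        r2_change[names[selected[k - 1]]] = r2_k - prev
        prev = r2_k
    Xs = X[:, selected]
    coef_p = _ols(y, Xs)[2]
    zy = (y - y.mean()) / y.std(ddof=1)
    zX = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0, ddof=1)
    beta, model_r2, _ = _ols(zy, zX)
    k = len(selected)
    dof = (k, n - k - 1)
    if model_r2 < 1.0 and dof[1] > 0:
        f_stat = (model_r2 / k) / ((1.0 - model_r2) / dof[1])
        p_model = float(sps.f.sf(f_stat, *dof))
    else:
        f_stat, p_model = np.inf, 0.0
    adj_r2 = 1.0 - (1.0 - model_r2) * (n - 1) / dof[1] if dof[1] > 0 else np.nan
    warns = [] if n > len(names) + 2 else ["small sample: selection unstable"]
    return StepwiseResult(
        response=response,
        entered=entered,
        std_beta={nm: float(b) for nm, b in zip(entered, beta)},
        p_values={nm: float(p) for nm, p in zip(entered, coef_p)},
        r2_change={nm: float(v) for nm, v in r2_change.items()},
        model_r2=float(model_r2),
        adj_r2=float(adj_r2),
        f_stat=float(f_stat),
        p_model=p_model,
        df=dof,
        n=n,
        warnings=warns,
    )


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with Holm-corrected post-hocs."""

    f_stat: float
    p: float
    df: tuple[float, float]
    eps_gg: float  # Greenhouse-Geisser epsilon (reported, uncorrected F primary)
    pairwise: pd.DataFrame  # pair, mean_diff, d_pooled, d_diff, p_raw, p_holm, magnitude

    def to_dict(self) -> dict:
        return {
            "F": self.f_stat, "p": self.p, "df": list(self.df), "eps_gg": self.eps_gg,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def rm_anova_holm(matrix: pd.DataFrame) -> AnovaResult:
    """Section contrast for one variable: rows athletes, columns conditions.

    Cohen's d per pair uses the pooled SD of the two conditions
    (d_pooled, primary) with the difference-SD variant (d_diff)
    alongside.  Degenerate (zero-variance) data yield F = 0.
    """
    if matrix.isna().any().any():
        raise ValueError("repeated-measures design must be complete")
    data = matrix.to_numpy(dtype=float)
    n, k = data.shape
    grand = data.mean()
    col_means = data.mean(axis=0)
    row_means = data.mean(axis=1)
    ss_treat = n * ((col_means - grand) ** 2).sum()
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid**2).sum()
    df_t, df_e = float(k - 1), float((n - 1) * (k - 1))
    if ss_err <= 1e-300:  # degenerate design pingouin cannot fit
        f_stat, p = (0.0, 1.0) if ss_treat <= 1e-300 else (np.inf, 0.0)
        eps = 1.0
    else:
        import pingouin as pg

        long = matrix.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="y"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.rm_anova(data=long, dv="y", within="condition",
                              subject="subject", correction=True, detailed=False)
        row = aov.iloc[0]
        f_stat, p = float(row["F"]), float(row["p_unc"])
        df_t, df_e = float(row["ddof1"]), float(row["ddof2"])
        eps = float(row["eps"]) if "eps" in aov.columns and np.isfinite(row.get("eps", np.nan)) else 1.0

    rows = []
    pairs = list(itertools.combinations(range(k), 2))
    raw_ps = []
    for i, j in pairs:
        a, b = data[:, i], data[:, j]
        diff = a - b
        sd_pool = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        sd_diff = diff.std(ddof=1)
        d_pool = diff.mean() / sd_pool if sd_pool > 0 else 0.0
        d_diff = diff.mean() / sd_diff if sd_diff > 0 else 0.0
        if sd_diff > 0:
            p_raw = float(sps.ttest_rel(a, b).pvalue)
        else:
            p_raw = 1.0
        raw_ps.append(p_raw)
        rows.append({
            "pair": f"{matrix.columns[i]} vs {matrix.columns[j]}",
            "mean_diff": float(diff.mean()),
            "d_pooled": float(d_pool),
            "d_diff": float(d_diff),
            "p_raw": p_raw,
        })
    holm = multipletests(raw_ps, method="holm")[1] if raw_ps else []
    for row, ph in zip(rows, holm):
        row["p_holm"] = float(ph)
        row["magnitude"] = _effect_magnitude(row["d_pooled"])
    return AnovaResult(float(f_stat), float(p), (df_t, df_e), eps, pd.DataFrame(rows))


#: Variables compared between sections (Table-1 style screen).
SECTION_VARIABLES = [
    "t_turn", "v_in", "de_mech_per_vin", "length", "d_alt",
    "f_tot", "f_out", "f_ins", "f_diff", "f_max", "f_maxout", "f_maxins",
    "f_r", "rf",
]

DATASETS = ("course",) + SECTIONS


def cohort_table(summaries: list[RunSummary], exclude: tuple[int, ...] = ()) -> pd.DataFrame:
    """Athlete-by-variable table: T plus metric_dataset columns."""
    rows = []
    for i, s in enumerate(summaries):
        if i in exclude:
            continue
        row = {"athlete": i, "T": s.course_time}
        for metric in SECTION_VARIABLES:
            row[f"{metric}_course"] = s.value(metric, "course")
            for sec in SECTIONS:
                row[f"{metric}_{sec}"] = s.value(metric, sec)
        rows.append(row)
    return pd.DataFrame(rows).set_index("athlete")


@dataclass
class SteppedModelReport:
    """Levels 1-4 fitted on the course and the three sections."""

    level1: dict[str, StepwiseResult]
    level2: dict[str, dict[str, CorrelationResult]]
    level3: dict[str, StepwiseResult]
    level4: dict[str, StepwiseResult]
    section_anova: dict[str, AnovaResult]
    normality: list[NormalityFlag]
    n_athletes: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_athletes": self.n_athletes,
            "warnings": list(self.warnings),
            "normality": [vars(f) for f in self.normality],
            "level1": {d: r.to_dict() for d, r in self.level1.items()},
            "level2": {
                d: {k: c.to_dict() for k, c in cs.items()} for d, cs in self.level2.items()
            },
            "level3": {d: r.to_dict() for d, r in self.level3.items()},
            "level4": {d: r.to_dict() for d, r in self.level4.items()},
            "section_anova": {v: a.to_dict() for v, a in self.section_anova.items()},
        }


def run_stepped_model(
    summaries: list[RunSummary],
    config: StatsConfig | None = None,
) -> SteppedModelReport:
    """Execute the full stepped analysis on a cohort of run summaries."""
    config = config or StatsConfig()
    table = cohort_table(summaries, config.exclude_athletes)
    n = len(table)
    warns = []
    if n < 10:
        warns.append(f"cohort of {n} athletes; models are underpowered (>= 10 recommended)")

    normality = screen_normality(table[["T"] + [f"{m}_course" for m in SECTION_VARIABLES]],
                                 config.alpha)

    level1, level2, level3, level4 = {}, {}, {}, {}
    for d in DATASETS:
        kw = dict(enter_p=config.enter_p, remove_p=config.remove_p)
        level1[d] = stepwise_regression(
            table["T"],
            table[[f"de_mech_per_vin_{d}", f"length_{d}"]].rename(
                columns={f"de_mech_per_vin_{d}": "de_mech_per_vin", f"length_{d}": "L"}
            ),
            response="T", **kw,
        )
        def _corr(x, y):
            try:
                return pearson_with_ci(x, y)
            except ValueError:
                return CorrelationResult(np.nan, np.nan, np.nan, np.nan, n, "trivial", True)

        level2[d] = {
            "T": _corr(table[f"f_r_{d}"], table["T"]),
            "de_mech_per_vin": _corr(table[f"f_r_{d}"], table[f"de_mech_per_vin_{d}"]),
        }
        level3[d] = stepwise_regression(
            table[f"f_r_{d}"],
            table[[f"f_tot_{d}", f"rf_{d}"]].rename(
                columns={f"f_tot_{d}": "F_tot", f"rf_{d}": "RF"}
            ),
            response="F_r", **kw,
        )
        level4[d] = stepwise_regression(
            table[f"f_tot_{d}"],
            table[[f"f_out_{d}", f"f_diff_{d}"]].rename(
                columns={f"f_out_{d}": "F_out", f"f_diff_{d}": "F_diff"}
            ),
            response="F_tot", **kw,
        )
        if any(c.degenerate for c in level2[d].values()):
            warns.append(f"level 2 correlations degenerate in dataset {d!r} (no variance)")

    anova = {
        v: rm_anova_holm(
            table[[f"{v}_{s}" for s in SECTIONS]].rename(
                columns={f"{v}_{s}": s for s in SECTIONS}
            )
        )
        for v in SECTION_VARIABLES
    }
    for r in list(level1.values()) + list(level3.values()) + list(level4.values()):
        r.warnings.extend(w for w in warns if "underpowered" in w)
    return SteppedModelReport(level1, level2, level3, level4, anova, normality, n, warns)
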