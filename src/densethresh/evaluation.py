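"""Cohort-level analyses: threshold sweep, model schemes, interactions.

Ties the pieces together: for a matched cohort carrying percent-density
measures, fit one-predictor conditional-logit models across a threshold
grid (AIC curve, matched concordance), compare the five standard modelling
schemes built from the un-thresholded volumetric measure and the best
thresholded volumetric/areal measures, test whether the areal association
differs between screen-detected and interval cancers, and run the
varying-threshold sensitivity analysis in which each woman's threshold is
a linear function of her characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import concordance as mc_mod
from .density_maps import DensityMap, ThresholdGrid
from .matched_logit import (
    AnalysisDataset,
    ClogitFit,
    SeparationError,
    fit_clogit,
    fit_interaction,
)
from .synthetic_cohort import measure_column

__all__ = [
    "SweepResult",
    "SchemeComparison",
    "VaryingThresholdModel",
    "dataset_from_cohort",
    "threshold_sweep_analysis",
    "compare_model_schemes",
    "screen_interval_analysis",
    "varying_threshold_analysis",
    "correlation_matrix",
    "plot_aic_curve",
]

SCHEME_PREDICTORS = {
    "M1": lambda tv, ta: [measure_column("vpd", 0)],
    "M2": lambda tv, ta: [measure_column("vpd", tv)],
    "M3": lambda tv, ta: [measure_column("apd", ta)],
    "M4": lambda tv, ta: [measure_column("vpd", 0), measure_column("vpd", tv)],
    "M5": lambda tv, ta: [measure_column("vpd", 0), measure_column("apd", ta)],
}


@dataclass
class SweepResult:
    """AIC/mC per (measure kind, threshold) with the best row flagged."""

    rows: pd.DataFrame  # columns: kind, threshold, aic, mc, n_sets, converged
    best_kind: str
    best_threshold: float

    @property
    def best_aic(self) -> float:
        sel = (self.rows["kind"] == self.best_kind) & (
            self.rows["threshold"] == self.best_threshold
        )
        return float(self.rows.loc[sel, "aic"].iloc[0])


@dataclass
class SchemeComparison:
    schemes: dict  # name -> dict of results
    t_v: float
    t_a: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in self.schemes.items():
            rows.append(
                {
                    "scheme": name,
                    "predictors": "+".join(res["predictors"]),
                    "aic": res["aic"],
                    "delta_aic_vs_M1": res["delta_aic_vs_M1"],
                    "mc": res["mc"],
                    "mc_ci_low": res["mc_ci"][0],
                    "mc_ci_high": res["mc_ci"][1],
                    "chisq": res["chisq"],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class VaryingThresholdModel:
    """Per-woman threshold t_i = clip(γ₀ + Σ γ_j z_j, 0, 25) mm."""

    gamma: np.ndarray  # (intercept, age, BMI, thickness, breast volume)
    covariate_names: tuple
    aic: float
    fixed_best_threshold: float
    fixed_best_aic: float
    measure_kind: str


def dataset_from_cohort(
    cohort: pd.DataFrame, columns: Sequence[str]
) -> AnalysisDataset:
    """AnalysisDataset view of a matched cohort's measure columns."""
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing measure columns {missing}")
    return AnalysisDataset(
        x=cohort[list(columns)].to_numpy(dtype=float),
        set_id=cohort["set_id"].to_numpy(),
        is_case=cohort["case"].to_numpy(dtype=bool),
        columns=tuple(columns),
    )


def _fit_one(cohort: pd.DataFrame, col: str):
    ds = dataset_from_cohort(cohort, [col])
    fit = fit_clogit(ds)
    lp = fit.linear_predictor(ds.x)
    mc = mc_mod.matched_concordance(ds.set_id, ds.is_case, lp)
    return ds, fit, mc


def threshold_sweep_analysis(
    cohort: pd.DataFrame,
    grid: ThresholdGrid | None = None,
    measure_kinds: Sequence[str] = ("vpd", "apd"),
) -> SweepResult:
    """One-predictor conditional-logit fit per (kind, threshold).

    The best row is the converged fit with minimum AIC; ties break toward
    the smaller threshold, then toward ``vpd`` before ``apd``.
    Non-converged (or degenerate, e.g. constant-measure) fits are kept in
    the table flagged ``converged=False`` and excluded from "best".
    """
    grid = grid or ThresholdGrid()
    rows = []
    for kind in measure_kinds:
        for t in grid:
            col = measure_column(kind, t)
            try:
                ds, fit, mc = _fit_one(cohort, col)
                rows.append(
                    {
                        "kind": kind,
                        "threshold": float(t),
                        "aic": fit.aic,
                        "mc": mc.mc,
                        "n_sets": fit.n_sets,
                        "converged": fit.converged,
                    }
                )
            except (SeparationError, np.linalg.LinAlgError):
                rows.append(
                    {
                        "kind": kind,
                        "threshold": float(t),
                        "aic": np.nan,
                        "mc": np.nan,
                        "n_sets": cohort["set_id"].nunique(),
                        "converged": False,
                    }
                )
    frame = pd.DataFrame(rows)
    ok = frame[frame["converged"] & frame["aic"].notna()]
    if ok.empty:
        raise RuntimeError("no threshold model converged; cannot pick a best row")
    kind_rank = ok["kind"].map({"vpd": 0, "apd": 1})
    order = np.lexsort((kind_rank, ok["threshold"], ok["aic"]))
    best = ok.iloc[order[0]]
    return SweepResult(
        rows=frame, best_kind=str(best["kind"]), best_threshold=float(best["threshold"])
    )


def compare_model_schemes(
    cohort: pd.DataFrame,
    t_v: float = 5,
    t_a: float = 6,
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> SchemeComparison:
    """Fit the five standard schemes and collect comparison statistics.

    M1: VPD0 — the un-thresholded volumetric measure (baseline);
    M2: VPD at ``t_v``; M3: APD at ``t_a``; M4: VPD0 + VPD(t_v);
    M5: VPD0 + APD(t_a).  Reports standardized ORs with 95% CIs, AIC and
    ΔAIC vs M1, matched concordance with a set-bootstrap percentile CI,
    and the model chi-square 2(ℓ̂ − ℓ₀).
    """
    results = {}
    aic_m1 = None
    for name in ("M1", "M2", "M3", "M4", "M5"):
        preds = SCHEME_PREDICTORS[name](t_v, t_a)
        try:
            ds = dataset_from_cohort(cohort, preds)
            fit = fit_clogit(ds)
        except Exception as exc:
            raise RuntimeError(f"scheme {name} ({'+'.join(preds)}) failed: {exc}") from exc
        lp = fit.linear_predictor(ds.x)
        mc = mc_mod.matched_concordance(ds.set_id, ds.is_case, lp)
        ci = mc_mod.bootstrap_mc_ci(ds.set_id, ds.is_case, lp, B=bootstrap_B, seed=seed)
        results[name] = {
            "predictors": preds,
            "fit": fit,
            "standardized_or": fit.standardized_or(),
            "aic": fit.aic,
            "chisq": fit.chisq,
            "mc": mc.mc,
            "mc_ci": ci,
            "linear_predictor": lp,
        }
        if name == "M1":
            aic_m1 = fit.aic
    for res in results.values():
        res["delta_aic_vs_M1"] = res["aic"] - aic_m1
    return SchemeComparison(schemes=results, t_v=t_v, t_a=t_a)


def screen_interval_analysis(cohort_study2: pd.DataFrame, t_a: float = 6) -> dict:
    """Does the areal-density association differ by mode of detection?

    Fits APD(t_a) with an APD×interval interaction on a study-2-style
    cohort (each set's mode is its case's), reporting per-mode standardized
    odds ratios and the likelihood-ratio p-value for the interaction.
    """
    col = measure_column("apd", t_a)
    ds = dataset_from_cohort(cohort_study2, [col])
    # per-set mode, broadcast from the case to the whole set
    case_mode = (
        cohort_study2[cohort_study2["case"]]
        .set_index("set_id")["cancer_mode"]
        .to_dict()
    )
    modes = cohort_study2["set_id"].map(case_mode)
    if (modes == "interval").sum() == 0:
        raise ValueError("cohort contains no interval-cancer sets")
    if (modes == "screen").sum() == 0:
        raise ValueError("cohort contains no screen-detected sets")
    # align with the dataset's internal stable sort by set_id
    order = np.argsort(cohort_study2["set_id"].to_numpy(), kind="stable")
    indicator = (modes.to_numpy() == "interval").astype(float)[order]
    res = fit_interaction(ds, col, indicator)
    res["per_mode_or"] = {
        "screen": res["per_group_or"]["group0"],
        "interval": res["per_group_or"]["group1"],
    }
    return res


_AGE_MID = {"<50": 47.0, "50-54": 52.0, "55-59": 57.0, "60-64": 62.0,
            "65-69": 67.0, "70+": 72.0}
_BMI_MID = {"<25": 22.5, "25-29": 27.0, ">=30": 33.0}

DEFAULT_GAMMA_GRIDS = (
    tuple(np.arange(0.0, 13.0, 2.0)),  # intercept, mm
    (-3.0, -1.5, 0.0, 1.5, 3.0),  # age (per SD)
    (-3.0, -1.5, 0.0, 1.5, 3.0),  # BMI (per SD)
    (-3.0, -1.5, 0.0, 1.5, 3.0),  # thickness (per SD)
    (-3.0, -1.5, 0.0, 1.5, 3.0),  # breast volume (per SD)
)


def varying_threshold_analysis(
    cohort: pd.DataFrame,
    maps: Mapping[str, DensityMap],
    measure_kind: str = "apd",
    gamma_grids: Sequence[Sequence[float]] = DEFAULT_GAMMA_GRIDS,
    fixed_grid: ThresholdGrid | None = None,
    max_sweeps: int = 5,
) -> VaryingThresholdModel:
    """Sensitivity analysis: per-woman thresholds from a linear model.

    Each woman's threshold is ``clip(γ₀ + γ₁·age + γ₂·BMI + γ₃·thickness +
    γ₄·breast volume, 0, 25)`` with covariates standardized (age and BMI
    from band midpoints, thickness and volume from her map).  The γ vector
    is found by coordinate descent over the supplied grids, minimizing the
    one-predictor conditional-logit AIC; the measure is re-evaluated from
    each woman's map at her own threshold.  Deterministic; no claim of
    global optimality.  Also reports the best *fixed* threshold for
    comparison.
    """
    from .density_maps import breast_volume as _bvol

    missing = [s for s in cohort["subject_id"] if s not in maps]
    if missing:
        raise ValueError(f"missing density maps for subjects {missing[:3]}...")
    cohort = cohort.reset_index(drop=True)
    n = len(cohort)
    # per-subject sorted heights and suffix sums for O(log n) measures at any t
    sorted_h, suffix_sum, n_mask, thick = [], [], [], []
    for sid in cohort["subject_id"]:
        d = maps[sid]
        h = np.sort(d.heights[d.breast_mask])
        sorted_h.append(h)
        suffix_sum.append(np.r_[np.cumsum(h[::-1])[::-1], 0.0])
        n_mask.append(h.size)
        thick.append(d.breast_thickness)
    n_mask = np.asarray(n_mask, dtype=float)
    thick = np.asarray(thick, dtype=float)

    def measures_at(ts: np.ndarray) -> np.ndarray:
        out = np.empty(n)
        for i in range(n):
            j = np.searchsorted(sorted_h[i], ts[i], side="right")
            if measure_kind == "apd":
                out[i] = 100.0 * (n_mask[i] - j) / n_mask[i]
            else:
                out[i] = 100.0 * suffix_sum[i][j] / (thick[i] * n_mask[i])
        return out

    age = cohort["age_band"].map(_AGE_MID).to_numpy(dtype=float)
    bmi = cohort["bmi_band"].map(_BMI_MID).to_numpy(dtype=float)
    vol = np.array([_bvol(maps[s]) for s in cohort["subject_id"]])
    z = np.column_stack([age, bmi, thick, vol])
    sd = z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (z - z.mean(axis=0)) / sd

    set_id = cohort["set_id"].to_numpy()
    is_case = cohort["case"].to_numpy(dtype=bool)

    def aic_for(gamma: np.ndarray) -> float:
        ts = np.clip(gamma[0] + z @ gamma[1:], 0.0, 25.0)
        x = measures_at(ts)
        if x.std() == 0:
            return np.inf
        try:
            fit = fit_clogit(
                AnalysisDataset(x=x[:, None], set_id=set_id, is_case=is_case,
                                columns=("measure",))
            )
        except (SeparationError, np.linalg.LinAlgError):
            return np.inf
        return fit.aic if fit.converged else np.inf

    # fixed-threshold reference sweep
    fixed_grid = fixed_grid or ThresholdGrid()
    fixed_aics = [aic_for(np.array([t, 0, 0, 0, 0], dtype=float))
                  for t in fixed_grid]
    i_best = int(np.argmin(fixed_aics))
    fixed_best_t, fixed_best_aic = list(fixed_grid)[i_best], fixed_aics[i_best]

    gamma = np.array([g[len(g) // 2] if 0.0 not in g else 0.0
                      for g in gamma_grids], dtype=float)
    gamma[0] = min(gamma_grids[0], key=lambda v: abs(v - fixed_best_t))
    best_aic = aic_for(gamma)
    for _ in range(max_sweeps):
        changed = False
        for j, gridj in enumerate(gamma_grids):
            for v in gridj:
                if v == gamma[j]:
                    continue
                cand = gamma.copy()
                cand[j] = v
                a = aic_for(cand)
                if a < best_aic - 1e-12:
                    gamma, best_aic, changed = cand, a, True
        if not changed:
            break
    return VaryingThresholdModel(
        gamma=gamma,
        covariate_names=("intercept", "age", "bmi", "thickness", "breast_volume"),
        aic=best_aic,
        fixed_best_threshold=float(fixed_best_t),
        fixed_best_aic=float(fixed_best_aic),
        measure_kind=measure_kind,
    )


def correlation_matrix(
    measures: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Spearman rank correlation (average ranks for ties) per column pair."""
    if len(measures) < 3:
        raise ValueError("Spearman correlation needs at least 3 subjects")
    rows = []
    for a, b in pairs:
        xa = measures[a].to_numpy(dtype=float)
        xb = measures[b].to_numpy(dtype=float)
        if np.all(xa == xa[0]) or np.all(xb == xb[0]):
            rho, note = np.nan, "undefined: constant vector"
        else:
            rho = float(spearmanr(xa, xb).statistic)
            note = ""
        rows.append({"a": a, "b": b, "spearman_rho": rho, "note": note})
    return pd.DataFrame(rows)


def plot_aic_curve(sweep: SweepResult, path: str) -> None:
    """AIC versus threshold, one curve per measure kind."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for kind, sub in sweep.rows.groupby("kind"):
        ax.plot(sub["threshold"], sub["aic"], marker="o", ms=3, label=kind.upper())
    ax.set_xlabel("threshold (mm)")
    ax.set_ylabel("AIC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
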