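"""Synthetic density maps and 3:1 matched case-control cohorts.

Real screening mammograms and their height maps are not redistributable, so
this module emulates them at the level the downstream analysis sees:

* :func:`simulate_density_map` draws a craniocaudal-view-like half-ellipse
  breast mask and fills it with a spatially correlated log-normal
  dense-tissue-height field (a shifted log-normal, so genuinely
  zero-height fatty pixels exist);
* :func:`simulate_measures` draws the same per-subject height model but as
  a modest number of independent height samples per subject — the
  "effective pixels" of a correlated map — and computes percent-density
  measures directly, which is orders of magnitude faster when maps
  themselves are not needed;
* :func:`simulate_subjects` attaches demographic covariates drawn from
  configurable category frequencies (defaults follow the control arms of
  the two screening case-control studies the package models);
* :func:`build_matched_sets` groups subjects into strata on the four
  matching variables (age band, BMI band, HRT use, menopausal status),
  forms disjoint sets of one-plus-m members, and labels one member of each
  set as the case with within-set softmax probability
  ``exp(β·x_i)/Σ_j exp(β·x_j)`` on the standardized designated predictor —
  exactly the conditional-logistic generative model, so conditional
  logistic regression on the output is correctly specified by
  construction.

Every stochastic operation takes an explicit seed; a master seed can be
fanned out with :func:`spawn_seeds`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .density_maps import DensityMap, ThresholdGrid

__all__ = [
    "MapSimParams",
    "CovariateFrequencies",
    "RiskParams",
    "MatchedSet",
    "SubjectRecord",
    "simulate_density_map",
    "simulate_measures",
    "simulate_subjects",
    "build_matched_sets",
    "write_cohort",
    "read_cohort",
    "spawn_seeds",
    "measure_column",
    "MATCHING_VARIABLES",
]

MATCHING_VARIABLES = ("age_band", "bmi_band", "hrt", "menopause")

AGE_BANDS = ("<50", "50-54", "55-59", "60-64", "65-69", "70+")
BMI_BANDS = ("<25", "25-29", ">=30")
HRT_LEVELS = ("Unknown", "Never", "Previous", "Current")
MENOPAUSE_LEVELS = ("Unknown", "Pre", "Peri", "Post")
ETHNICITY_LEVELS = ("Other/unknown", "White")
PARITY_LEVELS = ("Unknown", "Nulliparous", "Parous")


def _props(counts):
    a = np.asarray(counts, dtype=float)
    return tuple(a / a.sum())


@dataclass(frozen=True)
class CovariateFrequencies:
    """Category frequencies for one study's subject pool.

    Defaults are the control-arm frequencies of the first nested
    case-control study (cancers found at the entry screen); use
    :meth:`study2` for the second study (cancers found subsequently).
    Each tuple must sum to 1 to within 1e-9.
    """

    age: tuple = _props((53, 242, 153, 229, 196, 74))
    bmi: tuple = _props((332, 331, 283))
    hrt: tuple = _props((14, 568, 315, 50))
    menopause: tuple = _props((31, 92, 112, 712))
    ethnicity: tuple = _props((52, 895))
    parity: tuple = _props((1, 112, 834))

    def __post_init__(self) -> None:
        for name, freqs, levels in (
            ("age", self.age, AGE_BANDS),
            ("bmi", self.bmi, BMI_BANDS),
            ("hrt", self.hrt, HRT_LEVELS),
            ("menopause", self.menopause, MENOPAUSE_LEVELS),
            ("ethnicity", self.ethnicity, ETHNICITY_LEVELS),
            ("parity", self.parity, PARITY_LEVELS),
        ):
            if len(freqs) != len(levels):
                raise ValueError(f"{name}: expected {len(levels)} frequencies")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError(f"{name} frequencies must sum to 1 (±1e-9)")

    @classmethod
    def study2(cls) -> "CovariateFrequencies":
        return cls(
            age=_props((46, 194, 164, 286, 198, 47)),
            bmi=_props((335, 341, 259)),
            hrt=_props((23, 475, 332, 105)),
            menopause=_props((32, 67, 134, 702)),
            ethnicity=_props((81, 854)),
            parity=_props((1, 91, 843)),
        )


@dataclass(frozen=True)
class MapSimParams:
    """Parameters of the synthetic height-map model.

    In-mask heights are ``clip(exp(μ_i + σ_i·G) − shift, 0, thickness)``
    where ``G`` is a unit-variance Gaussian field smoothed to the given
    correlation length and ``(μ_i, σ_i)`` vary between subjects
    (``μ_i ~ N(mu, tau_mu²)``, ``log σ_i ~ N(log sigma, tau_logsigma²)``).
    The subtraction of ``shift`` mm models purely fatty tissue as exact
    zeros.  Defaults are calibrated so that the population of un-thresholded
    volumetric percent densities matches published screening controls
    (median ≈ 4.9%, interquartile range ≈ 3.6–7.2%).
    """

    shape: tuple = (80, 60)
    pixel_area: float = 4.0  # mm² (2 mm spacing)
    breast_thickness: float = 55.0  # mm
    semi_axes: tuple = (36.0, 54.0)  # (rows, cols) of the half-ellipse, px
    correlation_length: float = 3.0  # px
    mu: float = 0.60  # location of log dense-tissue height
    sigma: float = 1.15  # within-map scale of log height
    tau_mu: float = 0.40  # between-subject SD of μ_i
    tau_logsigma: float = 0.12  # between-subject SD of log σ_i
    shift: float = 0.5  # mm subtracted before clipping at zero
    n_effective_pixels: int = 96  # independent samples for simulate_measures

    def __post_init__(self) -> None:
        if min(self.shape) < 4 or min(self.semi_axes) <= 0:
            raise ValueError("degenerate grid or mask geometry")
        for name in ("pixel_area", "breast_thickness", "correlation_length",
                     "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_mu < 0 or self.tau_logsigma < 0 or self.shift < 0:
            raise ValueError("tau_mu, tau_logsigma and shift must be >= 0")


@dataclass(frozen=True)
class RiskParams:
    """Generative risk model for case labelling.

    ``beta`` is the log odds ratio per standard deviation of the designated
    predictor.  For a study-2-style cohort, per-mode coefficients
    ``beta_screen``/``beta_interval`` (also per SD) replace ``beta`` and a
    fraction ``interval_fraction`` of sets is designated interval.
    """

    predictor: str = "apd_6"
    beta: float = float(np.log(1.34))
    beta_screen: float | None = None
    beta_interval: float | None = None
    interval_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not 0.0 <= self.interval_fraction <= 1.0:
            raise ValueError("interval_fraction must be in [0, 1]")

    @property
    def by_mode(self) -> bool:
        return self.beta_screen is not None and self.beta_interval is not None


@dataclass(frozen=True)
class MatchedSet:
    set_id: int
    case_id: str
    control_ids: tuple
    stratum: str


@dataclass(frozen=True)
class SubjectRecord:
    """Schema of one cohort row; the pipeline itself works on DataFrames."""

    subject_id: str
    study: int
    age_band: str
    bmi_band: str
    hrt: str
    menopause: str
    ethnicity: str
    parity: str
    case: bool = False
    cancer_mode: str = "none"
    set_id: int = -1


def measure_column(kind: str, t: float) -> str:
    """Column name for a precomputed measure, e.g. ``apd_6`` or ``vpd_2.5``."""
    if kind not in ("vpd", "apd"):
        raise ValueError(f"unknown measure kind {kind!r}")
    return f"{kind}_{t:g}"


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministically fan a master seed out into n stage seeds < 2³¹."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


# ---------------------------------------------------------------------------
# Density-map and measure simulation
# ---------------------------------------------------------------------------


def _half_ellipse_mask(shape, semi_axes) -> np.ndarray:
    """Half-ellipse flush against the left image edge, long axis vertical."""
    h, w = shape
    ry, rx = semi_axes
    rows, cols = np.ogrid[:h, :w]
    return ((rows - (h - 1) / 2.0) / ry) ** 2 + (cols / rx) ** 2 <= 1.0


def _smoothed_unit_field(rng, shape, corr_len) -> np.ndarray:
    g = gaussian_filter(rng.standard_normal(shape), corr_len, mode="reflect")
    sd = g.std()
    return g / sd if sd > 0 else g


def simulate_density_map(
    params: MapSimParams, seed: int, subject_id: str = "sim"
) -> DensityMap:
    """One synthetic density map; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    mask = _half_ellipse_mask(params.shape, params.semi_axes)
    mu_i = params.mu + params.tau_mu * rng.standard_normal()
    sigma_i = params.sigma * np.exp(params.tau_logsigma * rng.standard_normal())
    if params.sigma > 0:
        field = _smoothed_unit_field(rng, params.shape, params.correlation_length)
    else:
        field = np.zeros(params.shape)
    heights = np.clip(
        np.exp(mu_i + sigma_i * field) - params.shift, 0.0, params.breast_thickness
    )
    heights[~mask] = 0.0
    return DensityMap(
        heights=heights,
        breast_mask=mask,
        pixel_area=params.pixel_area,
        breast_thickness=params.breast_thickness,
        subject_id=subject_id,
    )


def simulate_measures(
    n: int,
    grid: ThresholdGrid,
    params: MapSimParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent-density measures for n subjects without materializing maps.

    Each subject's height distribution is sampled at
    ``params.n_effective_pixels`` independent points — the number of
    effectively independent patches of a correlated map of the default
    geometry — and VPD/APD are computed from those samples exactly as the
    map pipeline would.  Columns: ``vpd_<t>`` and ``apd_<t>`` per grid
    threshold, plus the latent ``mu_i``/``sigma_i`` for diagnostics.
    """
    params = params or MapSimParams()
    rng = np.random.default_rng(seed)
    mu_i = params.mu + params.tau_mu * rng.standard_normal(n)
    sigma_i = params.sigma * np.exp(params.tau_logsigma * rng.standard_normal(n))
    z = rng.standard_normal((n, params.n_effective_pixels))
    h = np.clip(
        np.exp(mu_i[:, None] + sigma_i[:, None] * z) - params.shift,
        0.0,
        params.breast_thickness,
    )
    out = {}
    for t in grid:
        above = h > t
        out[measure_column("vpd", t)] = (
            100.0 * (h * above).mean(axis=1) / params.breast_thickness
        )
        out[measure_column("apd", t)] = 100.0 * above.mean(axis=1)
    out["mu_i"] = mu_i
    out["sigma_i"] = sigma_i
    return pd.DataFrame(out)


def expected_apd(t: float, mu: float, sigma: float, shift: float = 0.5) -> float:
    """Population APD (%) of the shifted log-normal height model."""
    return float(100.0 * norm.sf((np.log(t + shift) - mu) / sigma))


# ---------------------------------------------------------------------------
# Subjects and matched sets
# ---------------------------------------------------------------------------


def simulate_subjects(
    n: int,
    study: int = 1,
    frequencies: CovariateFrequencies | None = None,
    map_params: MapSimParams | None = None,
    grid: ThresholdGrid | None = None,
    seed: int = 0,
    with_measures: bool = True,
) -> pd.DataFrame:
    """Draw n subjects: demographics plus (optionally) density measures.

    Covariate categories are independent multinomials with the configured
    frequencies; measures come from :func:`simulate_measures` on the same
    map model.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if study not in (1, 2):
        raise ValueError("study must be 1 or 2")
    if frequencies is None:
        frequencies = (
            CovariateFrequencies() if study == 1 else CovariateFrequencies.study2()
        )
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{study}-{i:06d}" for i in range(n)],
            "study": study,
            "age_band": rng.choice(AGE_BANDS, size=n, p=frequencies.age),
            "bmi_band": rng.choice(BMI_BANDS, size=n, p=frequencies.bmi),
            "hrt": rng.choice(HRT_LEVELS, size=n, p=frequencies.hrt),
            "menopause": rng.choice(MENOPAUSE_LEVELS, size=n, p=frequencies.menopause),
            "ethnicity": rng.choice(ETHNICITY_LEVELS, size=n, p=frequencies.ethnicity),
            "parity": rng.choice(PARITY_LEVELS, size=n, p=frequencies.parity),
        }
    )
    if with_measures:
        grid = grid or ThresholdGrid()
        meas = simulate_measures(
            n, grid, map_params, seed=int(rng.integers(0, 2**31))
        )
        df = pd.concat([df, meas], axis=1)
    return df


def build_matched_sets(
    subjects: pd.DataFrame,
    risk: RiskParams,
    m: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[MatchedSet]]:
    """Form 1:m matched sets and label cases by the within-set softmax.

    Subjects are grouped into strata on the four matching variables;
    within each stratum, disjoint groups of ``m+1`` are formed (leftovers
    unused; strata smaller than ``m+1`` are skipped).  In each group one
    member becomes the case with probability
    ``exp(β·x_i) / Σ_j exp(β·x_j)`` where ``x`` is the designated
    predictor standardized over the full input sample.  With per-mode risk
    parameters, each set is first designated screen or interval and the
    mode's β is used.

    Returns the cohort (only subjects placed in sets, with ``set_id``,
    ``case`` and ``cancer_mode`` columns) and the set records.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if risk.predictor not in subjects.columns:
        raise ValueError(f"predictor column {risk.predictor!r} not in subjects")
    rng = np.random.default_rng(seed)
    x_all = subjects[risk.predictor].to_numpy(dtype=float)
    x_std = (x_all - x_all.mean()) / x_all.std(ddof=1)

    strata = subjects.groupby(list(MATCHING_VARIABLES), observed=True, sort=True)
    group_members: list[np.ndarray] = []
    group_strata: list[str] = []
    n_skipped = 0
    for key, idx in sorted(strata.indices.items()):
        idx = np.asarray(idx)
        if idx.size < m + 1:
            n_skipped += 1
            continue
        perm = rng.permutation(idx)
        n_groups = idx.size // (m + 1)
        label = "|".join(map(str, key))
        for gi in range(n_groups):
            group_members.append(perm[gi * (m + 1): (gi + 1) * (m + 1)])
            group_strata.append(label)
    if not group_members:
        raise ValueError(
            f"no matched sets could be formed ({n_skipped} strata too small "
            f"for 1:{m} matching)"
        )

    n_sets = len(group_members)
    members = np.stack(group_members)  # (n_sets, m+1) row indices
    if risk.by_mode:
        is_interval = rng.random(n_sets) < risk.interval_fraction
        betas = np.where(is_interval, risk.beta_interval, risk.beta_screen)
    else:
        is_interval = np.zeros(n_sets, dtype=bool)
        betas = np.full(n_sets, risk.beta)
    eta = betas[:, None] * x_std[members]
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n_sets)
    case_pos = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)

    cohort = subjects.iloc[members.ravel()].copy().reset_index(drop=True)
    cohort["set_id"] = np.repeat(np.arange(n_sets), m + 1)
    case_flags = np.zeros(n_sets * (m + 1), dtype=bool)
    case_flags[np.arange(n_sets) * (m + 1) + case_pos] = True
    cohort["case"] = case_flags
    modes = np.where(is_interval, "interval", "screen")
    cohort["cancer_mode"] = np.where(
        case_flags, np.repeat(modes, m + 1), "none"
    )

    ids = subjects["subject_id"].to_numpy()
    sets = []
    for s in range(n_sets):
        row_ids = ids[members[s]]
        sets.append(
            MatchedSet(
                set_id=s,
                case_id=str(row_ids[case_pos[s]]),
                control_ids=tuple(
                    str(r) for i, r in enumerate(row_ids) if i != case_pos[s]
                ),
                stratum=group_strata[s],
            )
        )
    return cohort, sets


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLS = [
    "subject_id", "study", "set_id", "case", "cancer_mode",
    "age_band", "bmi_band", "hrt", "menopause", "ethnicity", "parity",
]


class CohortFormatError(ValueError):
    """Raised when a cohort file violates the schema."""


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort to CSV (schema-validated, lossless round trip)."""
    _validate_cohort(cohort)
    cols = _REQUIRED_COLS + [c for c in cohort.columns if c not in _REQUIRED_COLS]
    cohort[cols].to_csv(path, index=False)


def read_cohort(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"cohort file {path} is empty") from exc
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"cohort file {path} missing columns {missing}")
    df["case"] = df["case"].astype(bool)
    _validate_cohort(df)
    return df


def _validate_cohort(df: pd.DataFrame) -> None:
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise CohortFormatError(f"duplicate subject_id {dup!r}")
    cases_per_set = df.groupby("set_id")["case"].sum()
    bad = cases_per_set[cases_per_set != 1]
    if len(bad):
        raise CohortFormatError(
            f"set {bad.index[0]!r} has {int(bad.iloc[0])} cases (expected 1)"
        )
    mode_vs_case = (df["cancer_mode"] != "none") != df["case"]
    if mode_vs_case.any():
        sid = df.loc[mode_vs_case, "subject_id"].iloc[0]
        raise CohortFormatError(
            f"subject {sid!r}: cancer_mode must be 'none' exactly for controls"
        )
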