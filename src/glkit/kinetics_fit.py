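"""Fitting mechanism models to initial-velocity data.

Implements the classical two-route analysis of bisubstrate steady-state
kinetics: direct weighted nonlinear least squares against a mechanism's rate
law (Levenberg–Marquardt via lmfit), and the reciprocal-space route —
double-reciprocal line families, their intersection diagnostics, and the
secondary (slope / intercept vs inhibitor) replots that yield Kis and Kii.
Both routes should agree on clean data; the package tests assert it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from . import kinetics_core as kc
from .errors import (
    AnalysisError,
    ConvergenceError,
    IdentifiabilityError,
    InputError,
)

#: Coefficient-of-variation threshold on per-level reciprocal slopes below
#: which a line family is called parallel (ping-pong diagnostic).
PARALLEL_CV = 0.05

_PARAM_NAMES = {
    "ordered_bibi": ("Vmax", "Km_A", "Km_B", "Ki_A"),
    "random_bibi_rapid_eq": ("Vmax", "Km_A", "Km_B", "alpha"),
    "ping_pong": ("Vmax", "Km_A", "Km_B"),
}


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class VelocityDataset:
    """Initial-rate measurements: concentrations (µM) and velocities
    (µmol·mg⁻¹·min⁻¹), one row per assay."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.frame
        for col in ("A", "B", "v"):
            if col not in df.columns:
                raise InputError(f"velocity data must have column {col!r}")
        for col in ("P", "Q"):
            if col not in df.columns:
                df[col] = 0.0
        if (df["v"] < 0).any():
            raise InputError("velocities must be >= 0")
        if "sigma" in df.columns and (df["sigma"] <= 0).any():
            raise InputError("sigma column must be strictly positive when present")

    def __len__(self) -> int:
        return len(self.frame)

    def levels(self, species: str) -> np.ndarray:
        return np.unique(self.frame[species].to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path, **metadata) -> "VelocityDataset":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        return cls(df, metadata=dict(metadata))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# direct nonlinear fits
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    mechanism: str
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    n_obs: int
    n_params: int
    aicc: float
    converged: bool
    message: str = ""

    def as_mechanism_params(self) -> kc.MechanismParams:
        p = self.params
        return kc.MechanismParams(
            Vmax=p["Vmax"], Km_A=p["Km_A"], Km_B=p["Km_B"],
            Ki_A=p.get("Ki_A", p["Km_A"]), mechanism=self.mechanism
            if self.mechanism in kc.MECHANISM_TAGS else "ordered_bibi",
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _rate_law(mechanism: str):
    if mechanism == "ordered_bibi":
        def law(a, b, p):
            return p["Vmax"] * a * b / (
                p["Ki_A"] * p["Km_B"] + p["Km_B"] * a + p["Km_A"] * b + a * b)
    elif mechanism == "random_bibi_rapid_eq":
        def law(a, b, p):
            return p["Vmax"] * a * b / (
                p["alpha"] * p["Km_A"] * p["Km_B"] + p["Km_B"] * a + p["Km_A"] * b + a * b)
    elif mechanism == "ping_pong":
        def law(a, b, p):
            return p["Vmax"] * a * b / (p["Km_B"] * a + p["Km_A"] * b + a * b)
    else:
        raise InputError(f"unknown mechanism tag {mechanism!r}")
    return law


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for Gaussian residuals."""
    if n - k - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _auto_init(data: VelocityDataset, mechanism: str) -> dict[str, float]:
    """Scale-free deterministic starting values: Vmax = 1.1·max(v), Km's at
    the median concentration of each substrate."""
    df = data.frame
    init = {
        "Vmax": 1.1 * float(df["v"].max()),
        "Km_A": float(np.median(df["A"])),
        "Km_B": float(np.median(df["B"])),
    }
    if mechanism == "ordered_bibi":
        init["Ki_A"] = init["Km_A"]
    elif mechanism == "random_bibi_rapid_eq":
        init["alpha"] = 1.0
    return init


def fit_mechanism(
    data: VelocityDataset,
    mechanism: str = "ordered_bibi",
    init: Mapping[str, float] | kc.MechanismParams | None = None,
) -> FitResult:
    """Weighted nonlinear least-squares fit of a bisubstrate rate law.

    Uniform weights by default; rows with a ``sigma`` column are weighted
    1/σ.  Deterministic: Levenberg–Marquardt from the fixed auto-init, with
    a seeded 8-point multi-start only on convergence failure.
    """
    df = data.frame
    if (df["P"] != 0).any() or (df["Q"] != 0).any():
        raise InputError("fit_mechanism expects forward initial-rate data (P = Q = 0); "
                         "use fit_linear_inhibition for product-inhibition designs")
    for sub, km in (("A", "Km_A"), ("B", "Km_B")):
        if len(data.levels(sub)) < 2:
            raise IdentifiabilityError(km, f"substrate {sub} is held at a single level; "
                                           f"{km} is not identifiable")
    law = _rate_law(mechanism)
    names = _PARAM_NAMES[mechanism]
    if isinstance(init, kc.MechanismParams):
        init = {"Vmax": init.Vmax, "Km_A": init.Km_A, "Km_B": init.Km_B, "Ki_A": init.Ki_A}
    init_values = dict(_auto_init(data, mechanism))
    if init:
        init_values.update({k: v for k, v in init.items() if k in names})

    a = df["A"].to_numpy(float)
    b = df["B"].to_numpy(float)
    v = df["v"].to_numpy(float)
    w = 1.0 / df["sigma"].to_numpy(float) if "sigma" in df.columns else np.ones_like(v)

    def residual(params):
        p = {name: params[name].value for name in names}
        return w * (law(a, b, p) - v)

    def make_params(values):
        params = lmfit.Parameters()
        for name in names:
            lo = 0.0 if name != "alpha" else 1e-3
            params.add(name, value=values[name], min=lo)
        return params

    result = lmfit.minimize(residual, make_params(init_values), method="leastsq")
    if not result.success:
        rng = np.random.default_rng(8)
        best = None
        for _ in range(8):
            jittered = {k: val * float(rng.uniform(0.2, 5.0)) for k, val in init_values.items()}
            trial = lmfit.minimize(residual, make_params(jittered), method="leastsq")
            if trial.success and (best is None or trial.chisqr < best.chisqr):
                best = trial
        if best is not None:
            result = best

    point = {name: float(result.params[name].value) for name in names}
    stderr = {name: float(result.params[name].stderr)
              if result.params[name].stderr is not None else math.nan
              for name in names}
    rss = float(np.sum(np.asarray(result.residual) ** 2))
    return FitResult(
        mechanism=mechanism,
        params=point,
        stderr=stderr,
        rss=rss,
        n_obs=len(v),
        n_params=len(names),
        aicc=aicc(rss, len(v), len(names)),
        converged=bool(result.success),
        message=str(result.message),
    )


# ---------------------------------------------------------------------------
# double-reciprocal diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ReciprocalDiagnostics:
    varied: str
    fixed: str
    lines: pd.DataFrame          # fixed level, slope, intercept, r2
    classification: str          # "intersecting" or "parallel"
    slope_cv: float
    intersections: pd.DataFrame  # pairwise (level_i, level_j, x, y)
    median_intersection_y: float

    @property
    def above_abscissa(self) -> bool:
        """True when the common intersection lies above the 1/[S] axis —
        the signature of a sequential mechanism with Kia < Ka·Kb/…"""
        return self.median_intersection_y > 0


def _per_level_lines(df: pd.DataFrame, varied: str, fixed: str) -> pd.DataFrame:
    rows = []
    for level, grp in df.groupby(fixed):
        if len(grp) < 4:
            raise InputError(f"need >=4 points of {varied} at each {fixed} level (got {len(grp)})")
        inv_s = 1.0 / grp[varied].to_numpy(float)
        with np.errstate(divide="raise"):
            inv_v = 1.0 / grp["v"].to_numpy(float)
        slope, intercept = np.polyfit(inv_s, inv_v, 1)
        pred = slope * inv_s + intercept
        ss_res = float(np.sum((inv_v - pred) ** 2))
        ss_tot = float(np.sum((inv_v - inv_v.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        rows.append({"level": float(level), "slope": float(slope),
                     "intercept": float(intercept), "r2": r2})
    lines = pd.DataFrame(rows).sort_values("level").reset_index(drop=True)
    if (lines["slope"] <= 0).any():
        raise AnalysisError("negative or zero reciprocal slope: data quality problem")
    return lines


def reciprocal_diagnostics(
    data: VelocityDataset,
    varied: str = "A",
    fixed: str = "B",
) -> ReciprocalDiagnostics:
    """Family of 1/v vs 1/[varied] lines at each fixed co-substrate level.

    A coefficient of variation of the slopes below ``PARALLEL_CV`` calls the
    family parallel (ping-pong); otherwise intersecting (sequential, ternary
    complex).  Pairwise intersection coordinates are reported so the
    "intersecting above the abscissa" observation can be checked directly.
    """
    df = data.frame
    if (df["P"] != 0).any() or (df["Q"] != 0).any():
        raise InputError("reciprocal_diagnostics expects product-free data")
    if len(data.levels(fixed)) < 3:
        raise InputError(f"need >=3 levels of the fixed substrate {fixed} "
                         f"(got {len(data.levels(fixed))}); classification refused")
    lines = _per_level_lines(df, varied, fixed)
    slopes = lines["slope"].to_numpy()
    slope_cv = float(np.std(slopes, ddof=1) / np.mean(slopes))
    classification = "parallel" if slope_cv < PARALLEL_CV else "intersecting"

    inter = []
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            m1, c1 = lines.loc[i, ["slope", "intercept"]]
            m2, c2 = lines.loc[j, ["slope", "intercept"]]
            if m1 == m2:
                continue
            x = (c2 - c1) / (m1 - m2)
            inter.append({"level_i": lines.loc[i, "level"], "level_j": lines.loc[j, "level"],
                          "x": float(x), "y": float(m1 * x + c1)})
    inter = pd.DataFrame(inter, columns=["level_i", "level_j", "x", "y"])
    median_y = float(np.median(inter["y"])) if len(inter) else math.nan
    return ReciprocalDiagnostics(varied, fixed, lines, classification,
                                 slope_cv, inter, median_y)


# ---------------------------------------------------------------------------
# linear product-inhibition analysis (secondary replots)
# ---------------------------------------------------------------------------

@dataclass
class ReplotResult:
    varied: str
    inhibitor: str
    lines: pd.DataFrame       # inhibitor level, slope, intercept, r2
    slope_replot: dict        # slope0, slope_vs_I, r2, affected
    intercept_replot: dict
    Kis: float                # µM, inf when the slope replot is flat
    Kii: float
    pattern: str
    linear: bool


def _replot(levels: np.ndarray, values: np.ndarray) -> dict:
    slope, intercept = np.polyfit(levels, values, 1)
    pred = slope * levels + intercept
    ss_res = float(np.sum((values - pred) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept), "r2": r2}


def fit_linear_inhibition(
    data: VelocityDataset,
    varied: str,
    inhibitor: str,
) -> ReplotResult:
    """Linear (Cleland) analysis of single-product inhibition.

    Fits 1/v = slope₀·(1 + [I]/Kis)·(1/[S]) + int₀·(1 + [I]/Kii) by
    per-level lines plus secondary regressions of slopes and intercepts on
    [I]; Kis and Kii follow from the replot intercept/slope ratios.
    Curvature in either replot (poor linear R² relative to a quadratic)
    marks the result non-linear — the simple single-product model without
    dead-end complexes is then not tenable.
    """
    if varied not in ("A", "B") or inhibitor not in ("P", "Q"):
        raise InputError("varied must be A or B; inhibitor must be P or Q")
    df = data.frame
    other_product = "Q" if inhibitor == "P" else "P"
    if (df[other_product] != 0).any():
        raise InputError(f"dataset also varies {other_product}; single-product design required")
    levels = data.levels(inhibitor)
    if len(levels) < 3 or 0.0 not in levels:
        raise InputError("need >=3 inhibitor levels including 0")

    rows = []
    for level, grp in df.groupby(inhibitor):
        inv_s = 1.0 / grp[varied].to_numpy(float)
        inv_v = 1.0 / grp["v"].to_numpy(float)
        if len(grp) < 3:
            raise InputError(f"need >=3 varied points per inhibitor level (got {len(grp)})")
        fit = _replot(inv_s, inv_v)
        rows.append({"level": float(level), "slope": fit["slope"],
                     "intercept": fit["intercept"], "r2": fit["r2"]})
    lines = pd.DataFrame(rows).sort_values("level").reset_index(drop=True)

    lev = lines["level"].to_numpy()
    slope_rep = _replot(lev, lines["slope"].to_numpy())
    int_rep = _replot(lev, lines["intercept"].to_numpy())

    def _affected(rep, series) -> bool:
        series = np.asarray(series)
        base = abs(series[0])
        rel = (series.max() - series.min()) / base if base > 0 else 0.0
        if rel <= kc.REL_CHANGE_MIN:
            return False
        # t-test on the replot slope against zero
        n = len(series)
        if n < 3:
            return rel > kc.REL_CHANGE_MIN
        pred = rep["slope"] * lev + rep["intercept"]
        resid = series - pred
        s2 = float(np.sum(resid**2)) / (n - 2)
        sxx = float(np.sum((lev - lev.mean()) ** 2))
        if s2 <= 0:
            return True
        t = rep["slope"] / math.sqrt(s2 / sxx)
        return 2 * stats.t.sf(abs(t), n - 2) < kc.ALPHA

    slope_hit = _affected(slope_rep, lines["slope"])
    int_hit = _affected(int_rep, lines["intercept"])
    slope_rep["affected"] = slope_hit
    int_rep["affected"] = int_hit
    # linearity matters only for replots the inhibitor actually moves;
    # a flat replot has no variance to explain and is trivially linear
    linear = bool((not slope_hit or slope_rep["r2"] > 0.8)
                  and (not int_hit or int_rep["r2"] > 0.8))

    kis = slope_rep["intercept"] / slope_rep["slope"] if slope_hit and slope_rep["slope"] > 0 else math.inf
    kii = int_rep["intercept"] / int_rep["slope"] if int_hit and int_rep["slope"] > 0 else math.inf

    if slope_hit and int_hit:
        pattern = "mixed"
    elif slope_hit:
        pattern = "competitive"
    elif int_hit:
        pattern = "uncompetitive"
    else:
        pattern = "none"

    return ReplotResult(varied, inhibitor, lines, slope_rep, int_rep,
                        float(kis), float(kii), pattern, linear)


# ---------------------------------------------------------------------------
# model discrimination
# ---------------------------------------------------------------------------

@dataclass
class Discrimination:
    ranked: list[FitResult]
    delta_aicc: list[float]
    best: str
    indeterminate: bool


def discriminate_mechanisms(
    data: VelocityDataset,
    candidates: Sequence[str] = ("ordered_bibi", "ping_pong"),
) -> Discrimination:
    """Fit each candidate mechanism and rank by AICc (ties by parameter
    count, fewer wins). ΔAICc < 2 between the top two is flagged
    indeterminate — the design does not separate the mechanisms."""
    if len(candidates) < 2:
        raise InputError("need >=2 candidate mechanisms")
    fits = []
    for tag in candidates:
        try:
            fits.append(fit_mechanism(data, tag))
        except AnalysisError:
            continue
    if not fits:
        raise ConvergenceError("no candidate mechanism could be fitted")
    fits.sort(key=lambda f: (f.aicc, f.n_params))
    deltas = [f.aicc - fits[0].aicc for f in fits]
    # indeterminacy is judged on the deviance term alone: with nested
    # candidates differing by one parameter, equal-RSS ties always show
    # ΔAICc >= 2 from the parameter penalty even though the data carry no
    # evidence either way
    dev = [f.n_obs * math.log(max(f.rss, 1e-300) / f.n_obs) for f in fits]
    indeterminate = len(fits) > 1 and (min(dev[1:]) - dev[0]) < 2.0
    return Discrimination(fits, deltas, fits[0].mechanism, indeterminate)
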