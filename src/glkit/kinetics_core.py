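"""Steady-state bisubstrate kinetics on enzyme-form graphs.

A kinetic mechanism is represented as a directed graph of enzyme forms
(``KineticScheme``).  Each edge carries a rate constant and, optionally, the
name of a ligand whose free concentration multiplies the rate (pseudo-first
order binding steps).  The steady-state velocity is obtained numerically by
the King–Altman construction: solve the linear system for the stationary
distribution over enzyme forms and read the net flux through a designated
reaction step.

For the ordered sequential Bi-Bi mechanism (A binds first, Q leaves last,
via a ternary central complex) the module also provides the Cleland
closed-form initial-rate law and a constructor that maps phenomenological
constants (Vmax, Km's, Ki's) onto a minimal 4-state microscopic scheme —
the two routes agree to numerical precision and serve as mutual oracles.

Units are fixed package-wide: concentrations in µM, velocities in
µmol·mg⁻¹·min⁻¹ (the scheme's ``total_enzyme`` is the specific-activity
scale factor, 1.0 by default so rate constants are expressed per minute).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, PatternUndefinedError, SchemeError

MECHANISM_TAGS = ("ordered_bibi", "random_bibi_rapid_eq", "ping_pong")

#: Classification thresholds for Cleland product-inhibition patterns: a
#: replot parameter (slope or intercept) counts as inhibitor-affected when its
#: fractional change across the inhibitor range exceeds REL_CHANGE_MIN *and*
#: an F-test comparing the constrained (shared parameter) against the free
#: per-level linear model rejects at ALPHA.
REL_CHANGE_MIN = 0.10
ALPHA = 0.05

#: Reciprocal grids mimic the experimental concentration span: 8 points with
#: 1/[S] evenly spaced between 1/(5·Km_app) and 1/(0.2·Km_app).
RECIPROCAL_POINTS = 8
RECIPROCAL_SPAN = (0.2, 5.0)

#: Relative RMS deviation of a reciprocal plot from its best line above which
#: the pattern is reported as undefined rather than silently classified.
LINEARITY_RTOL = 1e-2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcentrationState:
    """Free ligand concentrations (µM). A = Mg·ADP, B = D-glucose,
    P = D-glucose-6-P, Q = Mg·AMP for the glucokinase reaction."""

    A: float = 0.0
    B: float = 0.0
    P: float = 0.0
    Q: float = 0.0

    def __post_init__(self):
        for name in ("A", "B", "P", "Q"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise InputError(f"concentration {name}={value} must be finite and >= 0")

    def as_dict(self) -> dict[str, float]:
        return {"A": self.A, "B": self.B, "P": self.P, "Q": self.Q}


@dataclass(frozen=True)
class MechanismParams:
    """Phenomenological constants of a bisubstrate mechanism.

    Vmax in µmol·mg⁻¹·min⁻¹; all K's in µM.  ``Ki_A`` is the dissociation
    constant of A from the binary E·A complex (Cleland's Kia); ``Ki_P`` and
    ``Ki_Q`` are product inhibition (rebinding) constants.
    """

    Vmax: float
    Km_A: float
    Km_B: float
    Ki_A: float
    Ki_P: float = np.inf
    Ki_Q: float = np.inf
    mechanism: str = "ordered_bibi"

    def __post_init__(self):
        if self.mechanism not in MECHANISM_TAGS:
            raise InputError(f"unknown mechanism tag {self.mechanism!r}")
        for name in ("Vmax", "Km_A", "Km_B", "Ki_A", "Ki_P", "Ki_Q"):
            value = getattr(self, name)
            if not value > 0:
                raise InputError(f"{name}={value} must be strictly positive")
        if not np.isfinite(self.Vmax):
            raise InputError("Vmax must be finite")


@dataclass(frozen=True)
class Transition:
    """One directed edge of the enzyme-form graph.

    ``rate`` is a first-order constant (min⁻¹) or, when ``ligand`` is set, a
    second-order constant (µM⁻¹·min⁻¹) multiplied by that ligand's
    concentration at evaluation time.
    """

    source: str
    target: str
    rate: float
    ligand: str | None = None
    label: str | None = None

    def __post_init__(self):
        if not self.rate > 0:
            raise SchemeError(f"rate constant on {self.source}->{self.target} must be > 0")


@dataclass
class KineticScheme:
    """Enzyme-form reaction graph with a designated net-flux step.

    ``flux`` lists (edge label, sign) pairs whose signed fluxes sum to the
    reaction velocity — e.g. the chemical step forward minus its reverse.
    """

    states: list[str]
    transitions: list[Transition]
    flux: list[tuple[str, int]]
    total_enzyme: float = 1.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(set(self.states)) != len(self.states) or not self.states:
            raise SchemeError("states must be a non-empty list of unique labels")
        index = {s: i for i, s in enumerate(self.states)}
        labels = [t.label for t in self.transitions if t.label is not None]
        if len(set(labels)) != len(labels):
            raise SchemeError("edge labels must be unique")
        for t in self.transitions:
            if t.source not in index or t.target not in index:
                raise SchemeError(f"edge {t.source}->{t.target} references unknown state")
        if not self.flux:
            raise SchemeError("scheme must designate at least one flux edge")
        for label, sign in self.flux:
            if label not in labels:
                raise SchemeError(f"flux edge {label!r} is not a labelled transition")
            if sign not in (-1, 1):
                raise SchemeError("flux signs must be +1 or -1")
        if not self.total_enzyme > 0:
            raise SchemeError("total_enzyme must be > 0")
        self._check_strongly_connected()

    def _check_strongly_connected(self) -> None:
        n = len(self.states)
        index = {s: i for i, s in enumerate(self.states)}
        fwd = [[] for _ in range(n)]
        bwd = [[] for _ in range(n)]
        for t in self.transitions:
            fwd[index[t.source]].append(index[t.target])
            bwd[index[t.target]].append(index[t.source])

        def reach(adj):
            seen = {0}
            stack = [0]
            while stack:
                for j in adj[stack.pop()]:
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
            return seen

        if len(reach(fwd)) != n or len(reach(bwd)) != n:
            raise SchemeError("scheme graph is not strongly connected")

    def ligands(self) -> set[str]:
        return {t.ligand for t in self.transitions if t.ligand is not None}

    # -- plain-text round-trippable serialization ---------------------------

    def to_text(self) -> str:
        lines = [
            "# glkit kinetic scheme",
            f"total_enzyme = {self.total_enzyme!r}",
            "states = " + ", ".join(self.states),
        ]
        for t in self.transitions:
            lines.append(
                "edge = {},{},{!r},{},{}".format(
                    t.source, t.target, t.rate, t.ligand or "", t.label or ""
                )
            )
        lines.append("flux = " + ", ".join(f"{lab}:{sgn:+d}" for lab, sgn in self.flux))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "KineticScheme":
        states: list[str] = []
        transitions: list[Transition] = []
        flux: list[tuple[str, int]] = []
        total = 1.0
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise SchemeError(f"unparseable scheme line: {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "total_enzyme":
                total = float(value)
            elif key == "states":
                states = [s.strip() for s in value.split(",") if s.strip()]
            elif key == "edge":
                parts = [p.strip() for p in value.split(",")]
                if len(parts) < 3:
                    raise SchemeError(f"edge needs source,target,rate: {raw!r}")
                parts += [""] * (5 - len(parts))
                src, dst, rate, ligand, label = parts[:5]
                transitions.append(
                    Transition(src, dst, float(rate), ligand or None, label or None)
                )
            elif key == "flux":
                for item in value.split(","):
                    lab, _, sgn = item.strip().rpartition(":")
                    flux.append((lab, int(sgn)))
            else:
                raise SchemeError(f"unknown scheme key {key!r}")
        return cls(states=states, transitions=transitions, flux=flux, total_enzyme=total)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def read(cls, path: str | Path) -> "KineticScheme":
        return cls.from_text(Path(path).read_text())


# ---------------------------------------------------------------------------
# closed-form rate laws
# ---------------------------------------------------------------------------

def rate_ordered_bibi(params: MechanismParams, state: ConcentrationState) -> float:
    """Forward initial-rate law of the ordered sequential Bi-Bi mechanism.

    v = Vmax·A·B / (Kia·Kb + Kb·A + Ka·B + A·B), valid for P = Q = 0.
    Tends to Vmax as both substrates saturate; exactly 0 when either is 0.
    """
    if state.P != 0 or state.Q != 0:
        raise InputError("rate_ordered_bibi is the forward initial-rate form; P and Q must be 0")
    a, b = state.A, state.B
    denom = (
        params.Ki_A * params.Km_B
        + params.Km_B * a
        + params.Km_A * b
        + a * b
    )
    return params.Vmax * a * b / denom


def rate_ping_pong(params: MechanismParams, state: ConcentrationState) -> float:
    """Forward initial-rate law of the ping-pong (substituted-enzyme)
    mechanism: no constant (Kia·Kb) term, hence parallel reciprocal lines."""
    if state.P != 0 or state.Q != 0:
        raise InputError("rate_ping_pong is the forward initial-rate form; P and Q must be 0")
    a, b = state.A, state.B
    denom = params.Km_B * a + params.Km_A * b + a * b
    return params.Vmax * a * b / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# microscopic scheme construction
# ---------------------------------------------------------------------------

def ordered_bibi_scheme(params: MechanismParams, total_enzyme: float = 1.0) -> KineticScheme:
    """Minimal 4-state ordered Bi-Bi scheme matching the given constants.

    States E, EA, EAB (the lumped ternary/central complex) and EQ; eight rate
    constants.  The chemistry+P-release is lumped into EAB -> EQ.  Microscopic
    constants are chosen so the Cleland definitions reproduce the
    phenomenological ones exactly:

        kcat = k5·k7/(k5+k7),  Km_A = k5·k7/(k1·(k5+k7)),  Kia = k2/k1,
        Km_B = k7·(k4+k5)/(k3·(k5+k7))

    with the free choices k5 = k7 = 2·kcat and k4 = k5.  Product rebinding
    uses Ki_P = k5/k6 (P on EQ) and Ki_Q = k7/k8 (Q on E); infinite Ki's
    yield vanishingly small but positive rebinding constants so the graph
    stays strongly connected.
    """
    kcat = params.Vmax  # per unit total_enzyme
    k5 = k7 = 2.0 * kcat
    k4 = k5
    k1 = kcat / params.Km_A
    k2 = params.Ki_A * k1
    k3 = k7 * (k4 + k5) / (params.Km_B * (k5 + k7))
    tiny = 1e-12  # keeps reverse edges present (strong connectivity) when Ki = inf
    k6 = max(k5 / params.Ki_P, tiny) if np.isfinite(params.Ki_P) else tiny
    k8 = max(k7 / params.Ki_Q, tiny) if np.isfinite(params.Ki_Q) else tiny
    return KineticScheme(
        states=["E", "EA", "EAB", "EQ"],
        transitions=[
            Transition("E", "EA", k1, "A", "bind_A"),
            Transition("EA", "E", k2, None, "release_A"),
            Transition("EA", "EAB", k3, "B", "bind_B"),
            Transition("EAB", "EA", k4, None, "release_B"),
            Transition("EAB", "EQ", k5, None, "chem_f"),
            Transition("EQ", "EAB", k6, "P", "chem_r"),
            Transition("EQ", "E", k7, None, "release_Q"),
            Transition("E", "EQ", k8, "Q", "bind_Q"),
        ],
        flux=[("chem_f", +1), ("chem_r", -1)],
        total_enzyme=total_enzyme,
    )


def michaelis_menten_scheme(kcat: float, k_on: float, k_off: float,
                            total_enzyme: float = 1.0) -> KineticScheme:
    """Two-state single-substrate scheme E ⇌ ES → E + P (textbook limit)."""
    return KineticScheme(
        states=["E", "ES"],
        transitions=[
            Transition("E", "ES", k_on, "A", "bind"),
            Transition("ES", "E", k_off, None, "unbind"),
            Transition("ES", "E", kcat, None, "cat"),
        ],
        flux=[("cat", +1)],
        total_enzyme=total_enzyme,
    )


# ---------------------------------------------------------------------------
# numeric King–Altman steady state
# ---------------------------------------------------------------------------

def stationary_distribution(scheme: KineticScheme,
                            concentrations: Mapping[str, float] | ConcentrationState) -> np.ndarray:
    """Stationary enzyme-form distribution (sums to 1) by linear solve."""
    conc = concentrations.as_dict() if isinstance(concentrations, ConcentrationState) else dict(concentrations)
    for lig in scheme.ligands():
        if lig not in conc:
            raise InputError(f"ligand {lig!r} appears on an edge but not in the concentration vector")
        if conc[lig] < 0:
            raise InputError(f"concentration of {lig!r} must be >= 0")
    n = len(scheme.states)
    index = {s: i for i, s in enumerate(scheme.states)}
    m = np.zeros((n, n))
    for t in scheme.transitions:
        k = t.rate * (conc[t.ligand] if t.ligand else 1.0)
        i, j = index[t.source], index[t.target]
        m[j, i] += k
        m[i, i] -= k
    # replace last balance equation with normalization Σx = 1
    a = m.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        x = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise SchemeError(f"singular steady-state system: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SchemeError("steady-state solve produced non-finite occupancies")
    return x


def steady_state_rate(scheme: KineticScheme,
                      concentrations: Mapping[str, float] | ConcentrationState) -> float:
    """Net steady-state velocity through the scheme's designated flux step.

    Returns velocity in the units of ``total_enzyme`` × rate constants
    (µmol·mg⁻¹·min⁻¹ under the package conventions).  At steady state the
    net flux is identical through every cut of a single catalytic cycle, so
    the choice of step is a labelling convenience, not a modelling choice.
    """
    conc = concentrations.as_dict() if isinstance(concentrations, ConcentrationState) else dict(concentrations)
    x = stationary_distribution(scheme, conc)
    index = {s: i for i, s in enumerate(scheme.states)}
    by_label = {t.label: t for t in scheme.transitions if t.label}
    v = 0.0
    for label, sign in scheme.flux:
        t = by_label[label]
        k = t.rate * (conc[t.ligand] if t.ligand else 1.0)
        v += sign * k * x[index[t.source]]
    return v * scheme.total_enzyme


# ---------------------------------------------------------------------------
# product-inhibition pattern prediction
# ---------------------------------------------------------------------------

def _line_fit(inv_s: np.ndarray, inv_v: np.ndarray) -> tuple[float, float, float]:
    """OLS line fit of 1/v on 1/[S]; returns (slope, intercept, rel_rms)."""
    slope, intercept = np.polyfit(inv_s, inv_v, 1)
    resid = inv_v - (slope * inv_s + intercept)
    rel_rms = float(np.sqrt(np.mean(resid**2)) / np.mean(np.abs(inv_v)))
    return float(slope), float(intercept), rel_rms


def _constrained_f_test(inv_s_all, inv_v_all, level_idx, share: str) -> float:
    """p-value of the F-test comparing per-level free lines against lines
    constrained to share a slope or intercept across inhibitor levels."""
    n_levels = level_idx.max() + 1
    n = len(inv_v_all)
    # free model: per-level slope + intercept
    rss_free = 0.0
    for lev in range(n_levels):
        m = level_idx == lev
        s, c, _ = _line_fit(inv_s_all[m], inv_v_all[m])
        rss_free += float(np.sum((inv_v_all[m] - (s * inv_s_all[m] + c)) ** 2))
    p_free = 2 * n_levels
    # constrained model via a stacked design matrix
    if share == "slope":
        cols = [inv_s_all] + [ (level_idx == lev).astype(float) for lev in range(n_levels)]
    else:  # shared intercept, per-level slopes
        cols = [np.ones(n)] + [inv_s_all * (level_idx == lev) for lev in range(n_levels)]
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, inv_v_all, rcond=None)
    rss_con = float(np.sum((inv_v_all - design @ beta) ** 2))
    p_con = design.shape[1]
    df_num = p_free - p_con
    df_den = n - p_free
    if df_den <= 0:
        return 1.0
    scale = rss_free / df_den
    if scale <= 0:  # free model is exact to machine precision
        return 0.0 if rss_con > 1e-12 * max(rss_free, 1.0) + 1e-300 else 1.0
    f = (rss_con - rss_free) / df_num / scale
    return float(stats.f.sf(f, df_num, df_den))


def _half_saturation(velocity, s_max: float = 1e9) -> float:
    """Concentration giving half the saturating velocity, by bisection."""
    v_inf = velocity(s_max)
    if not v_inf > 0:
        raise InputError("velocity does not saturate to a positive plateau")
    lo, hi = 1e-9, s_max
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if velocity(mid) < 0.5 * v_inf:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def reciprocal_grid(km_app: float, n: int = RECIPROCAL_POINTS,
                    span: tuple[float, float] = RECIPROCAL_SPAN) -> np.ndarray:
    """Substrate grid with 1/[S] evenly spaced between 1/(span[1]·Km) and
    1/(span[0]·Km) — the classic double-reciprocal design."""
    inv = np.linspace(1.0 / (span[1] * km_app), 1.0 / (span[0] * km_app), n)
    return 1.0 / inv[::-1]


def predict_inhibition_pattern(
    scheme: KineticScheme,
    varied: str,
    inhibitor: str,
    fixed_levels: Mapping[str, float] | None = None,
    inhibitor_levels: Sequence[float] | None = None,
) -> str:
    """Classify the product-inhibition pattern of ``inhibitor`` against
    ``varied`` on the given scheme.

    Velocities are computed by :func:`steady_state_rate` on a double-
    reciprocal grid at ≥3 inhibitor levels; per-level lines are regressed
    and the pattern follows Cleland's diagnostics: slope-only effect →
    competitive, intercept-only → uncompetitive, both → mixed, neither →
    none.  The co-substrate defaults to its own half-saturating level
    (non-saturating, where mixed patterns are not masked).
    """
    if varied not in ("A", "B") or inhibitor not in ("P", "Q"):
        raise InputError("varied must be a substrate (A/B) and inhibitor a product (P/Q)")
    co = "B" if varied == "A" else "A"
    fixed = dict(fixed_levels or {})

    def v_of(s: float, i: float, co_level: float) -> float:
        conc = {varied: s, co: co_level, inhibitor: i, "P": 0.0, "Q": 0.0}
        conc[inhibitor] = i
        for sp, lvl in fixed.items():
            if sp not in (varied, inhibitor):
                conc[sp] = lvl
        return steady_state_rate(scheme, conc)

    if co in fixed:
        co_level = fixed[co]
    else:
        co_level = _half_saturation(lambda s: steady_state_rate(
            scheme, {varied: 1e9, co: s, "P": 0.0, "Q": 0.0}))
    km_app = _half_saturation(lambda s: v_of(s, 0.0, co_level))
    grid = reciprocal_grid(km_app)

    if inhibitor_levels is None:
        # self-scaling levels: find the dose halving v at the grid midpoint
        s_mid = float(np.median(grid))
        v0 = v_of(s_mid, 0.0, co_level)

        def drop(i):
            return v_of(s_mid, i, co_level) - 0.5 * v0

        hi = km_app
        for _ in range(80):
            if drop(hi) < 0:
                break
            hi *= 2.0
        else:
            # inhibitor has no effect at any dose -> pattern "none"
            return "none"
        from scipy.optimize import brentq
        i_half = brentq(drop, 0.0, hi, xtol=1e-9 * hi)
        inhibitor_levels = [0.0, 0.5 * i_half, i_half, 2.0 * i_half]
    inhibitor_levels = list(inhibitor_levels)
    if len(inhibitor_levels) < 3:
        raise InputError("need at least 3 inhibitor levels (including 0)")
    if all(i == 0 for i in inhibitor_levels):
        return "none"

    slopes, intercepts = [], []
    inv_s_all, inv_v_all, lev_all = [], [], []
    for lev, i_conc in enumerate(inhibitor_levels):
        v = np.array([v_of(s, i_conc, co_level) for s in grid])
        if np.any(v <= 0):
            raise PatternUndefinedError("non-positive velocity on the reciprocal grid")
        slope, intercept, rel_rms = _line_fit(1.0 / grid, 1.0 / v)
        if rel_rms > LINEARITY_RTOL:
            raise PatternUndefinedError(
                f"reciprocal plot at inhibitor level {i_conc:g} deviates from a line "
                f"(relative RMS {rel_rms:.2e} > {LINEARITY_RTOL:g})")
        slopes.append(slope)
        intercepts.append(intercept)
        inv_s_all.append(1.0 / grid)
        inv_v_all.append(1.0 / v)
        lev_all.append(np.full(grid.size, lev))
    inv_s_all = np.concatenate(inv_s_all)
    inv_v_all = np.concatenate(inv_v_all)
    lev_all = np.concatenate(lev_all)

    slope_rel = (max(slopes) - min(slopes)) / abs(slopes[0])
    int_rel = (max(intercepts) - min(intercepts)) / abs(intercepts[0])
    slope_hit = slope_rel > REL_CHANGE_MIN and \
        _constrained_f_test(inv_s_all, inv_v_all, lev_all.astype(int), "slope") < ALPHA
    int_hit = int_rel > REL_CHANGE_MIN and \
        _constrained_f_test(inv_s_all, inv_v_all, lev_all.astype(int), "intercept") < ALPHA

    if slope_hit and int_hit:
        return "mixed"
    if slope_hit:
        return "competitive"
    if int_hit:
        return "uncompetitive"
    return "none"


def inhibition_pattern_matrix(
    scheme: KineticScheme,
    substrates: Iterable[str] = ("A", "B"),
    products: Iterable[str] = ("P", "Q"),
) -> dict[tuple[str, str], str]:
    """Full substrates × products pattern matrix, keyed (inhibitor, varied)."""
    return {
        (prod, sub): predict_inhibition_pattern(scheme, sub, prod)
        for prod, sub in itertools.product(products, substrates)
    }
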