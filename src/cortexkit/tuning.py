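"""Contrast tuning curves and optogenetic-modulation models.

Sigmoid (Naka-Rushton-style) fits to normalized contrast tuning curves,
the normalized first/second-peak difference, rank-score stimulus parameter
selection, robust-tuning detection, the divisive / subtractive /
saturation-additive interneuron modulation models, and the two-stage
conductance-based pyramidal-cell rate model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import rankdata

CONTRASTS = (0.06, 0.12, 0.24, 0.5, 1.0)


@dataclass
class TuningCurve:
    """Mean (and sd) response per contrast, one curve per opto level.

    Responses are normalized by the mean baseline (no-opto) firing rate at
    the highest contrast level.
    """

    contrasts: np.ndarray
    mean: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


def normalize_tuning(contrasts, mean_rates_by_level: dict, baseline_level=0.0
                     ) -> dict[float, TuningCurve]:
    """Divide every curve by the baseline curve's highest-contrast mean."""
    base = np.asarray(mean_rates_by_level[baseline_level], dtype=float)
    denom = base[np.argmax(np.asarray(contrasts))]
    if denom <= 0:
        raise ValueError("baseline response at highest contrast must be > 0")
    return {lvl: TuningCurve(contrasts, np.asarray(r, float) / denom)
            for lvl, r in mean_rates_by_level.items()}


@dataclass
class SigmoidParams:
    m: float        # baseline response at minimum contrast
    R_max: float    # maximum increase above baseline
    n: float        # steepness
    c50: float      # contrast at half R_max
    r2: float = float("nan")
    degenerate: bool = False


def sigmoid_response(c, m: float, R_max: float, n: float, c50: float):
    """R(c) = R_max c^n / (c^n + c50^n) + m."""
    c = np.asarray(c, dtype=float)
    cn = np.power(c, n)
    return R_max * cn / (cn + c50 ** n) + m


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_sigmoid(curve: TuningCurve) -> SigmoidParams:
    """Least-squares sigmoid fit with multi-start over (n, c50).

    Requires at least 4 contrast points. A flat curve yields R_max ~ 0 with
    a degenerate-r2 flag.
    """
    c = curve.contrasts
    y = curve.mean
    if len(np.unique(c)) < 4:
        raise ValueError("need >= 4 contrast points for a 4-parameter fit")

    spread = y.max() - y.min()
    best = None
    for n0 in (1.0, 2.0, 4.0):
        for c500 in (0.1, 0.3, 0.6):
            x0 = np.array([y.min(), max(spread, 1e-3), n0, c500])
            try:
                res = least_squares(
                    lambda p: sigmoid_response(c, *p) - y, x0,
                    bounds=([-np.inf, 0.0, 1e-3, 1e-3],
                            [np.inf, np.inf, 50.0, 1.0]))
            except ValueError:
                continue
            if best is None or res.cost < best.cost:
                best = res
    m, R_max, n, c50 = best.x
    r2 = _r2(y, sigmoid_response(c, m, R_max, n, c50))
    degenerate = spread < 1e-12 or not math.isfinite(r2)
    return SigmoidParams(m=float(m), R_max=float(R_max), n=float(n),
                         c50=float(c50), r2=r2, degenerate=degenerate)


def peak_difference(r1: float, r2: float) -> float:
    """Normalized difference (r1 - r2)/(r1 + r2) of the first and second
    response peaks (the Michelson contrast of the two peak rates)."""
    if r1 + r2 == 0:
        raise ValueError("r1 + r2 must be nonzero")
    return (r1 - r2) / (r1 + r2)


def select_grating_params(table, r_th: float = 30.0, c50_border: float = 0.95):
    """Rank-score selection of the stimulus parameter combination.

    ``table`` is a sequence of dicts with keys 'r1', 'r2', 'c50', 'n',
    'peak_diff' (plus arbitrary identifiers). Combinations with either peak
    rate below ``r_th`` or c50 near 1.0 are excluded; among the rest, rank
    scores (peak_diff and c50: lower is better; n: higher is better) are
    multiplied and the highest product wins. Ties break on the lowest
    peak difference.
    """
    rows = list(table)
    keep = [row for row in rows
            if row["r1"] >= r_th and row["r2"] >= r_th
            and row["c50"] <= c50_border]
    if not keep:
        raise ValueError("all parameter combinations excluded")
    if len(keep) == 1:
        return keep[0]
    pd_arr = np.array([row["peak_diff"] for row in keep])
    c50_arr = np.array([row["c50"] for row in keep])
    n_arr = np.array([row["n"] for row in keep])
    # higher rank score = better
    score = rankdata(-pd_arr) * rankdata(-c50_arr) * rankdata(n_arr)
    best = np.flatnonzero(score == score.max())
    if len(best) > 1:
        best = [best[int(np.argmin(pd_arr[best]))]]
    return keep[int(best[0])]


def detect_robust_tuning(curves_by_cell: dict, min_rate_hz: float = 0.5
                         ) -> set:
    """Cells firing above ``min_rate_hz`` under every stimulus condition
    with strictly monotonically increasing tuning curves.

    ``curves_by_cell`` maps cell id -> array of mean rates (Hz) per contrast
    in increasing-contrast order (for multi-condition data, the per-cell
    minimum rate over all conditions must respect the threshold; pass the
    baseline curve here and enforce other conditions upstream, or pass a
    2-D array (n_conditions, n_contrasts)).
    """
    out = set()
    for cid, rates in curves_by_cell.items():
        arr = np.atleast_2d(np.asarray(rates, dtype=float))
        if arr.min() < min_rate_hz:
            continue
        if all(np.all(np.diff(row) > 0) for row in arr):
            out.add(cid)
    return out


# ---------------------------------------------------------------------------
# Interneuron modulation models
# ---------------------------------------------------------------------------

@dataclass
class ModulationFit:
    model: str               # divisive | subtractive | saturation_additive
    terms: dict[str, float]  # g | h | (S, A)
    r2: float


def modulation_response(c, baseline: SigmoidParams, model: str,
                        **terms):
    """Evaluate a modulation model on top of fixed baseline parameters."""
    R = sigmoid_response(c, baseline.m, baseline.R_max, baseline.n, baseline.c50)
    if model == "divisive":
        return R / terms["g"]
    if model == "subtractive":
        return np.maximum(R - terms["h"], 0.0)
    if model == "saturation_additive":
        c = np.asarray(c, dtype=float)
        n, c50 = baseline.n, baseline.c50
        cn = np.power(c, -n)
        return R + terms["S"] * cn / (cn + c50 ** (-n)) + terms["A"]
    raise ValueError(f"unknown model '{model}'")


def fit_modulation(baseline: SigmoidParams, curve: TuningCurve,
                   model: str) -> ModulationFit:
    """Fit the free term(s) of one modulation model, baseline held fixed."""
    if baseline is None:
        raise ValueError("baseline fit missing")
    c, y = curve.contrasts, curve.mean
    if model == "divisive":
        res = least_squares(
            lambda p: modulation_response(c, baseline, model, g=p[0]) - y,
            x0=[1.0], bounds=([1e-9], [np.inf]))
        terms = {"g": float(res.x[0])}
    elif model == "subtractive":
        res = least_squares(
            lambda p: modulation_response(c, baseline, model, h=p[0]) - y,
            x0=[0.0])
        terms = {"h": float(res.x[0])}
    elif model == "saturation_additive":
        res = least_squares(
            lambda p: modulation_response(c, baseline, model,
                                          S=p[0], A=p[1]) - y,
            x0=[0.0, 0.0])
        terms = {"S": float(res.x[0]), "A": float(res.x[1])}
    else:
        raise ValueError(f"unknown model '{model}'")
    yhat = modulation_response(c, baseline, model, **terms)
    return ModulationFit(model=model, terms=terms, r2=_r2(y, yhat))


_MODULATION_NPARAMS = {"divisive": 1, "subtractive": 1,
                       "saturation_additive": 2}


def identify_modulation_model(baseline: SigmoidParams, curve: TuningCurve
                              ) -> tuple[str, dict[str, ModulationFit]]:
    """Fit all three modulation models and name the best-supported one.

    Every divisive curve is exactly a saturation-additive curve (the
    suppressive term satisfies c^-n/(c^-n + c50^-n) = 1 - c^n/(c^n + c50^n),
    so R/g is reproduced by S = R_max (1 - 1/g), A = m/g - m - S). Raw r^2
    therefore cannot separate the nested pair; the comparison uses the
    small-sample-corrected AIC, which penalizes the extra free parameter.
    Per-fit r^2 values remain available for reporting.
    """
    n = len(curve.contrasts)
    fits = {m: fit_modulation(baseline, curve, m) for m in _MODULATION_NPARAMS}
    best, best_aicc = None, math.inf
    for m, f in fits.items():
        pred = modulation_response(curve.contrasts, baseline, m, **f.terms)
        sse = max(float(np.sum((pred - curve.mean) ** 2)), 1e-300)
        p = _MODULATION_NPARAMS[m]
        aicc = n * math.log(sse / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)
        if aicc < best_aicc:
            best, best_aicc = m, aicc
    return best, fits


# ---------------------------------------------------------------------------
# Conductance-based pyramidal-cell model
# ---------------------------------------------------------------------------

@dataclass
class CondModelParams:
    """Two-stage conductance model constants and fitted parameters.

    Reversal potentials are named E_exc/E_inh here (the literature's R_E/R_I)
    to avoid collision with the evoked ratio R_E.
    """

    g_L: float = 6.0          # nS
    E_leak: float = -50.0     # mV
    E_exc: float = 0.0        # mV
    E_inh: float = -65.0      # mV
    V_r: float = -50.0        # mV
    V_th: float = 3.4         # mV, cubic rectification threshold
    g_E_min: float = 0.0      # nS
    g_E_max: float = 10.0     # nS
    delta_g_IE_min: float = 2.0  # nS
    c50: float = 0.3
    n: float = 2.0
    S: float = 0.0            # saturation term, nS
    A: float = 0.0            # additive term, nS


def cond_model_conductances(c, p: CondModelParams):
    """(g_E(c), g_I(c)) of the conductance model."""
    c = np.asarray(c, dtype=float)
    cn = np.power(c, p.n)
    g_E = p.g_E_max * cn / (cn + p.c50 ** p.n) + p.g_E_min
    cmn = np.power(c, -p.n)
    g_I = g_E + p.S * cmn / (cmn + p.c50 ** (-p.n)) + p.delta_g_IE_min + p.A
    return g_E, g_I


def rate_from_conductances(g_E, g_I, p: CondModelParams):
    """Cubic-rectified rate given excitatory/inhibitory conductances.

    Delta V = (g_L E_leak + g_E E_exc + g_I E_inh)/(g_L + g_E + g_I) - V_r;
    rate = [Delta V - V_th]^3 rectified at zero (arbitrary units).
    """
    g_tot = p.g_L + np.asarray(g_E, dtype=float) + np.asarray(g_I, dtype=float)
    if np.any(g_tot == 0):
        raise ZeroDivisionError("total conductance is zero")
    dV = (p.g_L * p.E_leak + g_E * p.E_exc + g_I * p.E_inh) / g_tot - p.V_r
    return np.maximum(dV - p.V_th, 0.0) ** 3


def cond_model_rate(c, p: CondModelParams):
    """Conductance-based PC model rate as a function of contrast."""
    g_E, g_I = cond_model_conductances(c, p)
    return rate_from_conductances(g_E, g_I, p)


@dataclass
class CondModelFit:
    baseline: CondModelParams
    modulated: list[CondModelParams] = field(default_factory=list)
    r2_baseline: float = float("nan")
    r2_modulated: list[float] = field(default_factory=list)


def fit_cond_model(contrasts, baseline_rates, modulated_rates_list=(),
                   base: CondModelParams | None = None) -> CondModelFit:
    """Two-stage fit of the conductance-based PC model.

    Stage 1 fits (c50, g_E_min, g_E_max, n) to the baseline curve with
    S = A = 0. Stage 2 keeps those values bit-identical and fits (S, A) for
    each modulated (photostimulation) curve.
    """
    c = np.asarray(contrasts, dtype=float)
    y0 = np.asarray(baseline_rates, dtype=float)
    order = np.argsort(c, kind="stable")  # canonical order: order-invariant fits
    c, y0 = c[order], y0[order]
    modulated_rates_list = [np.asarray(y, dtype=float)[order]
                            for y in modulated_rates_list]
    base = base or CondModelParams()

    def stage1_resid(p):
        trial = replace(base, c50=p[0], g_E_min=p[1], g_E_max=p[2], n=p[3],
                        S=0.0, A=0.0)
        return cond_model_rate(c, trial) - y0

    best = None
    for c500 in (0.1, 0.3, 0.6):
        for n0 in (1.0, 2.0, 4.0):
            for ge0 in (2.0, 6.0, 12.0):
                try:
                    res = least_squares(
                        stage1_resid, x0=[c500, 0.5, ge0, n0],
                        bounds=([1e-3, 0.0, 1e-6, 0.2], [1.0, 50.0, 200.0, 10.0]))
                except ValueError:
                    continue
                if best is None or res.cost < best.cost:
                    best = res
    if best is None:
        raise RuntimeError("stage-1 fit failed")
    fitted = replace(base, c50=float(best.x[0]), g_E_min=float(best.x[1]),
                     g_E_max=float(best.x[2]), n=float(best.x[3]),
                     S=0.0, A=0.0)
    fit = CondModelFit(baseline=fitted,
                       r2_baseline=_r2(y0, cond_model_rate(c, fitted)))

    for y in modulated_rates_list:
        y = np.asarray(y, dtype=float)

        def stage2_resid(p):
            return cond_model_rate(c, replace(fitted, S=p[0], A=p[1])) - y

        res2 = least_squares(stage2_resid, x0=[0.0, 0.0])
        mod = replace(fitted, S=float(res2.x[0]), A=float(res2.x[1]))
        fit.modulated.append(mod)
        fit.r2_modulated.append(_r2(y, cond_model_rate(c, mod)))
    return fit
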