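"""Enzyme-kinetics fits for RNA polymerase proofreading experiments.

Four model families cover the quantities the hydrolysis assays report:

* single-exponential time courses, y(t) = A * (1 - exp(-k t)), for
  incorporation / misincorporation / cleavage rates;
* Michaelis-Menten titrations, v(c) = kcat * c / (KM + c), for the Mg2+
  dependence of transcript hydrolysis;
* Arrhenius temperature series, ln k = ln A - Ea / (R T), fitted by ordinary
  least squares of ln k on 1/T with R = 8.314 J mol-1 K-1 and Ea reported in
  kJ mol-1;
* pH-rate profiles, compared between a log-linear form
  (log10 k = c0 + g * pH, the shape expected when rate tracks hydroxide
  concentration) and a titration form k = kmax / (1 + 10**(n (pKa - pH)))
  whose half-maximum marks an apparent pKa, diagnostic of a general base in
  catalysis. Both pH models are fitted on the log10 k scale and compared by
  small-sample-corrected AIC, since they are non-nested.

Nonlinear fits use bounded Levenberg-Marquardt/trust-region least squares
(scipy.optimize.curve_fit) with deterministic, derivative-free starting
values; the two linear fits use closed-form OLS.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "R_GAS",
    "KineticSeries",
    "FitResult",
    "ModelComparison",
    "FoldChange",
    "fit_exponential",
    "fit_michaelis_menten",
    "fit_arrhenius",
    "fit_ph_loglinear",
    "fit_ph_titration",
    "analyze_ph_profile",
    "fold_change",
    "model_function",
]

#: gas constant, J mol-1 K-1
R_GAS = 8.314


# ---------------------------------------------------------------------------
# model functions (kwargs mirror FitResult parameter names)
# ---------------------------------------------------------------------------

def _exponential(t, k, A):
    return A * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def _michaelis_menten(c, kcat, km):
    c = np.asarray(c, dtype=float)
    return kcat * c / (km + c)


def _arrhenius(T, ea_kj, lnA):
    T = np.asarray(T, dtype=float)
    return np.exp(lnA - ea_kj * 1000.0 / (R_GAS * T))


def _ph_loglinear(ph, g, c0):
    return 10.0 ** (c0 + g * np.asarray(ph, dtype=float))


def _ph_titration(ph, kmax, pka, n):
    ph = np.asarray(ph, dtype=float)
    return kmax / (1.0 + 10.0 ** (n * (pka - ph)))


_MODELS = {
    "exponential": _exponential,
    "michaelis_menten": _michaelis_menten,
    "arrhenius": _arrhenius,
    "ph_loglinear": _ph_loglinear,
    "ph_titration": _ph_titration,
}

MODEL_NAMES = frozenset(_MODELS)


def model_function(name: str):
    """Return the response function for a named model (kwargs interface)."""
    try:
        return _MODELS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; expected one of {sorted(_MODELS)}") from None


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class KineticSeries:
    """One measured series: x (time s, concentration mM, temperature K, or
    pH) against y (fraction reacted or rate s-1). Sorted by x on creation."""

    x: np.ndarray
    y: np.ndarray
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        order = np.argsort(x, kind="stable")
        self.x = x[order]
        self.y = y[order]

    def __len__(self) -> int:
        return self.x.size


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    se: dict[str, float]
    rss: float
    converged: bool
    n_obs: int
    message: str = ""

    def __getitem__(self, name: str) -> float:
        return self.params[name]


@dataclass
class ModelComparison:
    """Outcome of fitting competing models to one series."""

    fits: dict[str, FitResult]
    scores: dict[str, float]          # AICc per candidate
    selected: str
    score_difference: float           # runner-up AICc minus winner AICc, >= 0
    ambiguous: bool                   # score difference < 2
    degenerate: bool = False          # e.g. flat profile; selection not meaningful

    @property
    def best(self) -> FitResult:
        return self.fits[self.selected]


@dataclass
class FoldChange:
    ratio: float
    se: float
    parameter: str = ""


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected Akaike information criterion for LS fits."""
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _failed(model: str, names: list[str], n: int, message: str) -> FitResult:
    nan = float("nan")
    return FitResult(
        model=model,
        params={p: nan for p in names},
        se={p: nan for p in names},
        rss=nan,
        converged=False,
        n_obs=n,
        message=message,
    )


def _curve_fit(model, f, series, p0, bounds, names, y=None):
    x = series.x
    yy = series.y if y is None else y
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(f, x, yy, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return _failed(model, names, len(series), str(exc))
    resid = yy - f(x, *popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    converged = bool(np.all(np.isfinite(se)))
    return FitResult(
        model=model,
        params=dict(zip(names, (float(v) for v in popt))),
        se=dict(zip(names, (float(v) for v in se))),
        rss=float(resid @ resid),
        converged=converged,
        n_obs=len(series),
        message="" if converged else "non-finite parameter covariance",
    )


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_exponential(series: KineticSeries) -> FitResult:
    """Least-squares fit of y = A (1 - exp(-k t)).

    Bounds keep k >= 0 and 0 < A <= 1.1 (fractions may overshoot 1 slightly
    through noise). The start value for k comes from the initial slope over
    the amplitude; a flat all-zero series is degenerate (k unidentifiable)
    and returns a flagged result rather than raising.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 points for an exponential fit")
    y = series.y
    if np.allclose(y, 0.0):
        return _failed("exponential", ["k", "A"], len(series), "all-zero response; rate undefined")
    a0 = float(np.clip(np.max(y), 1e-6, 1.1))
    dt = series.x[1] - series.x[0]
    slope = (y[1] - y[0]) / dt if dt > 0 else 0.0
    k0 = float(np.clip(slope / a0, 1e-6, None)) if slope > 0 else 0.1
    return _curve_fit(
        "exponential", _exponential, series,
        p0=[k0, a0], bounds=([0.0, 1e-9], [np.inf, 1.1]), names=["k", "A"],
    )


def fit_michaelis_menten(series: KineticSeries) -> FitResult:
    """Least-squares fit of v = kcat c / (KM + c), both parameters positive.

    Start values come from a Lineweaver-Burk linearization (1/v on 1/c).
    Data that never bend over (KM running away past 50x the largest
    concentration, or an unbounded covariance) are returned flagged.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 points for a Michaelis-Menten fit")
    c, v = series.x, series.y
    pos = v > 0
    kcat0, km0 = float(np.max(v)) * 1.2, float(np.median(c))
    if pos.sum() >= 2:
        slope, inter = np.polyfit(1.0 / c[pos], 1.0 / v[pos], 1)
        if inter > 0:
            kcat0 = 1.0 / inter
            if slope > 0:
                km0 = slope * kcat0
    res = _curve_fit(
        "michaelis_menten", _michaelis_menten, series,
        p0=[kcat0, km0], bounds=([1e-12, 1e-12], [np.inf, np.inf]), names=["kcat", "km"],
    )
    if res.converged and not (np.min(c) <= res.params["km"] <= np.max(c)):
        warnings.warn(
            "fitted KM lies outside the sampled concentration range; the design "
            "does not span the half-saturation point", stacklevel=2,
        )
    if res.converged and res.params["km"] > 50.0 * np.max(c):
        res.converged = False
        res.message = "KM beyond the sampled concentration range; data look linear"
    return res


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Closed-form simple OLS: slope, intercept, their s.e., and RSS."""
    n = x.size
    xb, yb = x.mean(), y.mean()
    sxx = float(((x - xb) ** 2).sum())
    slope = float(((x - xb) * (y - yb)).sum() / sxx)
    intercept = float(yb - slope * xb)
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    if n > 2:
        s2 = rss / (n - 2)
        se_slope = float(np.sqrt(s2 / sxx))
        se_inter = float(np.sqrt(s2 * (1.0 / n + xb**2 / sxx)))
    else:
        se_slope = se_inter = float("nan")
    return slope, intercept, se_slope, se_inter, rss


def fit_arrhenius(series: KineticSeries, temperature_unit: str = "K") -> FitResult:
    """OLS of ln k on 1/T; Ea = -slope * R, reported in kJ mol-1.

    Temperatures may be given in degrees Celsius with
    ``temperature_unit="C"``; internally everything is Kelvin. Any
    non-positive rate is rejected (its logarithm is undefined).
    """
    if temperature_unit not in ("K", "C"):
        raise ValueError("temperature_unit must be 'K' or 'C'")
    T = series.x + 273.15 if temperature_unit == "C" else series.x
    if len(series) < 3:
        raise ValueError("need at least 3 points for an Arrhenius fit")
    if (series.y <= 0).any():
        raise ValueError("all rates must be positive for an Arrhenius fit")
    if (T <= 0).any():
        raise ValueError("absolute temperatures must be positive")
    slope, intercept, se_slope, se_inter, rss = _ols(1.0 / T, np.log(series.y))
    ea_kj = -slope * R_GAS / 1000.0
    return FitResult(
        model="arrhenius",
        params={"ea_kj": ea_kj, "lnA": intercept},
        se={"ea_kj": se_slope * R_GAS / 1000.0, "lnA": se_inter},
        rss=rss,
        converged=True,
        n_obs=len(series),
    )


def fit_ph_loglinear(series: KineticSeries) -> FitResult:
    """OLS of log10 k on pH; the slope g is the profile gradient."""
    if (series.y <= 0).any():
        raise ValueError("all rates must be positive for a pH profile fit")
    slope, intercept, se_slope, se_inter, rss = _ols(series.x, np.log10(series.y))
    return FitResult(
        model="ph_loglinear",
        params={"g": slope, "c0": intercept},
        se={"g": se_slope, "c0": se_inter},
        rss=rss,
        converged=True,
        n_obs=len(series),
    )


def fit_ph_titration(series: KineticSeries) -> FitResult:
    """Fit k = kmax / (1 + 10**(n (pKa - pH))) on the log10 k scale.

    The slope n is bounded to [0.3, 3]; pKa starts at the pH where the rate
    first crosses half its maximum.
    """
    if (series.y <= 0).any():
        raise ValueError("all rates must be positive for a pH profile fit")
    y = series.y
    kmax0 = float(np.max(y)) * 1.05
    half = kmax0 / 2.0
    pka0 = float(series.x[int(np.argmin(np.abs(y - half)))])

    def f(ph, kmax, pka, n):
        return np.log10(_ph_titration(ph, kmax, pka, n))

    return _curve_fit(
        "ph_titration", f, series,
        p0=[kmax0, pka0, 1.0],
        bounds=([1e-12, series.x.min() - 4.0, 0.3], [np.inf, series.x.max() + 4.0, 3.0]),
        names=["kmax", "pka", "n"],
        y=np.log10(y),
    )


def analyze_ph_profile(series: KineticSeries) -> ModelComparison:
    """Fit both pH models and select by AICc on the common log10 k scale.

    A score difference below 2 is flagged ambiguous; a profile whose log10 k
    spans less than 0.05 (essentially flat, so neither shape is identified)
    is flagged degenerate.
    """
    if len(series) < 5:
        raise ValueError("need at least 5 points for a pH profile analysis")
    if series.x.max() - series.x.min() < 1.5:
        raise ValueError("pH span must be at least 1.5 units")
    if (series.y <= 0).any():
        raise ValueError("all rates must be positive for a pH profile fit")

    fits = {"ph_loglinear": fit_ph_loglinear(series), "ph_titration": fit_ph_titration(series)}
    n = len(series)
    scores = {}
    for name, fr in fits.items():
        k = len(fr.params)
        scores[name] = _aicc(fr.rss, n, k) if fr.converged else np.inf
    selected = min(scores, key=scores.get)
    other = max(scores, key=scores.get)
    diff = scores[other] - scores[selected]
    degenerate = float(np.ptp(np.log10(series.y))) < 0.05
    return ModelComparison(
        fits=fits,
        scores=scores,
        selected=selected,
        score_difference=float(diff),
        ambiguous=bool(diff < 2.0),
        degenerate=degenerate,
    )


def fold_change(result_a: FitResult, result_b: FitResult, parameter: str) -> FoldChange:
    """Ratio a/b of one fitted parameter with first-order error propagation.

    se(ratio) = ratio * sqrt((se_a/a)^2 + (se_b/b)^2), the delta-method
    variance for a quotient of independent estimates.
    """
    if result_a.model != result_b.model:
        raise ValueError("fold change requires fits of the same model")
    if parameter not in result_a.params or parameter not in result_b.params:
        raise ValueError(f"parameter {parameter!r} not present in both fits")
    pa, pb = result_a.params[parameter], result_b.params[parameter]
    if not pb > 0:
        raise ValueError("denominator parameter must be positive")
    ratio = pa / pb
    sa, sb = result_a.se[parameter], result_b.se[parameter]
    se = abs(ratio) * float(np.sqrt((sa / pa) ** 2 + (sb / pb) ** 2)) if pa != 0 else float("nan")
    return FoldChange(ratio=float(ratio), se=se, parameter=parameter)
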