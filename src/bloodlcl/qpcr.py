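"""Real-time PCR signal models and callers.

Covers the raw-signal layer of the tissue-of-origin test:

* a four-parameter logistic amplification model in cycle number, used to
  simulate instrument fluorescence traces from a template copy number and a
  per-cycle amplification efficiency;
* Ct (crossing-point) calling by the second-derivative-maximum method:
  the Ct is the cycle at which the curvature of the smoothed amplification
  curve peaks, which is threshold-free and insensitive to the plateau level;
* a two-state melting model (one sigmoidal dissociation transition per PCR
  product) and melting-peak extraction from the negative first derivative
  -dF/dT, used to separate specific amplicons from primer dimers by their
  melting temperature Tm.

Smoothing uses Savitzky-Golay local polynomial filters; discrete extrema are
refined to sub-grid precision by local quadratic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter
from scipy.special import expit

ASSAYS = ("GAPDH", "EBV", "TCRG", "TCRB")

#: acquisition grid of the post-PCR melting step: 65 -> 95 degC, 0.2 degC steps
MELT_T_START = 65.0
MELT_T_STOP = 95.0
MELT_T_STEP = 0.2

#: default number of PCR cycles
N_CYCLES = 50

#: sentinel value for called_by when an amplification check fails
NO_AMPLIFICATION = "no_amplification"


def _as_float_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D array")
    return a


@dataclass(frozen=True)
class AmplificationCurve:
    """Fluorescence versus PCR cycle for one sample and one assay."""

    sample_id: str
    assay: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycles", _as_float_array(self.cycles))
        object.__setattr__(self, "fluorescence", _as_float_array(self.fluorescence))
        if len(self.cycles) != len(self.fluorescence):
            raise ValueError("cycles and fluorescence must have equal length")
        if len(self.cycles) < 2:
            raise ValueError("need at least 2 cycles")
        d = np.diff(self.cycles)
        if not np.allclose(d, 1.0):
            raise ValueError("cycles must be strictly increasing and unit-spaced")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence versus temperature for one post-PCR melting acquisition."""

    sample_id: str
    assay: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures", _as_float_array(self.temperatures))
        object.__setattr__(self, "fluorescence", _as_float_array(self.fluorescence))
        if len(self.temperatures) != len(self.fluorescence):
            raise ValueError("temperatures and fluorescence must have equal length")
        if len(self.temperatures) < 2:
            raise ValueError("need at least 2 acquisition points")
        d = np.diff(self.temperatures)
        if np.any(d <= 0) or not np.allclose(d, d[0], atol=1e-6):
            raise ValueError("temperatures must be strictly increasing with constant spacing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])


@dataclass(frozen=True)
class CtResult:
    """Outcome of Ct calling for one curve.

    ``ct`` is None when no amplification was detected; ``called_by`` is
    ``"second_derivative_max"`` for a signal-derived Ct, ``"imputed"`` for the
    fixed fallback values assigned downstream, or ``"no_amplification"``.
    """

    sample_id: str
    assay: str
    ct: float | None
    called_by: str = "second_derivative_max"

    @property
    def is_amplified(self) -> bool:
        return self.ct is not None and self.called_by == "second_derivative_max"


@dataclass(frozen=True)
class TmPeaks:
    """Melting peaks for one curve: (tm, prominence) pairs sorted by tm."""

    sample_id: str
    assay: str
    peaks: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    @property
    def max_tm(self) -> float | None:
        """Highest-temperature peak, or None when no peak was found."""
        if not self.peaks:
            return None
        return self.peaks[-1][0]


def melt_temperature_grid() -> np.ndarray:
    """The default melting acquisition grid (65 to 95 degC, 0.2 degC steps)."""
    n = int(round((MELT_T_STOP - MELT_T_START) / MELT_T_STEP)) + 1
    return MELT_T_START + MELT_T_STEP * np.arange(n)


def simulate_amplification(
    template_copies: float,
    efficiency: float = 2.0,
    plateau: float = 10.0,
    noise_sd: float = 0.0,
    n_cycles: int = N_CYCLES,
    seed: int | np.random.Generator = 0,
    *,
    baseline: float = 0.5,
    midpoint_copies: float = 8e11,
    sample_id: str = "",
    assay: str = "",
) -> AmplificationCurve:
    """Simulate a real-time PCR fluorescence trace.

    The product copy number grows as ``N * efficiency**cycle`` until it
    saturates the reaction at ``midpoint_copies`` (half-saturation), giving a
    logistic curve in cycle number:

        F(c) = baseline + plateau / (1 + exp(-(ln E) * (c - c_mid))),
        c_mid = log_E(midpoint_copies / N).

    Multiplying the template by a factor f therefore shifts the inflection
    (and every curve feature, including the second-derivative maximum) left by
    exactly ``log_E(f)`` cycles. ``template_copies == 0`` yields a flat
    baseline with noise only.
    """
    if not np.isfinite(template_copies) or template_copies < 0:
        raise ValueError("template_copies must be a finite non-negative number")
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must lie in (1, 2] (at most doubling per cycle)")
    if plateau <= 0:
        raise ValueError("plateau must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_cycles < 2:
        raise ValueError("n_cycles must be at least 2")

    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    if template_copies == 0:
        frac = np.zeros_like(cycles)
    else:
        log_e = np.log(efficiency)
        z = cycles * log_e + np.log(template_copies) - np.log(midpoint_copies)
        frac = expit(z)
    f = baseline + plateau * frac
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    f = np.clip(f, 0.0, None)
    return AmplificationCurve(sample_id=sample_id, assay=assay, cycles=cycles, fluorescence=f)


def call_ct(
    curve: AmplificationCurve,
    min_amplitude: float = 0.5,
    *,
    window: int = 7,
    polyorder: int = 4,
    refine: str = "logistic_fit",
) -> CtResult:
    """Call the Ct of an amplification curve by second-derivative maximum.

    The curve is smoothed with a Savitzky-Golay filter and the discrete
    second derivative with respect to cycle is taken from the same local
    polynomial fit; its maximum, searched in a window around the rise
    (located via the first-derivative maximum), brackets the Ct. The bracket
    is then refined to sub-cycle precision:

    * ``refine="logistic_fit"`` (default): a four-parameter logistic model is
      least-squares fitted to the whole trace and the Ct is the analytic
      curvature maximum of the fitted model, ``m - ln(2 + sqrt(3)) / k``.
      This uses every point, so it is exact on noiseless logistic curves and
      stable to fluorescence noise. If the fit fails or lands > 2 cycles from
      the discrete bracket it is discarded in favour of the quadratic rule.
    * ``refine="quadratic"``: vertex of the parabola through the three
      second-derivative points around the discrete maximum.

    Two no-amplification guards apply: the rise amplitude (maximum minus
    early baseline) must reach ``min_amplitude``, and a positive curvature
    maximum must occur before the last three cycles (late baseline drift is
    not amplification). Ties at the discrete maximum resolve to the earlier
    cycle (``argmax`` takes the first).
    """
    if min_amplitude <= 0:
        raise ValueError("min_amplitude must be positive")
    if refine not in ("logistic_fit", "quadratic"):
        raise ValueError("refine must be 'logistic_fit' or 'quadratic'")
    n = curve.n_cycles
    if n < max(window, 9):
        raise ValueError(f"curve has {n} cycles, shorter than the smoothing window")

    f = curve.fluorescence
    smooth = savgol_filter(f, window, polyorder)
    baseline = float(np.median(smooth[: min(5, n)]))
    amplitude = float(np.max(smooth)) - baseline
    no_amp = CtResult(curve.sample_id, curve.assay, None, NO_AMPLIFICATION)
    if amplitude < min_amplitude:
        return no_amp

    # locate the exponential rise from the first-derivative maximum, away
    # from filter edge effects and the last three cycles (late drift there
    # must not count as amplification)
    d1 = savgol_filter(f, 9, 3, deriv=1, delta=1.0)
    edge = 4
    tail = max(3, edge)
    if n - edge - tail < 3:
        return no_amp
    i0 = edge + int(np.argmax(d1[edge : n - tail]))

    d2 = savgol_filter(f, window, polyorder, deriv=2, delta=1.0)
    lo = max(1, i0 - 7)
    hi = min(n - tail, i0 + 2)
    if hi <= lo:
        return no_amp
    i = lo + int(np.argmax(d2[lo:hi]))
    if d2[i] <= 0:
        return no_amp

    y0, y1, y2 = d2[i - 1], d2[i], d2[i + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.0
    if denom < 0:  # proper local maximum of the fitted parabola
        delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    ct = float(curve.cycles[i] + delta)

    if refine == "logistic_fit":
        ct_fit = _fit_logistic_sdm(curve.cycles, f, baseline, amplitude, curve.cycles[i0])
        if ct_fit is not None and abs(ct_fit - ct) <= 2.0:
            ct = ct_fit

    if not (curve.cycles[0] < ct < curve.cycles[-1]):
        return no_amp
    return CtResult(curve.sample_id, curve.assay, ct, "second_derivative_max")


def _fit_logistic_sdm(cycles: np.ndarray, f: np.ndarray, baseline: float,
                      amplitude: float, c_rise: float) -> float | None:
    """Least-squares logistic fit; returns the fitted curvature-maximum cycle."""

    def model(c, b, a, k, m):
        return b + a * expit(k * (c - m))

    p0 = (baseline, amplitude, 0.7, c_rise)
    try:
        popt, _ = curve_fit(model, cycles, f, p0=p0, maxfev=5000)
    except (RuntimeError, ValueError):
        return None
    _, a, k, m = popt
    if a <= 0 or k <= 0:
        return None
    return float(m - np.log(2.0 + np.sqrt(3.0)) / k)


def simulate_melt(
    products: list[tuple[float, float]],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    amplitude: float = 10.0,
    transition_width: float = 0.25,
    baseline: float = 0.5,
    drift_per_degC: float = 0.01,
    temperatures: np.ndarray | None = None,
    sample_id: str = "",
    assay: str = "TCRB",
) -> MeltCurve:
    """Simulate a post-PCR melting curve from (tm, fraction) products.

    Each product contributes a two-state dissociation transition: a sigmoid
    in temperature centred on its Tm, with the stated fraction of the total
    double-stranded signal. Fluorescence is the weighted sum of transitions
    on a gently decaying baseline. The negative derivative -dF/dT of the
    noiseless curve peaks at each product Tm.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    temps = melt_temperature_grid() if temperatures is None else _as_float_array(temperatures)
    total = 0.0
    for tm, frac in products:
        if not (temps[0] < tm < temps[-1]):
            raise ValueError(f"product Tm {tm} outside acquisition window "
                             f"[{temps[0]}, {temps[-1]}] degC")
        if frac < 0:
            raise ValueError("product fractions must be non-negative")
        total += frac
    if total > 1.0 + 1e-9:
        raise ValueError("product fractions must sum to at most 1")

    rng = np.random.default_rng(seed)
    f = baseline + drift_per_degC * (temps[-1] - temps)
    for tm, frac in products:
        f = f + amplitude * frac * expit((tm - temps) / transition_width)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    f = np.clip(f, 0.0, None)
    return MeltCurve(sample_id=sample_id, assay=assay, temperatures=temps, fluorescence=f)


def extract_tm_peaks(
    curve: MeltCurve,
    min_prominence: float = 0.5,
    *,
    window: int = 9,
    polyorder: int = 3,
) -> TmPeaks:
    """Extract melting peaks from -dF/dT of a smoothed melting curve.

    Local maxima of the negative first derivative with prominence at least
    ``min_prominence`` are reported, each refined by quadratic interpolation
    on the three points around the discrete maximum. ``max_tm`` is the
    highest-temperature peak — the value the TCR-beta test thresholds.
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    n = len(curve.temperatures)
    if n < 5:
        raise ValueError("melting curve needs at least 5 acquisition points")
    w = min(window, n if n % 2 == 1 else n - 1)
    if w <= polyorder:
        raise ValueError("curve too short for the smoothing order")

    step = curve.step
    negd = -savgol_filter(curve.fluorescence, w, polyorder, deriv=1, delta=step)
    idx, props = find_peaks(negd, prominence=min_prominence)
    peaks: list[tuple[float, float]] = []
    for j, i in enumerate(idx):
        tm = float(curve.temperatures[i])
        if 0 < i < n - 1:
            y0, y1, y2 = negd[i - 1], negd[i], negd[i + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                tm += float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)) * step
        peaks.append((tm, float(props["prominences"][j])))
    peaks.sort(key=lambda p: p[0])
    return TmPeaks(curve.sample_id, curve.assay, tuple(peaks))


def logistic_sdm_cycle(template_copies: float, efficiency: float,
                       midpoint_copies: float = 8e11) -> float:
    """Analytic second-derivative-maximum position of the noiseless model.

    For the logistic amplification model the curvature maximum sits
    ``ln(2 + sqrt(3)) / ln(efficiency)`` cycles before the inflection.
    Useful as a closed-form reference for the numerical Ct caller.
    """
    if template_copies <= 0:
        raise ValueError("template_copies must be positive for an analytic Ct")
    log_e = np.log(efficiency)
    c_mid = (np.log(midpoint_copies) - np.log(template_copies)) / log_e
    return float(c_mid - np.log(2.0 + np.sqrt(3.0)) / log_e)
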