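"""Fluorescence-polarization competition analysis.

A fluorescein-labelled probe peptide bound to the SH2 domain tumbles
slowly and gives a high polarization reading; a competitor phosphopeptide
displaces it and lowers the signal.  Given the blank control ``FP_0``
(domain + probe, no competitor) and the background ``FP_b`` (probe
alone), the inhibition percentage of a sample reading ``FP`` is

    IP = 100 * (FP_0 - FP) / (FP_0 - FP_b)

IP-versus-concentration curves are fitted with a four-parameter logistic
(4PL); the IC50 is the concentration at which the *fitted* curve crosses
IP = 50.  Binding free energies are put on the usual molar scale,

    dG = R T ln(IC50 / 1 M),   R = 8.314 J/(mol K), T = 298.15 K,

reported in kJ/mol; differences dd_G = R T ln(IC50_b / IC50_a) compare
two peptides measured at the same temperature (positive = b binds more
weakly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TitrationSeries",
    "AffinityResult",
    "inhibition_percentage",
    "fit_ic50",
    "delta_g",
    "delta_delta_g",
    "DegenerateControlsError",
    "FitError",
    "ExtrapolationWarning",
]

R_GAS = 8.314  # J/(mol·K)
STANDARD_TEMPERATURE = 298.15  # K


class DegenerateControlsError(ValueError):
    pass


class FitError(RuntimeError):
    pass


class ExtrapolationWarning(UserWarning):
    """The fitted curve crosses IP = 50 outside the measured range."""


@dataclass
class TitrationSeries:
    """One peptide's competition titration plus its controls."""

    peptide: str
    concentrations: np.ndarray  # M, ascending, zero allowed
    fp_readings: np.ndarray  # mP
    fp0: float  # blank control (domain + probe)
    fpb: float  # background control (probe alone)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, float)
        self.fp_readings = np.asarray(self.fp_readings, float)
        if self.fp0 <= self.fpb:
            raise DegenerateControlsError("FP_0 must exceed FP_b")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be sorted ascending")

    @property
    def inhibition(self) -> np.ndarray:
        return inhibition_percentage(self.fp_readings, self.fp0, self.fpb)


@dataclass
class AffinityResult:
    peptide: str
    ic50: float  # M
    ic50_ci: tuple[float, float] | None  # bootstrap percentile CI, M
    hill: float
    delta_g: float  # kJ/mol
    temperature: float = STANDARD_TEMPERATURE
    fit_params: dict = field(default_factory=dict)


def inhibition_percentage(fp, fp0: float, fpb: float):
    """Inhibition percentage from sample, blank and background readings.

    Not clamped: noisy data may fall slightly outside [0, 100].
    """
    if fp0 == fpb:
        raise DegenerateControlsError("FP_0 equals FP_b: controls are degenerate")
    return 100.0 * (fp0 - np.asarray(fp, float)) / (fp0 - fpb)


def _four_pl(conc, bottom, top, log_ic50, hill):
    """4PL in concentration; evaluated safely at c = 0 (returns bottom)."""
    conc = np.asarray(conc, float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(conc > 0, (10.0**log_ic50) / np.where(conc > 0, conc, 1.0), np.inf)
        return bottom + (top - bottom) / (1.0 + ratio**hill)


def _solve_ip50(bottom, top, log_ic50, hill) -> float:
    if not (min(bottom, top) < 50.0 < max(bottom, top)):
        raise FitError("fitted curve never crosses IP = 50")
    ratio = (top - 50.0) / (50.0 - bottom)
    return float(10.0**log_ic50 * ratio ** (1.0 / hill))


def fit_ic50(
    series: TitrationSeries,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    temperature: float = STANDARD_TEMPERATURE,
    anchor_asymptotes: bool = True,
) -> AffinityResult:
    """Fit a logistic dose-response curve and locate the IC50.

    The inhibition percentage is normalized by its defining controls
    (IP = 0 with no competitor, IP = 100 at full probe displacement), so
    by default the asymptotes are anchored at 0 and 100 and only the
    midpoint and the Hill slope float — the standard normalized-response
    model, which roughly halves the IC50 noise floor on sparse grids.
    ``anchor_asymptotes=False`` frees all four parameters.

    Requires at least five distinct non-zero concentrations.  A warning
    (:class:`ExtrapolationWarning`) is raised when the measured IP values
    never straddle 50%, i.e. the IC50 is an extrapolation.  The
    confidence interval is a seeded percentile bootstrap over residuals.
    """
    conc = series.concentrations
    ip = series.inhibition
    nz = conc > 0
    if len(np.unique(conc[nz])) < 5:
        raise FitError("need at least 5 distinct non-zero concentrations")

    ip_min, ip_max = float(np.min(ip)), float(np.max(ip))
    if not (ip_min < 50.0 < ip_max):
        warnings.warn(
            "measured inhibition never crosses 50%: IC50 is extrapolated",
            ExtrapolationWarning,
            stacklevel=2,
        )

    # initial guess: midpoint crossing by interpolation
    order = np.argsort(conc[nz])
    c_nz, ip_nz = conc[nz][order], ip[nz][order]
    above = np.nonzero(ip_nz >= 50.0)[0]
    c_mid = c_nz[above[0]] if len(above) else float(np.sqrt(c_nz[0] * c_nz[-1]))
    p0 = [min(0.0, ip_min), max(100.0, ip_max), np.log10(c_mid), 1.0]

    def _fit(ip_values):
        if anchor_asymptotes:
            popt, _ = curve_fit(
                lambda c, log_ic50, hill: _four_pl(c, 0.0, 100.0, log_ic50, hill),
                conc,
                ip_values,
                p0=p0[2:],
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
                bounds=([np.log10(c_nz[0]) - 4, 0.1],
                        [np.log10(c_nz[-1]) + 4, 10.0]),
            )
            return np.array([0.0, 100.0, *popt])
        popt, _ = curve_fit(
            _four_pl,
            conc,
            ip_values,
            p0=p0,
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            bounds=([-50.0, 50.0, np.log10(c_nz[0]) - 4, 0.1],
                    [50.0, 200.0, np.log10(c_nz[-1]) + 4, 10.0]),
        )
        return popt

    try:
        popt = _fit(ip)
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, log_ic50, hill = popt
    ic50 = _solve_ip50(bottom, top, log_ic50, hill)

    ci = None
    if n_bootstrap and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        residuals = ip - _four_pl(conc, *popt)
        estimates = []
        for _ in range(n_bootstrap):
            resampled = _four_pl(conc, *popt) + rng.choice(residuals, size=len(residuals))
            try:
                b = _fit(resampled)
                estimates.append(_solve_ip50(*b))
            except (RuntimeError, FitError):
                continue
        if len(estimates) >= max(10, n_bootstrap // 10):
            ci = tuple(np.percentile(estimates, [2.5, 97.5]))

    return AffinityResult(
        peptide=series.peptide,
        ic50=ic50,
        ic50_ci=ci,
        hill=float(hill),
        delta_g=delta_g(ic50, temperature),
        temperature=temperature,
        fit_params={"bottom": float(bottom), "top": float(top),
                    "log10_ic50_param": float(log_ic50)},
    )


def delta_g(ic50: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Apparent binding free energy, kJ/mol, from an IC50 in molar units."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    return R_GAS * temperature * np.log(ic50) / 1000.0


def delta_delta_g(result_a: AffinityResult, result_b: AffinityResult) -> float:
    """ddG = dG_b - dG_a (kJ/mol); positive means b binds more weakly."""
    if abs(result_a.temperature - result_b.temperature) > 1e-9:
        raise ValueError("affinities measured at different temperatures")
    return result_b.delta_g - result_a.delta_g
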