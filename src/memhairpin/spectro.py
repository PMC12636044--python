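"""Laurdan GP, Hill binding-curve fitting, and spectrum/melt normalization.

The generalized polarization GP = (I440 − I490)/(I440 + I490) reports
lipid head-group packing from the Laurdan emission spectrum.  Apparent
binding affinity comes from fitting GP vs. protein concentration with
the Hill model GP = GP0 + ΔGP·[P]^n/(K_D^n + [P]^n), where K_D is the
apparent affinity (μM) and n an apparent cooperativity index needed for
the sigmoidal part of some curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "EmissionSpectrum",
    "BindingCurve",
    "HillFit",
    "MeltCurve",
    "compute_gp",
    "intensity_at",
    "normalize_emission",
    "hill_model",
    "fit_hill",
    "normalize_melt",
]


@dataclass
class EmissionSpectrum:
    """One emission spectrum: ascending wavelengths (nm), intensities (a.u.)."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must match")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")


def compute_gp(i440: float, i490: float) -> float:
    """GP = (I440 − I490)/(I440 + I490); bounded by [−1, 1] for positive input."""
    denom = i440 + i490
    if denom == 0:
        raise ValueError("I440 + I490 must be non-zero")
    return (i440 - i490) / denom


def intensity_at(spectrum: EmissionSpectrum, wavelength: float,
                 snap_nm: float = 1.0) -> float:
    """Intensity at a wavelength: nearest sample within ±snap_nm, else
    linear interpolation (the measurement grid is instrument-dependent)."""
    w = spectrum.wavelengths
    j = int(np.argmin(np.abs(w - wavelength)))
    if abs(w[j] - wavelength) <= snap_nm:
        return float(spectrum.intensities[j])
    if wavelength < w[0] or wavelength > w[-1]:
        raise ValueError(f"{wavelength} nm outside measured range")
    return float(np.interp(wavelength, w, spectrum.intensities))


def normalize_emission(spectra: list[EmissionSpectrum], apo: EmissionSpectrum,
                       window: tuple[float, float] = (333.0, 337.0),
                       ) -> list[EmissionSpectrum]:
    """Divide every spectrum by the mean apo intensity over the window
    (inclusive), so the apo spectrum is ≈1 near its 335 nm peak region."""
    lo, hi = window
    mask = (apo.wavelengths >= lo) & (apo.wavelengths <= hi)
    if not np.any(mask):
        raise ValueError(f"apo spectrum has no samples in [{lo}, {hi}] nm")
    ref = float(apo.intensities[mask].mean())
    if ref == 0:
        raise ValueError("apo reference intensity is zero")
    return [EmissionSpectrum(s.wavelengths, s.intensities / ref, s.label)
            for s in spectra]


@dataclass
class BindingCurve:
    """GP as a function of protein concentration (μM, strictly ascending)."""

    concentrations: np.ndarray
    gp: np.ndarray
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.gp = np.asarray(self.gp, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly ascending")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)


@dataclass
class HillFit:
    gp0: float
    delta_gp: float
    kd: float       # μM
    n: float
    se: dict = field(default_factory=dict)
    rss: float = np.nan
    converged: bool = True
    low_confidence: bool = False
    notes: str = ""


def hill_model(c, gp0, delta_gp, kd, n):
    c = np.asarray(c, dtype=float)
    return gp0 + delta_gp * c**n / (kd**n + c**n)


_N_BOUNDS = (0.25, 8.0)


def fit_hill(curve: BindingCurve, fix_n: float | None = None,
             weighted: bool = False) -> HillFit:
    """Nonlinear least-squares Hill fit of a GP binding curve.

    Initialisation: GP0 = GP at the lowest concentration, ΔGP = signed GP
    range, K_D = geometric-median concentration, n = 1.  ``fix_n`` pins
    the cooperativity; ``weighted`` uses the replicate errors as sigma.
    Non-convergence and poorly constrained curves are flagged on the
    result, never raised.
    """
    c, gp = curve.concentrations, curve.gp
    notes = []
    low_conf = c.size < 5
    if low_conf:
        notes.append("fewer than 5 points")
    gp0_init = float(gp[0])
    dgp_init = float(gp[-1] - gp[0])
    if dgp_init == 0.0:
        dgp_init = 1e-6
    kd_init = float(np.exp(np.median(np.log(c))))

    if fix_n is None:
        def model(cc, gp0, dgp, kd, n):
            return hill_model(cc, gp0, dgp, kd, n)
        p0 = [gp0_init, dgp_init, kd_init, 1.0]
        lower = [-np.inf, -np.inf, 1e-12, _N_BOUNDS[0]]
        upper = [np.inf, np.inf, np.inf, _N_BOUNDS[1]]
        names = ["gp0", "delta_gp", "kd", "n"]
    else:
        def model(cc, gp0, dgp, kd):
            return hill_model(cc, gp0, dgp, kd, fix_n)
        p0 = [gp0_init, dgp_init, kd_init]
        lower = [-np.inf, -np.inf, 1e-12]
        upper = [np.inf, np.inf, np.inf]
        names = ["gp0", "delta_gp", "kd"]

    sigma = curve.errors if (weighted and curve.errors is not None) else None
    try:
        import warnings as _warnings

        from scipy.optimize import OptimizeWarning

        with _warnings.catch_warnings():
            # unresolvable covariance is reported via the low-confidence flag
            _warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(model, c, gp, p0=p0, bounds=(lower, upper),
                                   sigma=sigma, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((len(p0), len(p0)), np.nan)
        converged = False
        notes.append("optimizer did not converge")

    se = {k: float(np.sqrt(pcov[i, i])) if np.isfinite(pcov[i, i]) else np.nan
          for i, k in enumerate(names)}
    params = dict(zip(names, (float(v) for v in popt)))
    n_val = fix_n if fix_n is not None else params["n"]
    rss = float(np.sum((gp - model(c, *popt)) ** 2))

    # a fit is only informative when the curve spans the half-saturation
    # region and the amplitude is resolved
    gp_span = float(np.ptp(gp))
    if abs(params["delta_gp"]) < 1e-8 or gp_span < 1e-12:
        low_conf = True
        notes.append("no resolvable amplitude; K_D unidentifiable")
    elif not (c[0] < params["kd"] < c[-1]):
        low_conf = True
        notes.append("K_D outside the measured concentration range")
    if se.get("kd") is not np.nan and np.isfinite(se.get("kd", np.nan)):
        if params["kd"] > 0 and se["kd"] / params["kd"] > 1.0:
            low_conf = True
            notes.append("K_D relative standard error above 100%")

    return HillFit(gp0=params["gp0"], delta_gp=params["delta_gp"],
                   kd=params["kd"], n=float(n_val), se=se, rss=rss,
                   converged=converged,
                   low_confidence=low_conf or not converged,
                   notes="; ".join(notes))


@dataclass
class MeltCurve:
    """Thermal melt followed by ellipticity at 222 nm."""

    temperatures: np.ndarray  # °C, ascending
    ellipticity: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly ascending")


def normalize_melt(curve: MeltCurve, t_low: float = 20.0,
                   t_high: float = 96.0) -> MeltCurve:
    """Affine-normalize a melt so ellipticity(t_low) → −1 and
    ellipticity(t_high) → 0 (anchor values taken at the nearest
    measured temperatures)."""
    t = curve.temperatures
    if t_low < t[0] or t_high > t[-1]:
        raise ValueError("anchor temperatures outside the measured range")
    e_low = curve.ellipticity[int(np.argmin(np.abs(t - t_low)))]
    e_high = curve.ellipticity[int(np.argmin(np.abs(t - t_high)))]
    if e_low == e_high:
        raise ValueError("equal anchor ellipticities; normalization undefined")
    norm = (curve.ellipticity - e_high) / (e_high - e_low)
    return MeltCurve(temperatures=t.copy(), ellipticity=norm)
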