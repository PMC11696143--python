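"""Equilibrium binding models: EMSA Hill fits, one-site ITC, FRET efficiency.

EMSA titrations are summarized as fraction bound,
``bound / (bound + unbound)`` band intensity, and fit by nonlinear least
squares to a specific-binding model with a Hill slope,

    f(c) = Bmax * c**h / (Kd**h + c**h),

reporting an apparent dissociation constant ``Kd`` (nM), Hill slope ``h``
and amplitude ``Bmax``.

ITC titrations follow the classic one-set-of-sites (Wiseman) isotherm with
the perfusion-cell displacement correction.  After injection ``i`` of volume
``v`` into a cell of volume ``V0`` containing macromolecule at initial
concentration ``M0``, with titrant at syringe concentration ``Xs``:

    M_i = M0 * (1 - i*v/(2*V0)) / (1 + i*v/(2*V0))
    X_i = Xs * (i*v/V0)         / (1 + i*v/(2*V0))

bound titrant solves the one-site quadratic

    [MX]_i = ((N*M_i + X_i + Kd) - sqrt((N*M_i + X_i + Kd)**2
              - 4*N*M_i*X_i)) / 2,

cumulative heat is ``Q_i = [MX]_i * dH * V0`` and the measured per-injection
heat, corrected for liquid displaced into the overflow, is

    dQ_i = Q_i - Q_{i-1} + (v/V0) * (Q_i + Q_{i-1}) / 2,

normalized per mole of injectant.  Fitting returns the stoichiometry ``N``
(sites), ``Kd`` (µM) and enthalpy ``dH`` (kJ/mol), with derived
``dG = R*T*ln(Kd)`` (Kd in molar) and ``-T*dS = dG - dH``.  A two-site model
is deliberately not offered: uniphasic isotherms do not constrain one.

Relative FRET efficiency is the acceptor fraction of total emission,
``I_668 / (I_668 + I_564)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GAS_CONSTANT_KJ",
    "TitrationSeries",
    "HillFit",
    "ITCExperiment",
    "OneSiteParams",
    "fraction_bound",
    "hill_model",
    "fit_hill",
    "default_dilution_series",
    "simulate_one_site_itc",
    "fit_one_site_itc",
    "fret_efficiency",
]

#: Gas constant in kJ/(mol*K).
GAS_CONSTANT_KJ = 8.314462618e-3


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or inputs cannot constrain it."""


# ---------------------------------------------------------------------------
# EMSA


def default_dilution_series(top_nM: float = 5000.0, n_points: int = 12, step: float = 2.0) -> np.ndarray:
    """Protein concentration grid for an EMSA: 2-fold dilutions from 5 µM, ascending."""
    conc = top_nM / step ** np.arange(n_points - 1, -1, -1)
    return conc


@dataclass(frozen=True)
class TitrationSeries:
    """Protein concentrations (nM, strictly increasing) with fraction bound."""

    concentrations: np.ndarray
    fraction_bound: np.ndarray
    rna_label: str = ""

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        frac = np.asarray(self.fraction_bound, dtype=float)
        if conc.shape != frac.shape:
            raise ValueError("concentrations and fraction_bound differ in length")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any((frac < 0) | (frac > 1)):
            raise ValueError("fraction_bound values must lie in [0, 1]")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "fraction_bound", frac)


@dataclass(frozen=True)
class HillFit:
    kd_app: float  # nM
    hill: float
    bmax: float
    fit_errors: dict[str, float] = field(default_factory=dict)


def fraction_bound(bound: float, unbound: float) -> float:
    """Fraction of RNA in the shifted band: bound / (bound + unbound)."""
    if bound < 0 or unbound < 0:
        raise ValueError("band intensities must be non-negative")
    total = bound + unbound
    if total == 0:
        raise ValueError("undefined lane: both band intensities are zero")
    return bound / total


def hill_model(conc, kd: float, h: float, bmax: float):
    """Specific binding with a Hill slope: bmax * c**h / (kd**h + c**h)."""
    if kd <= 0 or h <= 0:
        raise ValueError("kd and h must be positive")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        ch = np.where(c > 0, c**h, 0.0)
    out = bmax * ch / (kd**h + ch)
    return out if out.ndim else float(out)


def _init_hill(conc: np.ndarray, frac: np.ndarray) -> tuple[float, float, float]:
    bmax0 = max(float(frac.max()), 1e-3)
    half = bmax0 / 2
    # first crossing of half-max, linearly interpolated in log-concentration
    above = np.nonzero(frac >= half)[0]
    if len(above) == 0 or above[0] == 0:
        kd0 = float(np.sqrt(conc[0] * conc[-1]))
    else:
        j = above[0]
        x0, x1 = np.log(conc[j - 1]), np.log(conc[j])
        y0, y1 = frac[j - 1], frac[j]
        w = 0.5 if y1 == y0 else (half - y0) / (y1 - y0)
        kd0 = float(np.exp(x0 + w * (x1 - x0)))
    return kd0, 1.0, bmax0


def fit_hill(series: TitrationSeries) -> HillFit:
    """Least-squares Hill fit of an EMSA titration.

    Parameters are bounded (kd > 0, h in (0.2, 5), bmax in (0, 1.2)) and
    initialized from the half-maximum crossing, which keeps the fit stable
    on noisy gel quantitations.  Asymptotic standard errors come from the
    covariance of the least-squares solution.
    """
    conc = series.concentrations
    frac = series.fraction_bound
    if len(conc) < 5:
        raise ValueError("need at least 5 titration points")
    if np.all(frac == 0):
        raise FitError("all fraction-bound values are zero; nothing to fit")

    p0 = _init_hill(conc, frac)
    bounds = ([1e-6, 0.2, 1e-6], [np.inf, 5.0, 1.2])
    p0 = tuple(np.clip(p0, bounds[0], bounds[1]))
    try:
        popt, pcov = curve_fit(
            hill_model,
            conc,
            frac,
            p0=p0,
            bounds=bounds,
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as exc:  # pragma: no cover - convergence failure path
        raise FitError(f"Hill fit did not converge: {exc}") from exc

    perr = np.sqrt(np.diag(pcov))
    return HillFit(
        kd_app=float(popt[0]),
        hill=float(popt[1]),
        bmax=float(popt[2]),
        fit_errors={"kd_app": float(perr[0]), "hill": float(perr[1]), "bmax": float(perr[2])},
    )


# ---------------------------------------------------------------------------
# ITC


@dataclass(frozen=True)
class ITCExperiment:
    """Geometry and (optionally) measured heats of one ITC titration.

    Concentrations are µM, volumes µL, temperature K; ``heats`` are
    per-injection heats normalized per mole of injectant (kJ/mol).
    """

    cell_conc: float
    syringe_conc: float
    cell_volume: float = 200.0
    injection_volume: float = 2.0
    n_injections: int = 19
    temperature: float = 293.15
    heats: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("cell_conc", "syringe_conc", "cell_volume", "injection_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.heats is not None:
            h = np.asarray(self.heats, dtype=float)
            if len(h) != self.n_injections:
                raise ValueError("heats length must equal n_injections")
            object.__setattr__(self, "heats", h)

    def molar_ratios(self) -> np.ndarray:
        """Titrant:macromolecule molar ratio in the cell after each injection."""
        i = np.arange(1, self.n_injections + 1)
        v, V0 = self.injection_volume, self.cell_volume
        f = i * v / (2 * V0)
        M = self.cell_conc * (1 - f) / (1 + f)
        X = self.syringe_conc * (i * v / V0) / (1 + f)
        return X / M


@dataclass(frozen=True)
class OneSiteParams:
    """One-set-of-sites parameters with derived free-energy terms.

    ``N`` is the fitted number of sites per macromolecule: N = 0.5 means one
    titrant molecule bridges two macromolecules (1:2 stoichiometry).
    """

    N: float
    kd_app: float  # µM
    dH: float  # kJ/mol
    temperature: float = 293.15
    fit_errors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.N <= 0 or self.kd_app <= 0:
            raise ValueError("N and kd_app must be positive")

    @property
    def dG(self) -> float:
        """Binding free energy RT*ln(Kd), Kd in molar; kJ/mol."""
        return GAS_CONSTANT_KJ * self.temperature * np.log(self.kd_app * 1e-6)

    @property
    def minus_TdS(self) -> float:
        """Entropic term -T*dS = dG - dH; kJ/mol."""
        return self.dG - self.dH


def _one_site_heats(
    n_inj: int,
    M0_uM: float,
    Xs_uM: float,
    V0_uL: float,
    v_uL: float,
    N: float,
    kd_uM: float,
    dH: float,
) -> np.ndarray:
    """Per-injection heats (kJ/mol injectant) of the one-site isotherm."""
    M0, Xs, Kd = M0_uM * 1e-6, Xs_uM * 1e-6, kd_uM * 1e-6
    V0, v = V0_uL * 1e-6, v_uL * 1e-6  # liters
    i = np.arange(1, n_inj + 1)
    f = i * v / (2 * V0)
    M = M0 * (1 - f) / (1 + f)
    X = Xs * (i * v / V0) / (1 + f)
    b = N * M + X + Kd
    disc = b * b - 4 * N * M * X
    if np.any(disc < 0):
        raise ArithmeticError("one-site quadratic has negative discriminant")
    MX = (b - np.sqrt(disc)) / 2
    Q = MX * dH * V0  # kJ
    Qprev = np.concatenate(([0.0], Q[:-1]))
    dQ = Q - Qprev + (v / V0) * (Q + Qprev) / 2
    return dQ / (Xs * v)  # kJ per mole injected


def simulate_one_site_itc(params: OneSiteParams, exp: ITCExperiment) -> np.ndarray:
    """Noise-free per-injection heats for a one-set-of-sites titration."""
    return _one_site_heats(
        exp.n_injections,
        exp.cell_conc,
        exp.syringe_conc,
        exp.cell_volume,
        exp.injection_volume,
        params.N,
        params.kd_app,
        params.dH,
    )


def fit_one_site_itc(exp: ITCExperiment) -> OneSiteParams:
    """Fit (N, Kd, dH) of the one-set-of-sites model to measured heats.

    Initial guesses: dH from the first-injection heat, N from the molar
    ratio at the half-enthalpy crossing, Kd from 1 µM.  Emits a warning when
    the Wiseman c-value (N * [M] / Kd) is below ~1, where the sigmoid is too
    shallow to constrain N well.
    """
    if exp.heats is None:
        raise ValueError("experiment carries no measured heats")
    if exp.n_injections < 5:
        raise ValueError("need at least 5 injections")
    heats = np.asarray(exp.heats, dtype=float)
    ratios = exp.molar_ratios()

    dH0 = float(heats[0])
    if dH0 == 0.0:
        dH0 = float(heats[np.argmax(np.abs(heats))]) or -1.0
    half_idx = int(np.argmin(np.abs(heats - dH0 / 2)))
    N0 = float(np.clip(ratios[half_idx], 0.05, 10.0))
    p0 = (N0, 1.0, dH0)

    def model(i, N, kd, dH):
        return _one_site_heats(
            exp.n_injections,
            exp.cell_conc,
            exp.syringe_conc,
            exp.cell_volume,
            exp.injection_volume,
            N,
            kd,
            dH,
        )

    x = np.arange(exp.n_injections)
    try:
        popt, pcov = curve_fit(
            model,
            x,
            heats,
            p0=p0,
            bounds=([1e-3, 1e-5, -1e5], [50.0, 1e5, 1e5]),
            maxfev=40000,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"one-site ITC fit did not converge: {exc}") from exc

    N, kd, dH = map(float, popt)
    c_value = N * exp.cell_conc / kd
    if c_value < 1:
        warnings.warn(
            f"Wiseman c-value {c_value:.2g} < 1: stoichiometry N poorly constrained",
            RuntimeWarning,
            stacklevel=2,
        )
    perr = np.sqrt(np.diag(pcov))
    return OneSiteParams(
        N=N,
        kd_app=kd,
        dH=dH,
        temperature=exp.temperature,
        fit_errors={"N": float(perr[0]), "kd_app": float(perr[1]), "dH": float(perr[2])},
    )


# ---------------------------------------------------------------------------
# FRET


def fret_efficiency(i_668: float, i_564: float) -> float:
    """Relative FRET efficiency: acceptor emission over total, I668/(I668+I564)."""
    if i_668 < 0 or i_564 < 0:
        raise ValueError("intensities must be non-negative")
    total = i_668 + i_564
    if total == 0:
        raise ValueError("both emission intensities are zero")
    return i_668 / total
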