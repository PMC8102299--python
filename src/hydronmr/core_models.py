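"""Pure model functions for gravimetric sorption and 1H-NMR hydration analysis.

Every function here is side-effect free and vectorised over its abscissa
argument; the estimation and simulation layers both evaluate these and
nothing else, so the two routes can never drift apart.

Units are enforced by convention at the type boundary: kinetics times in
hours, FID times in microseconds, spectral frequencies in Hz (offsets from
the carrier), and all masses as dimensionless ratios to the dry mass m0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import PROTON_GYROMAGNETIC_RATIO

__all__ = [
    "KineticsParams",
    "IsothermParams",
    "ParabolicCoeffs",
    "FIDComponents",
    "SpectralComponents",
    "SoluteModelParams",
    "eval_kinetics",
    "total_hydration",
    "eval_isotherm",
    "gab_to_parabola",
    "parabola_to_gab",
    "eval_fid",
    "apparent_t2",
    "eval_spectrum",
    "ls_ratio",
    "l1_fraction",
    "dissolved_solid_mass",
]


class ModelDomainError(ValueError):
    """An abscissa value lies outside the validity domain of a model."""


class ModelConfigError(ValueError):
    """A parameter bundle is internally inconsistent for the requested use."""


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsParams:
    """Exponential sorption-kinetics parameters.

    For hydration the model is an approach to saturation with one or two
    components on top of the residual offset ``A0`` (the hydration level
    retained over silica gel); for dehydration it is a single decaying
    exponential from ``A0 + Ad`` down to ``A0``.

    Attributes
    ----------
    A0 : hydration offset (very tightly bound water), units of dry mass.
    A1, t1 : amplitude and time constant (hours) of the tightly bound pool.
    A2, t2 : amplitude and time constant of the loosely bound pool; ``None``
        for the one-component model.
    direction : ``"hydration"`` or ``"dehydration"``.
    Ad, td : dehydration amplitude and time constant (hours); only used when
        ``direction == "dehydration"``.
    """

    A0: float = 0.0
    A1: Optional[float] = None
    t1: Optional[float] = None
    A2: Optional[float] = None
    t2: Optional[float] = None
    direction: str = "hydration"
    Ad: Optional[float] = None
    td: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in ("hydration", "dehydration"):
            raise ModelConfigError(f"unknown direction {self.direction!r}")
        if self.direction == "hydration":
            if self.A1 is None or self.t1 is None:
                raise ModelConfigError("hydration requires A1 and t1")
            if (self.A2 is None) != (self.t2 is None):
                raise ModelConfigError("A2 and t2 must be supplied together")
        else:
            if self.Ad is None or self.td is None:
                raise ModelConfigError("dehydration requires Ad and td")
        for name in ("A0", "A1", "A2", "Ad"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ModelConfigError(f"{name} must be >= 0, got {v}")
        for name in ("t1", "t2", "td"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ModelConfigError(f"{name} must be > 0, got {v}")

    @property
    def order(self) -> int:
        """Number of exponential components (1 or 2)."""
        if self.direction == "dehydration":
            return 1
        return 1 if self.A2 is None else 2


@dataclass(frozen=True)
class IsothermParams:
    """Multilayer sorption-isotherm parameters (Dent/GAB family).

    ``b`` is the occupancy ratio of n-fold to (n-1)-fold covered secondary
    sites at unit water activity; ``b = 1`` is exactly the classical BET
    model.  ``1/b1`` measures the fraction of primary binding sites still
    empty at h = 1 and is an index of surface hydrophobicity.
    """

    dM_over_m0: float
    b: float
    b1: float
    model_tag: str = "GAB"

    def __post_init__(self) -> None:
        if self.dM_over_m0 <= 0:
            raise ModelConfigError("dM_over_m0 must be > 0")
        if not (0 < self.b <= 1):
            raise ModelConfigError(f"b must lie in (0, 1], got {self.b}")
        if self.b1 <= 0:
            raise ModelConfigError("b1 must be > 0")
        if self.model_tag not in ("GAB", "BET"):
            raise ModelConfigError(f"unknown model_tag {self.model_tag!r}")
        if self.model_tag == "BET" and not math.isclose(self.b, 1.0):
            raise ModelConfigError("BET requires b == 1")


@dataclass(frozen=True)
class ParabolicCoeffs:
    """Coefficients of the linearised isotherm h/(dm/m0) = A + B h - C h^2."""

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ModelConfigError("A must be > 0")

    def evaluate(self, h):
        h = np.asarray(h, dtype=float)
        return self.A + self.B * h - self.C * h * h


@dataclass(frozen=True)
class FIDComponents:
    """Amplitudes and decay times of a multi-component free induction decay.

    One Gaussian solid component plus one or two exponential liquid
    components.  ``abragam_freq`` (rad/us), when set, multiplies the solid
    Gaussian by sin(a t)/(a t) — the beat-pattern variant; it is off by
    default because it is rarely needed for spectra without a visible beat.
    """

    S: float
    T2S_star: float
    L1: float
    T2L1_star: float
    L2: Optional[float] = None
    T2L2_star: Optional[float] = None
    abragam_freq: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.S, self.L1) < 0 or (self.L2 is not None and self.L2 < 0):
            raise ModelConfigError("amplitudes must be >= 0")
        if self.T2S_star <= 0 or self.T2L1_star <= 0:
            raise ModelConfigError("decay times must be > 0")
        if (self.L2 is None) != (self.T2L2_star is None):
            raise ModelConfigError("L2 and T2L2_star must be supplied together")
        if self.T2L2_star is not None and self.T2L2_star <= 0:
            raise ModelConfigError("decay times must be > 0")
        times = [self.T2S_star, self.T2L1_star]
        if self.T2L2_star is not None:
            times.append(self.T2L2_star)
        if any(a >= b for a, b in zip(times, times[1:])):
            raise ModelConfigError(
                "require T2S* < T2L1* < T2L2* (solid decays fastest)"
            )

    @property
    def total_amplitude(self) -> float:
        return self.S + self.L1 + (self.L2 or 0.0)


@dataclass(frozen=True)
class SpectralComponents:
    """One Gaussian (solid) line plus one or two Lorentzian (mobile) lines.

    Peak positions are offset frequencies in Hz relative to the carrier;
    half-widths are FWHM in Hz.  ``A_G`` is the Gaussian weight parameter as
    fitted (its analytic area is ``A_G / ln 4``); each Lorentzian is
    parameterised so that ``A_Li`` is exactly its analytic area.  When two
    Lorentzians are present the broader one (tightly bound water) is L1.
    """

    A_G: float
    nu_G: float
    dnu_G: float
    A_L1: float
    nu_L1: float
    dnu_L1: float
    A_L2: Optional[float] = None
    nu_L2: Optional[float] = None
    dnu_L2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.A_G < 0 or self.A_L1 < 0:
            raise ModelConfigError("weights/areas must be >= 0")
        if self.dnu_G <= 0 or self.dnu_L1 <= 0:
            raise ModelConfigError("half-widths must be > 0")
        second = (self.A_L2, self.nu_L2, self.dnu_L2)
        if any(v is None for v in second) != all(v is None for v in second):
            raise ModelConfigError("A_L2, nu_L2, dnu_L2 must come together")
        if self.dnu_L2 is not None:
            if self.dnu_L2 <= 0:
                raise ModelConfigError("half-widths must be > 0")
            if self.A_L2 < 0:
                raise ModelConfigError("weights/areas must be >= 0")
            if not self.dnu_L1 > self.dnu_L2:
                raise ModelConfigError("L1 must be the broader Lorentzian")

    @property
    def n_lorentzians(self) -> int:
        return 1 if self.A_L2 is None else 2

    @property
    def gaussian_analytic_area(self) -> float:
        """Area under the Gaussian term, ``A_G / ln 4``."""
        return self.A_G / math.log(4.0)

    def ratio_table(self) -> dict:
        """Mobile/solid parameter ratios as conventionally tabulated."""
        out = {"AL1_over_S": self.A_L1 / self.A_G}
        if self.A_L2 is not None:
            out["AL2_over_S"] = self.A_L2 / self.A_G
        out["AL_over_S"] = sum(
            v for k, v in out.items() if k != "AL_over_S"
        )
        return out


@dataclass(frozen=True)
class SoluteModelParams:
    """Parameters of the water-soluble solid-fraction dissolution model.

    ``cs`` is the saturation concentration of the soluble fraction (mass
    fraction of the saturated solution), ``gamma`` and ``delta`` the proton
    densities of solute and solid matrix in units of the water proton
    density, ``k`` the liquid/solid slope that would be seen with no soluble
    fraction, and ``m1`` the water mass saturating the tightly bound pool.

    ``alpha_cd_over_s`` / ``alpha_cu_over_s`` opt into the general form in
    which the dissolved and undissolved solute contribute to the NMR signal
    with their own effective coefficients; by default the specialisation
    (alpha_cd/alpha_s ~ k, alpha_cu/alpha_s ~ 1) is evaluated.
    """

    cs: float
    gamma: float
    delta: float
    k: float
    m1: float
    alpha_cd_over_s: Optional[float] = None
    alpha_cu_over_s: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.cs < 1):
            raise ModelConfigError(f"cs must lie in [0, 1), got {self.cs}")
        for name in ("gamma", "delta", "k", "m1"):
            if getattr(self, name) <= 0:
                raise ModelConfigError(f"{name} must be > 0")
        if (self.alpha_cd_over_s is None) != (self.alpha_cu_over_s is None):
            raise ModelConfigError("both alpha ratios required for general form")

    @property
    def solute_load(self) -> float:
        """cs/(1-cs): dissolved solute mass per unit water mass."""
        return self.cs / (1.0 - self.cs)

    def valid_dm_max(self) -> float:
        """Largest hydration level before the L/S denominator vanishes."""
        if self.alpha_cd_over_s is not None:
            g = self.alpha_cu_over_s * (self.gamma / self.delta) * self.solute_load
        else:
            g = (self.gamma / self.delta) * self.solute_load
        return math.inf if g <= 0 else 1.0 / g


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def eval_kinetics(params: KineticsParams, t):
    """Relative mass gain dm/m0 at time ``t`` (hours).

    Hydration: ``A0 + sum_i Ai (1 - exp(-t/ti))``.
    Dehydration: ``A0 + Ad exp(-t/td)``, i.e. decay from ``A0 + Ad`` toward
    the residual ``A0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ModelDomainError("time must be >= 0")
    if params.direction == "hydration":
        out = params.A0 + params.A1 * -np.expm1(-t / params.t1)
        if params.A2 is not None:
            out = out + params.A2 * -np.expm1(-t / params.t2)
    else:
        out = params.A0 + params.Ad * np.exp(-t / params.td)
    return out if out.ndim else float(out)


def total_hydration(params: KineticsParams) -> float:
    """Saturation hydration level C^h = A0 + A1 + A2 (sum of all pools)."""
    if params.direction != "hydration":
        raise ModelConfigError("total hydration is defined for hydration params")
    return params.A0 + params.A1 + (params.A2 or 0.0)


def eval_isotherm(params: IsothermParams, h):
    """Equilibrium hydration level at water activity ``h``.

    dm/m0 = (dM/m0) b1 h / [(1 - b h)(1 + b1 h - b h)]; the BET model is
    the ``b = 1`` member of the family.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ModelDomainError("relative humidity must be >= 0")
    if np.any(params.b * h >= 1.0):
        raise ModelDomainError(
            f"h must stay below the 1/b = {1.0 / params.b:.4g} singularity"
        )
    num = params.dM_over_m0 * params.b1 * h
    den = (1.0 - params.b * h) * (1.0 + params.b1 * h - params.b * h)
    out = num / den
    return out if out.ndim else float(out)


def gab_to_parabola(params: IsothermParams) -> ParabolicCoeffs:
    """Exact parabolic (linearised) coefficients of the isotherm.

    Expanding h / (dm/m0) = (1 - b h)(1 + b1 h - b h) / ((dM/m0) b1) gives
    A = 1/((dM/m0) b1), B = (b1 - 2b) A, C = b (b1 - b) A.
    """
    A = 1.0 / (params.dM_over_m0 * params.b1)
    B = (params.b1 - 2.0 * params.b) * A
    C = params.b * (params.b1 - params.b) * A
    return ParabolicCoeffs(A=A, B=B, C=C)


def parabola_to_gab(coeffs: ParabolicCoeffs, model_tag: str = "GAB") -> IsothermParams:
    """Invert parabolic coefficients back to isotherm parameters.

    b  = (sqrt(B^2 + 4 A C) - B) / (2 A)
    b1 = B/A + 2 b
    dM/m0 = 1 / (A b1)
    """
    disc = coeffs.B * coeffs.B + 4.0 * coeffs.A * coeffs.C
    if disc < 0:
        raise ModelDomainError("negative discriminant: no real isotherm parameters")
    b = (math.sqrt(disc) - coeffs.B) / (2.0 * coeffs.A)
    if 1.0 < b < 1.0 + 1e-9:  # round-off guard at the BET boundary
        b = 1.0
    b1 = coeffs.B / coeffs.A + 2.0 * b
    dM = 1.0 / (coeffs.A * b1)
    return IsothermParams(dM_over_m0=dM, b=b, b1=b1, model_tag=model_tag)


def eval_fid(components: FIDComponents, t):
    """Free-induction-decay amplitude at time ``t`` (microseconds)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ModelDomainError("time must be >= 0")
    solid = components.S * np.exp(-((t / components.T2S_star) ** 2))
    if components.abragam_freq is not None:
        # np.sinc(x) = sin(pi x)/(pi x); handles t = 0 exactly.
        solid = solid * np.sinc(components.abragam_freq * t / np.pi)
    out = solid + components.L1 * np.exp(-t / components.T2L1_star)
    if components.L2 is not None:
        out = out + components.L2 * np.exp(-t / components.T2L2_star)
    return out if out.ndim else float(out)


def apparent_t2(T2: float, dB0: float) -> float:
    """Effective spin-spin time T2* (us) under field inhomogeneity dB0 (T).

    1/T2* = 1/T2 + gamma dB0 / 2 with the proton gyromagnetic ratio; the
    input/output times are in microseconds.
    """
    if T2 <= 0:
        raise ModelDomainError("T2 must be > 0")
    if dB0 < 0:
        raise ModelDomainError("dB0 must be >= 0")
    rate = 1e6 / T2 + PROTON_GYROMAGNETIC_RATIO * dB0 / 2.0  # s^-1
    return 1e6 / rate


def eval_spectrum(components: SpectralComponents, nu):
    """Spectral amplitude at offset frequency ``nu`` (Hz).

    Gaussian term: A_G/(dnu_G sqrt(ln4 pi/2)) exp[-2 ln4 ((nu-nu_G)/dnu_G)^2];
    each Lorentzian term (2 A_L/pi) dnu_L / (4 (nu-nu_L)^2 + dnu_L^2)
    integrates analytically to A_L.
    """
    nu = np.asarray(nu, dtype=float)
    ln4 = math.log(4.0)
    g_height = components.A_G / (components.dnu_G * math.sqrt(ln4 * math.pi / 2.0))
    out = g_height * np.exp(
        -2.0 * ln4 * ((nu - components.nu_G) / components.dnu_G) ** 2
    )
    out = out + _lorentzian(nu, components.A_L1, components.nu_L1, components.dnu_L1)
    if components.A_L2 is not None:
        out = out + _lorentzian(
            nu, components.A_L2, components.nu_L2, components.dnu_L2
        )
    return out if out.ndim else float(out)


def _lorentzian(nu, area, center, fwhm):
    return (2.0 * area / math.pi) * fwhm / (4.0 * (nu - center) ** 2 + fwhm * fwhm)


def ls_ratio(params: SoluteModelParams, dm):
    """Mobile-to-solid signal ratio L/S at hydration level ``dm``.

    Rational in dm because the dissolving solid fraction both adds mobile
    signal and removes solid signal:

        L/S = (k + g) dm / (1 - g dm),  g = (gamma/delta) cs/(1-cs)

    With the optional alpha ratios the general form is evaluated instead,
    with g_num = (alpha_cd/alpha_s)(gamma/delta) cs/(1-cs) in the numerator
    and g_den built from alpha_cu/alpha_s in the denominator.  At cs = 0
    both reduce exactly to the linear law k dm.
    """
    dm = np.asarray(dm, dtype=float)
    if np.any(dm < 0):
        raise ModelDomainError("hydration level must be >= 0")
    rho_ratio = (params.gamma / params.delta) * params.solute_load
    if params.alpha_cd_over_s is not None:
        g_num = params.alpha_cd_over_s * rho_ratio
        g_den = params.alpha_cu_over_s * rho_ratio
    else:
        g_num = rho_ratio
        g_den = rho_ratio
    den = 1.0 - g_den * dm
    if np.any(den <= 0):
        raise ModelDomainError(
            "hydration level beyond model validity (denominator <= 0)"
        )
    out = (params.k + g_num) * dm / den
    return out if out.ndim else float(out)


def l1_fraction(params: SoluteModelParams, dm):
    """Less-mobile liquid fraction L1/L at hydration level ``dm``.

    Equals 1 while only the tightly bound pool (mass m1) is filling; beyond
    that the loosely bound pool grows as dm2 = dm - m1 and also carries the
    dissolved solute signal:

        L1/L = m1 / (m1 + (1 + gamma cs/(1-cs)) dm2)
    """
    dm = np.asarray(dm, dtype=float)
    if np.any(dm < 0):
        raise ModelDomainError("hydration level must be >= 0")
    dm2 = np.clip(dm - params.m1, 0.0, None)
    out = params.m1 / (
        params.m1 + (1.0 + params.gamma * params.solute_load) * dm2
    )
    return out if out.ndim else float(out)


def dissolved_solid_mass(cs: float, dm):
    """Mass of dissolved soluble solid, m_cd = (cs/(1-cs)) dm."""
    if not (0 <= cs < 1):
        raise ModelDomainError(f"cs must lie in [0, 1), got {cs}")
    dm = np.asarray(dm, dtype=float)
    if np.any(dm < 0):
        raise ModelDomainError("hydration level must be >= 0")
    out = (cs / (1.0 - cs)) * dm
    return out if out.ndim else float(out)
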