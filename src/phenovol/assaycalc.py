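"""Colorimetric assay quantification and unit conversions.

Converts raw spectrophotometer readings into tissue-level quantities the way
a postharvest-physiology lab reports them: analyte standard curves (nitrate
against KNO3, sucrose/total sugars against sucrose/glucose, total phenolics
as gallic-acid equivalents, flavonoids as rutin equivalents, antioxidant
capacity as ascorbic-acid equivalents), the Lichtenthaler pigment equations
for 100% methanol extracts, phenylalanine ammonia-lyase (PAL) activity units,
and static-headspace ethylene emission rates.

All quantification paths are linear, so each is the exact inverse of the
synthetic reading generator at zero read noise — a property the test suite
exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import CurveQualityError, InvalidInputError


__all__ = [
    "StandardCurve",
    "AssayReading",
    "FluorescenceRecord",
    "AssaySpec",
    "DEFAULT_ASSAYS",
    "fit_standard_curve",
    "quantify",
    "absorbance_for",
    "lichtenthaler_pigments",
    "PalActivity",
    "pal_activity",
    "ethylene_rate",
]


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear response of absorbance on standard concentration."""

    analyte: str
    points: tuple  # ((concentration, absorbance), ...)
    slope: float
    intercept: float
    r2: float
    valid_range: tuple  # (min conc, max conc) spanned by the standards

    def concentration(self, absorbance_corrected: float) -> float:
        """Invert the curve: concentration for a blank-corrected absorbance."""
        return (absorbance_corrected - self.intercept) / self.slope

    def response(self, concentration: float) -> float:
        """Forward prediction: absorbance expected for a concentration."""
        return self.intercept + self.slope * concentration


@dataclass(frozen=True)
class AssayReading:
    """One raw optical reading plus the extraction bookkeeping.

    ``absorbances`` maps wavelength (nm) to the measured value; single-
    wavelength assays use one entry. ``dilution`` is the fold-dilution of the
    extract before reading (1 = undiluted).
    """

    assay: str
    absorbances: Mapping[float, float]
    blank: float = 0.0
    tissue_mass: float = 1.0       # g FW extracted
    extract_volume: float = 1.0    # mL of extract
    aliquot_volume: float = 0.0    # mL read (informational)
    dilution: float = 1.0
    reaction_time: float = 0.0     # min, for kinetic assays
    protein_conc: float = 0.0      # mg/mL, PAL specific activity only

    def __post_init__(self):
        if self.tissue_mass <= 0 or self.extract_volume <= 0 or self.dilution <= 0:
            raise InvalidInputError("tissue mass, extract volume and dilution must be > 0")

    @property
    def absorbance(self) -> float:
        """The single absorbance for one-wavelength assays."""
        if len(self.absorbances) != 1:
            raise InvalidInputError(
                f"assay '{self.assay}' has {len(self.absorbances)} wavelengths; "
                "specify which one to quantify"
            )
        return next(iter(self.absorbances.values()))


@dataclass(frozen=True)
class FluorescenceRecord:
    """Instrument-computed chlorophyll-a fluorescence parameters.

    Carried as data: Fv/Fm (maximum quantum efficiency of PSII), the
    performance index (PI), active reaction centres per cross-section
    (RC/CS) and energy dissipated per reaction centre (DIo/RC).
    """

    fvfm: float
    pi: float = float("nan")
    rc_cs: float = float("nan")
    dio_rc: float = float("nan")

    def __post_init__(self):
        if not 0.0 <= self.fvfm <= 1.0:
            raise InvalidInputError(f"Fv/Fm must lie in [0, 1], got {self.fvfm}")


def fit_standard_curve(points: Sequence[tuple], analyte: str = "") -> StandardCurve:
    """Fit an OLS line of absorbance on concentration.

    Parameters
    ----------
    points : sequence of (concentration, absorbance)
        At least three standards; duplicate concentrations are allowed.

    Raises
    ------
    CurveQualityError
        Fewer than three points, or a non-monotone mean response.
    """
    pts = [(float(c), float(a)) for c, a in points]
    if len(pts) < 3:
        raise CurveQualityError(f"standard curve needs >= 3 points, got {len(pts)}")
    conc = np.array([p[0] for p in pts])
    absb = np.array([p[1] for p in pts])
    if np.ptp(conc) == 0:
        raise CurveQualityError("all standards have the same concentration")
    # Monotone mean response across distinct concentrations.
    order = np.argsort(conc)
    uconc, idx = np.unique(conc[order], return_inverse=True)
    means = np.array([absb[order][idx == i].mean() for i in range(len(uconc))])
    diffs = np.diff(means)
    if not (np.all(diffs >= 0) or np.all(diffs <= 0)):
        raise CurveQualityError(f"non-monotone response for analyte '{analyte}'")
    res = stats.linregress(conc, absb)
    r2 = float(res.rvalue**2)
    if r2 < 0.99:
        warnings.warn(
            f"standard curve for '{analyte}' has r2 = {r2:.4f} < 0.99",
            stacklevel=2,
        )
    return StandardCurve(
        analyte=analyte,
        points=tuple(pts),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        valid_range=(float(conc.min()), float(conc.max())),
    )


class Quantification(NamedTuple):
    value: float
    unit: str
    extrapolated: bool
    clipped: bool


@dataclass(frozen=True)
class AssaySpec:
    """How one assay's cuvette concentration maps to a tissue-level value.

    tissue value = cuvette concentration x dilution x extract_volume
                   / tissue_mass x unit_scale
    """

    analyte: str
    curve_points: tuple
    unit: str
    unit_scale: float = 1.0
    tissue_mass: float = 1.0
    extract_volume: float = 3.0
    dilution: float = 1.0
    wavelength: float = 0.0
    blank: float = 0.0

    def curve(self) -> StandardCurve:
        return fit_standard_curve(self.curve_points, analyte=self.analyte)


def quantify(curve: StandardCurve, reading: AssayReading,
             unit: str = "", unit_scale: float = 1.0) -> Quantification:
    """Convert a raw reading into the assay's tissue-level reporting unit.

    The blank-corrected absorbance is pushed back through the standard curve,
    then scaled by dilution and the extract-volume / tissue-mass ratio.
    Negative blank-corrected responses are clipped to zero concentration with
    a warning; values outside the standards' range are flagged as
    extrapolation, never refused.
    """
    a_corr = reading.absorbance - reading.blank
    clipped = False
    conc = curve.concentration(a_corr)
    if conc < 0:
        warnings.warn(
            f"negative blank-corrected response for '{reading.assay}'; clipped to 0",
            stacklevel=2,
        )
        conc = 0.0
        clipped = True
    extrapolated = not (curve.valid_range[0] <= conc <= curve.valid_range[1])
    value = conc * reading.dilution * reading.extract_volume / reading.tissue_mass
    value *= unit_scale
    return Quantification(float(value), unit, bool(extrapolated), clipped)


def absorbance_for(spec: AssaySpec, tissue_value: float) -> float:
    """Forward model: the absorbance a tissue-level value would produce.

    Exact inverse of :func:`quantify` under the same assay spec; used by the
    synthetic reading generator.
    """
    conc = tissue_value / spec.unit_scale * spec.tissue_mass / (
        spec.extract_volume * spec.dilution
    )
    curve = spec.curve()
    return curve.response(conc) + spec.blank


class Pigments(NamedTuple):
    chl_a: float
    chl_b: float
    chl_total: float
    carotenoids: float
    unit: str


def lichtenthaler_pigments(a665_2: float, a652_4: float, a470: float,
                           tissue_mass: float, solvent_volume: float) -> Pigments:
    """Chlorophylls and carotenoids from methanol-extract absorbances.

    Applies the pure-methanol coefficient set:
    chl_a = 16.72 A665.2 - 9.16 A652.4, chl_b = 34.09 A652.4 - 15.28 A665.2
    (ug/mL), carotenoids = (1000 A470 - 1.63 chl_a - 104.96 chl_b) / 221,
    then scales to mg per g of fresh tissue. Negative pigments (possible at
    noisy low absorbance) are clipped to zero with a warning.
    """
    if min(a665_2, a652_4, a470) < 0:
        raise InvalidInputError("absorbances must be >= 0")
    if tissue_mass <= 0 or solvent_volume <= 0:
        raise InvalidInputError("tissue mass and solvent volume must be > 0")
    chl_a = 16.72 * a665_2 - 9.16 * a652_4
    chl_b = 34.09 * a652_4 - 15.28 * a665_2
    clipped = [v for v, n in ((chl_a, "chl_a"), (chl_b, "chl_b")) if v < 0]
    chl_a = max(chl_a, 0.0)
    chl_b = max(chl_b, 0.0)
    car = (1000.0 * a470 - 1.63 * chl_a - 104.96 * chl_b) / 221.0
    if car < 0:
        clipped.append(car)
        car = 0.0
    if clipped:
        warnings.warn("negative computed pigment clipped to 0", stacklevel=2)
    # ug/mL -> mg/g FW
    f = solvent_volume / tissue_mass / 1000.0
    return Pigments(chl_a * f, chl_b * f, (chl_a + chl_b) * f, car * f,
                    "mg g^-1 FW")


class PalActivity(NamedTuple):
    units: float
    nmol_ca_per_h: float
    specific_activity: float  # nmol CA h^-1 mg^-1 protein
    unit: str


#: One PAL unit = dA290 of 0.01 per hour = 3.09 nmol trans-cinnamic acid per hour.
PAL_UNIT_DELTA_A = 0.01
PAL_NMOL_CA_PER_UNIT = 3.09


def pal_activity(delta_a290_blanked: float, reaction_time: float,
                 protein_in_assay: float) -> PalActivity:
    """PAL activity from the blank-corrected A290 increase.

    The absorbance increase is first normalised to an hourly rate
    (assays run 30 or 60 min), converted to enzyme units (0.01 dA290/h per
    unit), to nmol of trans-cinnamic acid formed per hour (3.09 nmol/h per
    unit), and finally to specific activity per mg of soluble protein.
    Negative increases yield zero activity with a warning.
    """
    if reaction_time <= 0:
        raise InvalidInputError("reaction time must be > 0 min")
    if protein_in_assay <= 0:
        raise InvalidInputError("protein in assay must be > 0 mg")
    da = delta_a290_blanked
    if da < 0:
        warnings.warn("negative dA290; PAL activity set to 0", stacklevel=2)
        da = 0.0
    da_per_h = da * (60.0 / reaction_time)
    units = da_per_h / PAL_UNIT_DELTA_A
    nmol_ca = units * PAL_NMOL_CA_PER_UNIT
    return PalActivity(units, nmol_ca, nmol_ca / protein_in_assay,
                       "nmol CA h^-1 mg^-1 protein")


def ethylene_rate(headspace_conc: float, jar_volume: float,
                  plant_mass: float, elapsed: float) -> float:
    """Ethylene emission rate in uL kg^-1 h^-1 from static headspace.

    ``headspace_conc`` in uL/L accumulated in a sealed jar of ``jar_volume``
    litres over ``elapsed`` hours by a plant of ``plant_mass`` kilograms.
    The free headspace is taken as the nominal jar volume (no displacement
    correction).
    """
    if min(jar_volume, plant_mass, elapsed) <= 0:
        raise InvalidInputError("jar volume, plant mass and elapsed time must be > 0")
    if headspace_conc < 0:
        raise InvalidInputError("headspace concentration must be >= 0")
    return headspace_conc * jar_volume / (plant_mass * elapsed)


def _line(slope: float, intercept: float, concs: Sequence[float]) -> tuple:
    return tuple((c, intercept + slope * c) for c in concs)


#: Default assay panel. Curve points are exact lines, so the fitted slope and
#: intercept reproduce the generating values and quantification round-trips
#: exactly at zero read noise. Extraction volumes follow the wet protocols
#: (about 1 g tissue in 3 mL water for nitrate and sugars; 1 g in ~2.5 mL
#: methanol for the phenolic/antioxidant panel).
DEFAULT_ASSAYS: dict[str, AssaySpec] = {
    # KNO3 curve in ug/mL; tissue nitrate in mg per kg FW (= ug/g).
    "nitrate": AssaySpec(
        "nitrate", _line(0.01, 0.02, (0, 20, 40, 60, 80, 100)),
        unit="mg kg^-1 FW", tissue_mass=1.0, extract_volume=3.0,
        dilution=10.0, wavelength=410.0, blank=0.02,
    ),
    # Sucrose curve in mg/mL (resorcinol method, A500).
    "sucrose": AssaySpec(
        "sucrose", _line(1.0, 0.01, (0, 0.2, 0.4, 0.6, 0.8, 1.0)),
        unit="mg g^-1 FW", tissue_mass=1.0, extract_volume=3.0,
        dilution=1.0, wavelength=500.0, blank=0.01,
    ),
    # Glucose curve in mg/mL (anthrone method, A620).
    "total_sugars": AssaySpec(
        "total_sugars", _line(1.0, 0.015, (0, 0.2, 0.4, 0.6, 0.8, 1.0)),
        unit="mg g^-1 FW", tissue_mass=1.0, extract_volume=3.0,
        dilution=5.0, wavelength=620.0, blank=0.015,
    ),
    # Gallic acid curve in mg/mL (Folin-Ciocalteu, A765); GAE mg per g FW.
    "phenolics": AssaySpec(
        "phenolics", _line(5.0, 0.02, (0, 0.05, 0.1, 0.2, 0.3, 0.4)),
        unit="mg GAE g^-1 FW", tissue_mass=1.0, extract_volume=2.5,
        dilution=2.0, wavelength=765.0, blank=0.02,
    ),
    # Rutin curve in nmol/mL (A510); flavonoids as nmol rutin eq per g FW.
    "flavonoids": AssaySpec(
        "flavonoids", _line(0.003, 0.01, (0, 25, 50, 100, 150, 200)),
        unit="nmol RE g^-1 FW", tissue_mass=1.0, extract_volume=2.5,
        dilution=1.0, wavelength=510.0, blank=0.01,
    ),
    # Ascorbic acid curve 10-150 uM (= nmol/mL, A695); reported as
    # umol ascorbic-acid equivalents per g FW.
    "antioxidant": AssaySpec(
        "antioxidant", _line(0.006, 0.03, (10, 25, 50, 75, 100, 150)),
        unit="umol AAE g^-1 FW", unit_scale=1e-3, tissue_mass=1.0,
        extract_volume=2.5, dilution=10.0, wavelength=695.0, blank=0.03,
    ),
}
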