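"""Reduce raw partition and titration measurements to logD(7.4) and pKa.

Partitioning (19F NMR, shake-flask with an internal standard of known
lipophilicity):

    logD = logD_standard + log10[(analyte_oct/standard_oct) / (analyte_aq/standard_aq)]

Partitioning (HPLC-UV mass balance over the aqueous phase):

    D = ((area_before - area_after) / area_after) * (V_aq / V_oct)

Titration: chemical shift vs pH follows the single-protonation sigmoid

    shift(pH) = shift_acid + (shift_base - shift_acid) / (1 + 10**(pKa - pH))

fitted by least squares; a model-free route takes the pH at the zero crossing
of the smoothed numeric second derivative of shift vs pH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import mean, stdev

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConvergenceError, DegenerateFitError, DomainError

#: default chemical-shift reference per nucleus (ppm): KF for 19F,
#: trifluoroethanol for 1H.
REFERENCE_SHIFTS = {"19F": -125.00, "1H": 3.14}


@dataclass(frozen=True)
class PartitionMeasurement:
    analyte_integral_oct: float
    standard_integral_oct: float
    analyte_integral_aq: float
    standard_integral_aq: float
    standard_logd: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        for name in (
            "analyte_integral_oct",
            "standard_integral_oct",
            "analyte_integral_aq",
            "standard_integral_aq",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class HplcPartition:
    area_before: float
    area_after: float
    v_aq: float
    v_oct: float

    def __post_init__(self) -> None:
        if self.v_aq <= 0 or self.v_oct <= 0:
            raise DomainError("volumes must be positive")
        if not 0 < self.area_after < self.area_before:
            raise DomainError(
                "need 0 < area_after < area_before (no partitioning into octanol?)"
            )


@dataclass(frozen=True)
class TitrationSeries:
    points: tuple[tuple[float, float], ...]
    nucleus: str = "19F"
    reference_shift: float | None = None

    def __post_init__(self) -> None:
        if len(self.points) < 8:
            raise DomainError("titration series needs at least 8 (pH, shift) points")
        if self.nucleus not in REFERENCE_SHIFTS:
            raise DomainError(f"unknown nucleus {self.nucleus!r}")
        if self.reference_shift is None:
            object.__setattr__(
                self, "reference_shift", REFERENCE_SHIFTS[self.nucleus]
            )

    def sorted_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pts = sorted(self.points)
        ph = np.array([p for p, _ in pts], dtype=float)
        shift = np.array([s for _, s in pts], dtype=float)
        return ph, shift


@dataclass(frozen=True)
class SigmoidFit:
    pka: float
    shift_acid: float
    shift_base: float
    residual_rms: float
    hill_slope: float = 1.0


@dataclass(frozen=True)
class LogdResult:
    mean: float
    sd: float | None
    values: tuple[float, ...] = field(default_factory=tuple)

    @property
    def n_replicates(self) -> int:
        return len(self.values)


def logd_from_nmr(m: PartitionMeasurement) -> float:
    """Double-ratio logD for one replicate."""
    ratio_oct = m.analyte_integral_oct / m.standard_integral_oct
    ratio_aq = m.analyte_integral_aq / m.standard_integral_aq
    return m.standard_logd + float(np.log10(ratio_oct / ratio_aq))


def aggregate_logd(measurements: list[PartitionMeasurement]) -> LogdResult:
    """Mean +/- sample SD across replicates (no outlier rejection)."""
    if not measurements:
        raise DomainError("no partition measurements")
    if len(measurements) < 2:
        warnings.warn("fewer than 2 replicates: standard deviation unavailable")
    values = tuple(logd_from_nmr(m) for m in measurements)
    sd = stdev(values) if len(values) >= 2 else None
    return LogdResult(mean=mean(values), sd=sd, values=values)


def logd_from_hplc(m: HplcPartition) -> float:
    """logD from aqueous-phase depletion, corrected for the volume ratio."""
    d = ((m.area_before - m.area_after) / m.area_after) * (m.v_aq / m.v_oct)
    return float(np.log10(d))


def _sigmoid(ph: np.ndarray, pka: float, shift_acid: float, shift_base: float,
             slope: float = 1.0) -> np.ndarray:
    return shift_acid + (shift_base - shift_acid) / (1.0 + 10.0 ** (slope * (pka - ph)))


def fit_titration(t: TitrationSeries, free_slope: bool = False) -> SigmoidFit:
    """Least-squares sigmoid fit; the pKa is the inflection point.

    Raises ``DegenerateFitError`` when the shift transition is absent or
    buried in noise, and ``ConvergenceError`` (with a residual report) when
    the optimizer fails or the pKa lands outside the observed pH range.
    """
    ph, shift = t.sorted_arrays()
    span = float(shift.max() - shift.min())
    if span < 1e-9:
        raise DegenerateFitError("no shift transition within the pH range")

    lo = float(np.mean(shift[:3]))
    hi = float(np.mean(shift[-3:]))
    mid = 0.5 * (shift.min() + shift.max())
    pka0 = float(ph[np.argmin(np.abs(shift - mid))])

    if free_slope:
        model = lambda x, pka, a, b, s: _sigmoid(x, pka, a, b, s)  # noqa: E731
        p0 = [pka0, lo, hi, 1.0]
    else:
        model = lambda x, pka, a, b: _sigmoid(x, pka, a, b)  # noqa: E731
        p0 = [pka0, lo, hi]
    try:
        popt, _ = curve_fit(model, ph, shift, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - rare optimizer failure
        raise ConvergenceError(f"sigmoid fit did not converge: {exc}") from exc

    fitted = model(ph, *popt)
    resid = shift - fitted
    rms = float(np.sqrt(np.mean(resid ** 2)))
    pka, shift_acid, shift_base = float(popt[0]), float(popt[1]), float(popt[2])
    slope = float(popt[3]) if free_slope else 1.0
    if abs(shift_base - shift_acid) < max(1e-9, 3.0 * rms):
        raise DegenerateFitError(
            "fitted transition amplitude indistinguishable from noise "
            f"(|delta shift|={abs(shift_base - shift_acid):.3g}, rms={rms:.3g})"
        )
    if not ph.min() <= pka <= ph.max():
        raise ConvergenceError(
            f"fitted pKa {pka:.3f} outside observed pH range "
            f"[{ph.min():.2f}, {ph.max():.2f}]; residual rms {rms:.3g}"
        )
    return SigmoidFit(
        pka=pka, shift_acid=shift_acid, shift_base=shift_base,
        residual_rms=rms, hill_slope=slope,
    )


def _local_cubic_derivatives(ph: np.ndarray, shift: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivative at each point from 5-point local cubic fits."""
    n = len(ph)
    d1 = np.empty(n)
    d2 = np.empty(n)
    for i in range(n):
        lo = min(max(0, i - 2), n - 5)
        sl = slice(lo, lo + 5)
        # center x at ph[i] so derivatives read off the low-order coefficients
        c = np.polyfit(ph[sl] - ph[i], shift[sl], 3)
        d1[i] = c[2]
        d2[i] = 2.0 * c[1]
    return d1, d2


def second_derivative_pka(t: TitrationSeries) -> float:
    """Model-free pKa: pH at the zero crossing of the smoothed second derivative.

    With multiple crossings, the one nearest the steepest-slope pH is
    returned with a warning.
    """
    ph, shift = t.sorted_arrays()
    if len(ph) < 10:
        raise DomainError("second-derivative estimate needs at least 10 points")
    span = float(shift.max() - shift.min())
    if span < 1e-9:
        raise DegenerateFitError("no shift transition within the pH range")
    d1, d2 = _local_cubic_derivatives(ph, shift)
    ph_span = float(ph.max() - ph.min())
    if np.max(np.abs(d2)) < 1e-6 * span / ph_span ** 2:
        raise DegenerateFitError("no inflection: second derivative is flat")
    crossings = []
    for i in range(len(ph) - 1):
        if d2[i] == 0.0 and d2[i + 1] != 0.0:
            crossings.append(float(ph[i]))
        elif d2[i] * d2[i + 1] < 0.0:
            # linear interpolation for the crossing pH
            w = d2[i] / (d2[i] - d2[i + 1])
            crossings.append(float(ph[i] + w * (ph[i + 1] - ph[i])))
    if not crossings:
        raise DegenerateFitError("no inflection: second derivative does not change sign")
    steepest = float(ph[np.argmax(np.abs(d1))])
    if len(crossings) > 1:
        warnings.warn(
            f"{len(crossings)} second-derivative zero crossings; "
            "returning the one nearest the steepest-slope pH"
        )
    return min(crossings, key=lambda c: abs(c - steepest))
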