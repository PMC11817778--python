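"""Spectral preprocessing: SNV, MSC and Savitzky–Golay smoothing/derivatives.

All three operate row-wise on a :class:`~nirquant.dataset.SpectraSet` and
return a new set on the same grid.  SNV and SG are stateless; MSC is fitted
against a reference spectrum — by convention the mean of the *calibration*
set — and the same reference must be reused when transforming prediction-set
spectra so that no prediction-set information leaks into the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectraSet
from .errors import ConfigError, DegenerateSpectrumError, DimensionError
from .simulate import spacing

METHODS = ("raw", "snv", "msc", "sg")


@dataclass
class PreprocConfig:
    """Configuration for one preprocessing method.

    ``sg_window`` must be odd and larger than ``sg_polyorder``; the derivative
    order may not exceed the polynomial order.  Defaults follow the standard
    NIR setting: window 11, polynomial order 2, no derivative.
    """

    method: str = "raw"
    sg_window: int = 11
    sg_polyorder: int = 2
    sg_deriv: int = 0
    msc_reference: str | np.ndarray = "mean"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown preprocessing method {self.method!r}")
        if self.sg_window % 2 == 0:
            raise ConfigError(f"sg_window must be odd, got {self.sg_window}")
        if self.sg_window <= self.sg_polyorder:
            raise ConfigError("sg_window must exceed sg_polyorder")
        if self.sg_deriv > self.sg_polyorder:
            raise ConfigError("sg_deriv may not exceed sg_polyorder")


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard Normal Variate: per-row centering and unit-variance scaling.

    Each row ``x`` becomes ``(x − mean(x)) / sd(x)`` with the sample standard
    deviation (denominator ``n − 1``), removing per-sample offset and
    multiplicative scale.  Constant rows cannot be normalized.
    """
    A = spectra.absorbance
    mean = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise DegenerateSpectrumError(
            f"constant spectrum (zero variance) for sample "
            f"{spectra.sample_ids[int(zero[0])]!r}"
        )
    return spectra.with_absorbance((A - mean) / sd)


def msc(spectra: SpectraSet, reference: str | np.ndarray = "mean") -> SpectraSet:
    """Multiplicative Scatter Correction against a reference spectrum.

    Each row is regressed on the reference, ``x ≈ a + b·ref`` (ordinary least
    squares over all wavelengths), and corrected to ``(x − a) / b``.  With
    ``reference="mean"`` the set's own mean spectrum is used; pass the
    calibration-set mean explicitly to transform prediction spectra.
    """
    A = spectra.absorbance
    if isinstance(reference, str):
        if reference != "mean":
            raise ConfigError(f"unknown MSC reference {reference!r}")
        ref = A.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (spectra.n_points,):
            raise DimensionError(
                f"MSC reference has {ref.size} points, grid has {spectra.n_points}"
            )
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0.0:
        raise DegenerateSpectrumError("MSC reference spectrum is constant")
    # closed-form simple-regression OLS per row: b = cov(x, ref)/var(ref)
    b = (A - A.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = A.mean(axis=1) - b * ref.mean()
    bad = np.flatnonzero(np.abs(b) < 1e-12)
    if bad.size:
        raise DegenerateSpectrumError(
            f"uncorrectable spectrum (slope ~ 0) for sample "
            f"{spectra.sample_ids[int(bad[0])]!r}"
        )
    return spectra.with_absorbance((A - a[:, None]) / b[:, None])


def msc_reference(calibration: SpectraSet) -> np.ndarray:
    """The MSC reference fitted on a calibration set (its mean spectrum)."""
    return calibration.absorbance.mean(axis=0)


def sg_filter(
    spectra: SpectraSet,
    window: int = 11,
    polyorder: int = 2,
    deriv: int = 0,
) -> SpectraSet:
    """Savitzky–Golay smoothing or differentiation.

    Each point is replaced by the ``deriv``-th derivative, at the window
    center, of the least-squares polynomial of degree ``polyorder`` fitted to
    the surrounding ``window`` points.  Derivatives are with respect to
    wavenumber, so the output units are absorbance per (cm⁻¹)^deriv.
    At the edges the polynomial is fitted to
    the first/last ``window`` points and evaluated at the edge positions
    (no reflection padding, which would fabricate derivative artifacts).
    """
    if window % 2 == 0:
        raise ConfigError(f"window must be odd, got {window}")
    if not (window > polyorder >= deriv >= 0):
        raise ConfigError("require window > polyorder >= deriv >= 0")
    if window >= spectra.n_points:
        raise ConfigError(
            f"window {window} must be smaller than the spectrum length "
            f"{spectra.n_points}"
        )
    delta = spacing(spectra.wavenumbers)
    out = savgol_filter(
        spectra.absorbance, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=delta, axis=1, mode="interp",
    )
    # the array axis runs along *descending* wavenumber: d/dnu flips sign
    if deriv % 2 == 1:
        out = -out
    return spectra.with_absorbance(out)


def apply_method(
    config: PreprocConfig,
    calibration: SpectraSet,
    prediction: SpectraSet | None = None,
):
    """Apply one preprocessing method, fitting any state on the calibration set.

    Returns ``(calibration_pp, prediction_pp)``; the second element is ``None``
    when no prediction set is given.
    """
    m = config.method
    if m == "raw":
        return calibration, prediction
    if m == "snv":
        return snv(calibration), None if prediction is None else snv(prediction)
    if m == "msc":
        if isinstance(config.msc_reference, str):
            ref = msc_reference(calibration)
        else:
            ref = np.asarray(config.msc_reference, float)
        return (
            msc(calibration, ref),
            None if prediction is None else msc(prediction, ref),
        )
    if m == "sg":
        args = (config.sg_window, config.sg_polyorder, config.sg_deriv)
        return (
            sg_filter(calibration, *args),
            None if prediction is None else sg_filter(prediction, *args),
        )
    raise ConfigError(f"unknown preprocessing method {m!r}")
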