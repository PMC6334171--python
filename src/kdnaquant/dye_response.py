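"""Dye fluorescence-vs-AT response calibration.

DAPI binds the DNA minor groove with a strong preference for AT-rich
sequence, while RedDot1 is an intercalator whose signal depends only
weakly on base composition.  Calibration against a dilution series of
double-stranded oligonucleotides of known AT fraction characterises
each dye by an affine response

    f(AT) = intercept + slope * AT,

normalised so that f(1) = 1 (response per unit DNA, relative to pure
AT).  The fitted model drives two things downstream: signature columns
for two-component unmixing, and the worst-case quantitation error a
composition-insensitive assumption can incur.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationRecord",
    "DyeResponseModel",
    "fit_response",
    "predict",
    "max_relative_error",
]


@dataclass(frozen=True)
class CalibrationRecord:
    """One oligo measurement: AT fraction, dye name, background-corrected fluorescence.

    Background correction can leave small negative values; these are kept
    (clipping would bias the fit low) but counted by :func:`fit_response`.
    """

    at_fraction: float
    dye: str
    fluorescence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ValueError(f"at_fraction {self.at_fraction} outside [0, 1]")


@dataclass(frozen=True)
class DyeResponseModel:
    """Affine per-dye response, normalised so the prediction at AT=1 is 1.

    ``residual_sd`` is the root-mean-square fit residual on the normalised
    scale; ``n_negative_inputs`` counts background-corrected measurements
    that were negative (retained in the fit, flagged here).
    """

    dye: str
    intercept: float
    slope: float
    residual_sd: float = 0.0
    n_negative_inputs: int = 0

    def __post_init__(self) -> None:
        if abs(self.intercept + self.slope - 1.0) > 1e-9:
            raise ValueError("model must be normalised so intercept + slope = 1")


def fit_response(records: list[CalibrationRecord], dye: str) -> DyeResponseModel:
    """Least-squares affine fit of fluorescence vs AT fraction for one dye.

    The fit is rescaled so the predicted response at AT = 1 equals 1; the
    residual standard deviation is reported on that normalised scale.
    Requires measurements at >= 3 distinct AT fractions.  A fit whose
    prediction goes negative anywhere on [0, 1] is returned but flagged
    with a warning (the affine form is then a poor description of the dye).
    """
    sub = [r for r in records if r.dye == dye]
    if not sub:
        raise ValueError(f"no calibration records for dye {dye!r}")
    at = np.array([r.at_fraction for r in sub], dtype=float)
    fl = np.array([r.fluorescence for r in sub], dtype=float)
    if len(np.unique(at)) < 3:
        raise ValueError(f"dye {dye!r}: need >= 3 distinct AT fractions, got {len(np.unique(at))}")
    if np.allclose(fl, 0.0):
        raise ValueError(f"dye {dye!r}: all fluorescence values are zero")

    n_negative = int(np.sum(fl < 0))
    if n_negative:
        warnings.warn(
            f"dye {dye!r}: {n_negative} negative background-corrected values retained in fit",
            stacklevel=2,
        )

    slope, intercept = np.polyfit(at, fl, 1)
    at_one = intercept + slope
    if at_one <= 0:
        raise ValueError(f"dye {dye!r}: fitted response at AT=1 is nonpositive ({at_one:.3g})")
    intercept /= at_one
    slope /= at_one

    resid = fl / at_one - (intercept + slope * at)
    residual_sd = float(np.sqrt(np.mean(resid**2)))

    if min(intercept, intercept + slope) < -1e-9:
        warnings.warn(
            f"dye {dye!r}: fitted response is negative somewhere on AT in [0, 1]",
            stacklevel=2,
        )
    return DyeResponseModel(
        dye=dye,
        intercept=float(intercept),
        slope=float(slope),
        residual_sd=residual_sd,
        n_negative_inputs=n_negative,
    )


def predict(model: DyeResponseModel, at: float) -> float:
    """Relative fluorescence per unit DNA at AT fraction ``at`` (in [0, 1])."""
    at = float(at)
    if not 0.0 <= at <= 1.0:
        raise ValueError(f"AT fraction {at} outside [0, 1]")
    return model.intercept + model.slope * at


def max_relative_error(model: DyeResponseModel, assumed_at: float = 0.5) -> float:
    """Worst-case relative quantitation error from unknown base composition.

    Quantifying DNA of true AT fraction ``at`` while assuming ``assumed_at``
    mis-scales the amount by f(at)/f(assumed_at).  For an affine response
    the extreme over at in [0, 1] is attained at an endpoint, so the bound is

        max_{e in {0,1}} | f(e)/f(assumed_at) - 1 |.

    Defaults to ``assumed_at = 0.5`` (compositions near 50% AT).
    """
    base = predict(model, assumed_at)
    if base <= 0:
        raise ValueError(f"response at assumed_at={assumed_at} is nonpositive")
    endpoints = (predict(model, 0.0), predict(model, 1.0))
    return max(abs(f / base - 1.0) for f in endpoints)
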