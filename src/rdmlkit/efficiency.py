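"""PCR amplification-efficiency estimation.

Two routes are supported, matching the two ways the format's efficiency
uncertainty can be obtained:

* **standard curve** — ordinary least squares of Cq on log10(input) over a
  dilution series of standards.  Efficiency is the usual
  ``E = 10^(-1/slope)`` (fold-change of product per cycle; perfect doubling
  gives E = 2 and a slope of about -3.32 cycles per 10-fold dilution).  The
  standard error of E follows by first-order (delta-method) propagation of
  the slope's standard error:

      SE(E) = E * ln(10) * SE(slope) / slope**2

* **per-curve SEM** — when an amplification-curve analysis tool has already
  produced one efficiency value per reaction, the target's efficiency is
  their arithmetic mean and the uncertainty the standard error of that mean
  (sample SD / sqrt(n)).  Computing those per-curve values is outside this
  package's scope; they are consumed, not derived.

Replicate standards enter the fit as independent observations (no
pre-averaging), preserving degrees of freedom for the standard error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    ElementWrongVersionError,
    InsufficientDataError,
    RdmlDocument,
    UnitMismatchError,
)

METHOD_STANDARD_CURVE = "standard-curve"
METHOD_PER_CURVE_SEM = "per-curve-sem"


@dataclass
class StandardPoint:
    """One standard reaction: log10 of its input quantity and observed Cq."""

    log10Input: float
    cq: float


@dataclass
class StandardCurveFit:
    efficiency: float  # fold-change per cycle
    efficiencySE: Optional[float]  # same scale
    nPoints: int
    method: str
    slope: Optional[float] = None  # cycles per log10 unit
    intercept: Optional[float] = None  # cycles at log10(input) = 0
    rSquared: Optional[float] = None


def fit_standard_curve(points: Iterable[StandardPoint]) -> StandardCurveFit:
    """Least-squares fit of Cq versus log10(input) over a dilution series.

    Requires at least three points spanning at least two distinct input
    levels.  A non-negative slope (no dilution-dependent Cq increase) yields
    an efficiency outside the meaningful (1, 2] range; a warning is issued
    but the fit is still returned.
    """
    pts = list(points)
    if len(pts) < 3:
        raise InsufficientDataError(
            f"standard curve needs >= 3 points, got {len(pts)}")
    x = np.array([p.log10Input for p in pts], dtype=float)
    y = np.array([p.cq for p in pts], dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("non-finite values in standard points")
    if np.unique(x).size < 2:
        raise InsufficientDataError(
            "standard curve needs >= 2 distinct input levels")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    if slope >= 0:
        warnings.warn(
            f"standard-curve slope {slope:.4g} is non-negative; the derived "
            "efficiency is outside the meaningful range", stacklevel=2)
        efficiency = math.inf if slope == 0 else 10.0 ** (-1.0 / slope)
        se = None
    else:
        efficiency = 10.0 ** (-1.0 / slope)
        se = efficiency * math.log(10.0) * float(res.stderr) / slope**2
    return StandardCurveFit(
        efficiency=efficiency,
        efficiencySE=se,
        nPoints=len(pts),
        method=METHOD_STANDARD_CURVE,
        slope=slope,
        intercept=float(res.intercept),
        rSquared=float(res.rvalue) ** 2,
    )


def efficiency_from_per_curve(values: Sequence[float]) -> StandardCurveFit:
    """Aggregate per-reaction efficiency values: mean and SEM."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise InsufficientDataError(
            f"per-curve aggregation needs >= 2 values, got {vals.size}")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return StandardCurveFit(
        efficiency=mean,
        efficiencySE=sem,
        nPoints=int(vals.size),
        method=METHOD_PER_CURVE_SEM,
    )


def standard_points_from_document(
    doc: RdmlDocument, target_id: str
) -> list[StandardPoint]:
    """Collect (log10 input, Cq) pairs for *target_id* from standard samples.

    Only reactions whose sample is of type ``standard`` and carries a
    quantity contribute.  All quantities must share one unit; standards with
    zero/negative quantity or without an observed Cq are excluded with a
    warning.
    """
    samples = {s.id: s for s in doc.samples}
    unit: Optional[str] = None
    out: list[StandardPoint] = []
    for exp in doc.experiments:
        for run in exp.runs:
            for react in run.reactions:
                sample = samples.get(react.sampleRef)
                if (sample is None or sample.sampleType != "standard"
                        or sample.quantity is None):
                    continue
                for d in react.data:
                    if d.targetRef != target_id:
                        continue
                    if unit is None:
                        unit = sample.quantity.unit
                    elif sample.quantity.unit != unit:
                        raise UnitMismatchError(
                            f"standards mix units {unit!r} and "
                            f"{sample.quantity.unit!r}")
                    if sample.quantity.value <= 0:
                        warnings.warn(
                            f"standard {sample.id!r} has non-positive "
                            "quantity; excluded", stacklevel=2)
                        continue
                    if d.cq is None:
                        warnings.warn(
                            f"standard {sample.id!r} at position "
                            f"{react.position} has no Cq; excluded",
                            stacklevel=2)
                        continue
                    out.append(StandardPoint(
                        log10Input=math.log10(sample.quantity.value),
                        cq=d.cq))
    return out


def annotate_target(
    doc: RdmlDocument,
    target_id: str,
    fit: StandardCurveFit,
    include_se: bool = True,
) -> RdmlDocument:
    """Return a copy of *doc* with the fit written onto the target.

    The efficiency SE element exists only from version 1.2 on; writing it
    into an older document raises unless *include_se* is disabled.
    """
    import copy

    out = copy.deepcopy(doc)
    target = out.target(target_id)  # raises UnknownIdError
    if include_se and fit.efficiencySE is not None and out.version != "1.2":
        raise ElementWrongVersionError(
            "amplificationEfficiencySE requires version 1.2; migrate the "
            "document or pass include_se=False")
    target.amplificationEfficiency = fit.efficiency
    if include_se and fit.efficiencySE is not None and out.version == "1.2":
        target.amplificationEfficiencySE = fit.efficiencySE
    return out
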