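"""Linear cheap-to-reference property calibration.

Each property (-IP, -EA, optical gap) gets its own independent
ordinary-least-squares model, cheap values as predictor and reference
values as response, so calibrated = slope * cheap + intercept.  The fit
stores its own diagnostics (standard errors, MAE/RMSE of the calibrated
values against the reference) because downstream analyses are run
exclusively on calibrated values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .chem_core import PROPERTY_NAMES, PropertyRecord

#: floor for calibrated optical gaps (eV)
GAP_FLOOR = 0.05


def mae(a: Sequence[float], b: Sequence[float]) -> float:
    """Mean absolute difference between two equal-length value lists."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("mae of empty input")
    return float(np.mean(np.abs(a - b)))


def rmse(a: Sequence[float], b: Sequence[float]) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class CalibrationModel:
    property: str
    slope: float
    intercept: float
    n_fit: int
    mae_calibrated: float
    rmse_calibrated: float
    mae_raw: float
    rmse_raw: float
    stderr_slope: float
    stderr_intercept: float
    r_value: float

    def predict(self, cheap_values) -> np.ndarray:
        return self.slope * np.asarray(cheap_values, float) + self.intercept

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def fit_calibration(
    cheap: Sequence[float], reference: Sequence[float], property: str
) -> CalibrationModel:
    """OLS fit of reference on cheap values for one property."""
    if property not in PROPERTY_NAMES:
        raise KeyError(f"unknown property {property!r}")
    x = np.asarray(cheap, float)
    y = np.asarray(reference, float)
    if x.shape != y.shape:
        raise ValueError("cheap and reference value lists must be id-aligned and equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points to fit a calibration")
    if np.ptp(x) == 0:
        raise ValueError("cheap values are constant; calibration slope undefined")
    fit = stats.linregress(x, y)
    calibrated = fit.slope * x + fit.intercept
    return CalibrationModel(
        property=property,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_fit=int(x.size),
        mae_calibrated=mae(calibrated, y),
        rmse_calibrated=rmse(calibrated, y),
        mae_raw=mae(x, y),
        rmse_raw=rmse(x, y),
        stderr_slope=float(fit.stderr),
        stderr_intercept=float(fit.intercept_stderr),
        r_value=float(fit.rvalue),
    )


def fit_all(
    cheap: Sequence[PropertyRecord], reference: Sequence[PropertyRecord]
) -> dict[str, CalibrationModel]:
    """Fit the three per-property models from id-aligned record lists."""
    ref_by_id = {r.molecule_id: r for r in reference}
    pairs = [(c, ref_by_id[c.molecule_id]) for c in cheap if c.molecule_id in ref_by_id]
    if len(pairs) < len(cheap):
        missing = len(cheap) - len(pairs)
        raise ValueError(f"{missing} cheap record(s) have no reference counterpart")
    return {
        p: fit_calibration(
            [c.value(p) for c, _ in pairs], [r.value(p) for _, r in pairs], p
        )
        for p in PROPERTY_NAMES
    }


def apply_calibration(
    model: "CalibrationModel | Mapping[str, CalibrationModel]",
    records: Iterable[PropertyRecord],
    level: str = "calibrated",
) -> list[PropertyRecord]:
    """Map record values through slope*x + intercept and relabel the level.

    Accepts a single per-property model or a mapping property -> model
    (the usual case: calibrate all three properties at once).  Records
    must be at the "cheap" level.
    """
    models = model if isinstance(model, Mapping) else {model.property: model}
    out = []
    for rec in records:
        if rec.level != "cheap":
            raise ValueError(
                f"calibration applies to 'cheap' records, got level {rec.level!r} "
                f"for {rec.molecule_id!r}"
            )
        new = rec
        for prop, m in models.items():
            new = new.with_value(prop, m.slope * rec.value(prop) + m.intercept)
        out.append(
            PropertyRecord(
                new.molecule_id,
                new.minus_ip,
                new.minus_ea,
                # an affine map can push a near-zero gap non-positive;
                # floor it to keep the optical-gap invariant
                max(new.optical_gap, GAP_FLOOR),
                level,
            )
        )
    return out
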