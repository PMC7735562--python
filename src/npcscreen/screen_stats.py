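"""Plate-wise robust normalization, assay QC and multiparameter hit calling.

Raw per-well features are standardized plate-by-plate into robust Z scores,
(x - plate median) / (1.4826 * MAD), so plates acquired on different days
are comparable; assay quality is summarized by the Z' factor,
1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|; hit thresholds are calibrated
as per-feature medians of a marginally active positive-control group, and a
library well is a hit only if it strictly exceeds ALL three feature
thresholds.  The 1.4826 MAD consistency constant (the usual normal-theory
scaling) is configurable and always recorded alongside the outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, QC_OK, WellRecord
from .io_plate import Role, ValidationError

MAD_CONSTANT = 1.4826
# roles over which the plate null (median/MAD) is computed; control
# dose-series wells would bias the null centre and blanks carry no cells
DEFAULT_NULL_ROLES = (Role.LIBRARY.value, Role.VEHICLE.value)


class DegeneratePlateError(ValueError):
    """MAD of a plate is zero; robust Z is undefined there."""

    def __init__(self, plate_id: str, feature: str = ""):
        self.plate_id = plate_id
        self.feature = feature
        super().__init__(f"plate {plate_id!r}: zero MAD" +
                         (f" for feature {feature!r}" if feature else ""))


@dataclass
class NormalizedRecord:
    """A WellRecord plus its per-feature robust Z scores."""

    record: WellRecord
    robust_z: dict[str, float]

    def __getattr__(self, name):
        return getattr(self.record, name)


@dataclass(frozen=True)
class HitThresholds:
    circularity_t: float
    small_obj_ratio_t: float
    gfp_int_t: float

    def as_dict(self) -> dict[str, float]:
        return {"circularity": self.circularity_t,
                "small_obj_ratio": self.small_obj_ratio_t,
                "gfp_int": self.gfp_int_t}


def robust_z(values, mad_constant: float = MAD_CONSTANT,
             plate_id: str = "?") -> np.ndarray:
    """Robust Z scores: (x - median) / (mad_constant * raw MAD).

    NaN inputs propagate as NaN and do not affect the median or MAD.
    Requires >= 4 finite values and a strictly positive MAD.
    """
    x = np.asarray(values, dtype=np.float64)
    finite = x[np.isfinite(x)]
    if finite.size < 4:
        raise ValidationError(
            f"plate {plate_id!r}: need >= 4 finite values, got {finite.size}")
    med = np.median(finite)
    mad = np.median(np.abs(finite - med))
    if mad == 0.0:
        raise DegeneratePlateError(plate_id)
    return (x - med) / (mad_constant * mad)


def normalize_plates(records: list[WellRecord],
                     features: tuple[str, ...] = FEATURE_NAMES,
                     null_roles: tuple[str, ...] = DEFAULT_NULL_ROLES,
                     mad_constant: float = MAD_CONSTANT) -> list[NormalizedRecord]:
    """Robust-Z-normalize each feature plate by plate.

    The plate centre and scale are computed over qc-ok wells whose role is in
    ``null_roles`` (library + vehicle by default); the resulting transform is
    then applied to every well on the plate, controls included.
    """
    out: list[NormalizedRecord] = []
    by_plate: dict[str, list[WellRecord]] = {}
    for r in records:
        by_plate.setdefault(r.plate_id, []).append(r)
    for plate_id, wells in by_plate.items():
        null_wells = [w for w in wells
                      if w.role in null_roles and w.qc_flag == QC_OK]
        scale: dict[str, tuple[float, float]] = {}
        for feat in features:
            vals = np.array([getattr(w, feat) for w in null_wells], dtype=np.float64)
            finite = vals[np.isfinite(vals)]
            if finite.size < 4:
                raise ValidationError(
                    f"plate {plate_id!r}: need >= 4 usable null wells for {feat!r}")
            med = float(np.median(finite))
            mad = float(np.median(np.abs(finite - med)))
            if mad == 0.0:
                raise DegeneratePlateError(plate_id, feat)
            scale[feat] = (med, mad_constant * mad)
        for w in wells:
            rz = {feat: (getattr(w, feat) - scale[feat][0]) / scale[feat][1]
                  for feat in features}
            out.append(NormalizedRecord(w, rz))
    return out


def z_prime(pos, neg) -> float:
    """Classical Z' factor, 1 - 3(sd+ + sd-)/|mean+ - mean-| (sample SDs).

    Equal group means make the window undefined; -inf is returned as a
    sentinel (flagged, never silently dropped, in QC reports).
    """
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("z_prime needs >= 2 values per group")
    diff = abs(pos.mean() - neg.mean())
    if diff == 0.0:
        return float("-inf")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / diff


def z_prime_robust(pos, neg, mad_constant: float = MAD_CONSTANT) -> float:
    """Median/MAD variant of the Z' factor (QC diagnostic only)."""
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("z_prime needs >= 2 values per group")
    diff = abs(np.median(pos) - np.median(neg))
    if diff == 0.0:
        return float("-inf")
    s_pos = mad_constant * np.median(np.abs(pos - np.median(pos)))
    s_neg = mad_constant * np.median(np.abs(neg - np.median(neg)))
    return 1.0 - 3.0 * (s_pos + s_neg) / diff


@dataclass
class QcReport:
    per_plate: pd.DataFrame        # plate, feature, z_prime, n_wells, n_flagged
    degenerate_plates: list[str] = field(default_factory=list)


def qc_report(records: list[WellRecord],
              pos_role: str = Role.POSITIVE_CONTROL.value,
              neg_role: str = Role.VEHICLE.value,
              features: tuple[str, ...] = FEATURE_NAMES) -> QcReport:
    """Per-plate, per-feature Z' between positive-control and vehicle wells."""
    rows = []
    degenerate = []
    by_plate: dict[str, list[WellRecord]] = {}
    for r in records:
        by_plate.setdefault(r.plate_id, []).append(r)
    for plate_id, wells in sorted(by_plate.items()):
        n_flagged = sum(1 for w in wells if w.qc_flag != QC_OK)
        ok = [w for w in wells if w.qc_flag == QC_OK]
        pos = [w for w in ok if w.role == pos_role]
        neg = [w for w in ok if w.role == neg_role]
        for feat in features:
            if len(pos) >= 2 and len(neg) >= 2:
                zp = z_prime([getattr(w, feat) for w in pos],
                             [getattr(w, feat) for w in neg])
            else:
                zp = float("nan")
            if not math.isfinite(zp):
                degenerate.append(plate_id)
            rows.append({"plate": plate_id, "feature": feat, "z_prime": zp,
                         "n_wells": len(wells), "n_flagged": n_flagged})
    return QcReport(pd.DataFrame(rows), sorted(set(degenerate)))


def calibrate_thresholds(records: list[NormalizedRecord],
                         role: str = Role.MARGINAL_POSITIVE.value) -> HitThresholds:
    """Per-feature medians of the marginally active positive-control wells.

    NaN-featured or qc-flagged wells are excluded before taking the median;
    at least two usable wells are required.
    """
    usable = [r for r in records if r.role == role and r.qc_flag == QC_OK]
    med: dict[str, float] = {}
    for feat in FEATURE_NAMES:
        vals = np.array([r.robust_z[feat] for r in usable], dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise ValidationError(
                f"need >= 2 usable {role!r} wells to calibrate {feat!r}, got {vals.size}")
        med[feat] = float(np.median(vals))
    return HitThresholds(med["circularity"], med["small_obj_ratio"], med["gfp_int"])


def call_hits(records: list[NormalizedRecord], t: HitThresholds) -> pd.DataFrame:
    """Multiparameter hit call: a library well is a hit iff its robust Z
    strictly exceeds the threshold for all three features.

    Control/vehicle/blank wells are reported with ``is_hit`` False and
    ``eligible`` False; qc-flagged wells are reported as excluded.
    """
    thr = t.as_dict()
    rows = []
    for r in records:
        eligible = r.role == Role.LIBRARY.value
        excluded = r.qc_flag != QC_OK
        exceeds = all(np.isfinite(r.robust_z[f]) and r.robust_z[f] > thr[f]
                      for f in FEATURE_NAMES)
        rows.append({
            "plate": r.plate_id, "well": r.well_id, "treatment": r.treatment,
            "dose_uM": r.dose_uM, "role": r.role, "eligible": eligible,
            "excluded": excluded, "exceeds_all": exceeds,
            "is_hit": bool(eligible and not excluded and exceeds),
            **{f"rz_{f}": r.robust_z[f] for f in FEATURE_NAMES},
        })
    return pd.DataFrame(rows)


def dose_response_summary(records: list[NormalizedRecord],
                          treatment: str) -> pd.DataFrame:
    """Per-dose mean, sample SD and n of each feature's robust Z for one
    treatment.  Doses with no wells are omitted; a single well at a dose
    reports SD as NaN with n = 1."""
    sub = [r for r in records if r.treatment == treatment and r.qc_flag == QC_OK]
    if not sub:
        raise ValidationError(f"no records for treatment {treatment!r}")
    rows = []
    doses = sorted({r.dose_uM for r in sub})
    for dose in doses:
        at_dose = [r for r in sub if r.dose_uM == dose]
        for feat in FEATURE_NAMES:
            vals = np.array([r.robust_z[feat] for r in at_dose], dtype=np.float64)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            rows.append({
                "dose_uM": dose, "feature": feat,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                "n": int(vals.size),
            })
    return pd.DataFrame(rows)
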