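"""End-to-end study protocols on synthetic plates.

Two headline experiments exercise the whole pipeline:

* the assay-quality protocol — one plate of vehicle wells against
  positive-control wells at a saturating dose of the control chaperone,
  summarized by the per-feature Z' factor of the well means;
* the specificity protocol — a multi-plate screen whose negative controls
  (vehicle and blank wells) are normalized plate-wise, thresholded with
  medians calibrated from marginally active positive controls, and counted
  for false hits.

Fields are rendered in memory (same per-field seed derivation as the
on-disk generator) and scored with the published processing parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import (FEATURE_NAMES, FeatureConfig, WellRecord,
                       aggregate_well, compute_field_features)
from .io_plate import Role
from .screen_stats import (HitThresholds, calibrate_thresholds, call_hits,
                           normalize_plates, z_prime)
from .segmentation import ScreenConfig
from .synthetic_plate import (DoseResponseModel, PhenotypeParams, field_seed,
                              qc_plate_layout, render_field,
                              sample_cell_states, screen_layout,
                              well_phenotype)


def score_synthetic_layout(layout, models: dict[str, DoseResponseModel],
                           base: PhenotypeParams, seed: int,
                           height: int = 512, width: int = 512,
                           scfg: ScreenConfig | None = None,
                           fcfg: FeatureConfig | None = None) -> list[WellRecord]:
    """Render every field of a layout in memory and score it per well."""
    scfg = scfg or ScreenConfig()
    fcfg = fcfg or FeatureConfig()
    records: list[WellRecord] = []
    df = layout.table
    gfp_rows = df[df["channel"] == "GFP"]
    for (plate, well), sub in gfp_rows.groupby(["plate", "well"], sort=True):
        meta = sub.iloc[0]
        cond = well_phenotype(meta["treatment"], float(meta["dose_uM"]),
                              meta["role"], models, base)
        feats = []
        for fld in sorted(sub["field"].unique()):
            fseed = field_seed(seed, str(plate), str(well), int(fld))
            states = sample_cell_states(cond, base,
                                        np.random.default_rng((fseed, 1)))
            gfp, hoechst, _ = render_field(cond.params, height, width,
                                           seed=fseed, cell_states=states)
            feats.append(compute_field_features(gfp, hoechst, scfg, fcfg))
        records.append(aggregate_well(feats, plate, well, meta["treatment"],
                                      float(meta["dose_uM"]), meta["role"], fcfg))
    return records


@dataclass
class QcProtocolResult:
    z_prime_by_feature: dict[str, float]
    records: list[WellRecord]


def run_qc_protocol(seed: int, n_vehicle: int = 8, n_positive: int = 8,
                    n_fields: int = 6, height: int = 512, width: int = 512,
                    base: PhenotypeParams | None = None,
                    model: DoseResponseModel | None = None) -> QcProtocolResult:
    """Assay-quality plate: Z' per feature between saturating-dose positive
    wells and vehicle wells, computed on well means."""
    base = base or PhenotypeParams(theta=0.0)
    model = model or DoseResponseModel()
    layout = qc_plate_layout(n_vehicle, n_positive, n_fields,
                             positive_dose_uM=100.0 * model.ec50_uM)
    records = score_synthetic_layout(layout, {"mo56HC": model}, base, seed,
                                     height, width)
    zps = {}
    for feat in FEATURE_NAMES:
        pos = [getattr(r, feat) for r in records
               if r.role == Role.POSITIVE_CONTROL.value and r.qc_flag == "ok"]
        neg = [getattr(r, feat) for r in records
               if r.role == Role.VEHICLE.value and r.qc_flag == "ok"]
        zps[feat] = z_prime(pos, neg)
    return QcProtocolResult(zps, records)


@dataclass
class SpecificityProtocolResult:
    n_negative_wells: int
    n_negative_hits: int
    thresholds: HitThresholds
    hit_table: object
    records: list[WellRecord]


def run_specificity_protocol(seed: int, n_plates: int = 4,
                             vehicles_per_plate: int = 15,
                             blanks_per_plate: int = 4,
                             n_fields: int = 6, height: int = 512,
                             width: int = 512,
                             base: PhenotypeParams | None = None,
                             model: DoseResponseModel | None = None
                             ) -> SpecificityProtocolResult:
    """Negative-control specificity: calibrate per-feature thresholds from
    the marginally active control wells (medians of their robust Z scores)
    and count vehicle/blank wells exceeding all three thresholds."""
    base = base or PhenotypeParams(theta=0.0)
    model = model or DoseResponseModel()
    layout = screen_layout(n_plates=n_plates,
                           vehicles_per_plate=vehicles_per_plate,
                           blanks_per_plate=blanks_per_plate,
                           n_fields=n_fields)
    records = score_synthetic_layout(layout, {"mo56HC": model}, base, seed,
                                     height, width)
    normalized = normalize_plates(records)
    thresholds = calibrate_thresholds(normalized)
    table = call_hits(normalized, thresholds)
    neg = table[table["role"].isin([Role.VEHICLE.value, Role.BLANK.value])]
    false_hits = int((neg["exceeds_all"] & ~neg["excluded"]).sum())
    return SpecificityProtocolResult(len(neg), false_hits, thresholds,
                                     table, records)
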