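"""Synthetic two-channel field images with known ground truth.

The generator emulates the two localization phenotypes the screen
discriminates: a reticular, ER-like GFP pattern (branched filaments plus a
diffuse perinuclear haze, low circularity, large connected objects) and a
punctate, late-endosome/lysosome-like pattern (small bright Gaussian spots
in a perinuclear annulus, high circularity).  A single parameter ``theta``
in [0, 1] sets the fraction of each cell's GFP signal placed in puncta; a
Hill dose-response maps compound dose to ``theta``, and an optional
toxicity term thins the expected cell count with dose.

Hoechst nuclei are filled ellipses with areas drawn uniformly from
[2000, 5000] px, safely inside the nuclei size filter of the segmentation
chain.  Filipin-style images carry three intensity populations (background,
diffuse cytoplasm, bright puncta) for the cholesterol-accumulation module.

Every field is rendered from a seed derived stably from
(master seed, plate, well, field), so any subset of a plate can be
regenerated independently and identical seeds give bit-identical images.
Ground-truth signal totals are recorded before noise and clipping.
"""

from __future__ import annotations

import math
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io_plate import (Channel, ImageField, PlateLayout, Role,
                       ValidationError, write_field_image, LAYOUT_COLUMNS)

# Total GFP signal (intensity-unit-pixels) contributed by one cell at
# expression_scale = 1.  Sets absolute brightness relative to the [0,1]
# intensity range and the detector-saturation clip.
UNIT_SIGNAL = 250.0
# Filipin signal per cell and the dim in-cell baseline that keeps the cell
# footprint visible even when all signal sits in puncta.
FILIPIN_UNIT = 1200.0
FILIPIN_CELL_BASE = 0.03

# share of the reticular component rendered as a diffuse perinuclear haze
# (ER sheets) rather than discrete filaments (ER tubules)
RETICULUM_DIFFUSE_FRACTION = 0.4


@dataclass(frozen=True)
class PhenotypeParams:
    """Ground-truth knobs for one rendered field."""

    theta: float
    expression_scale: float = 1.0
    n_cells: int = 30
    puncta_per_cell: int = 10
    puncta_radius_px: float = 2.2
    noise_sd: float = 0.02  # detector noise, sd in [0,1] intensity units

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValidationError("theta must be in [0, 1]")
        if self.expression_scale <= 0:
            raise ValidationError("expression_scale must be positive")
        if self.n_cells < 0 or self.puncta_per_cell < 1:
            raise ValidationError("n_cells >= 0 and puncta_per_cell >= 1 required")
        if self.puncta_radius_px <= 0 or self.noise_sd < 0:
            raise ValidationError("puncta_radius_px > 0 and noise_sd >= 0 required")


@dataclass(frozen=True)
class DoseResponseModel:
    """Hill dose-response for theta plus a saturable toxicity term.

    The default EC50/Hill pair places a 0.03 uM dose at ~3% of the response
    range (a marginally active control) and makes 3-10 uM saturating.
    ``expr_gain`` couples expression level to the same Hill fraction
    (chaperones stabilize the mutant, raising its steady-state level): at a
    saturating dose expression is (1 + expr_gain) times the vehicle level.
    """

    theta_min: float = 0.15
    theta_max: float = 0.85
    ec50_uM: float = 0.17
    hill: float = 2.0
    tox_dose_uM: float = math.inf
    expr_gain: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.theta_min <= 1 and 0 <= self.theta_max <= 1):
            raise ValidationError("theta bounds must be in [0, 1]")
        if self.theta_min > self.theta_max:
            raise ValidationError("theta_min must be <= theta_max")
        if self.ec50_uM <= 0 or self.hill <= 0 or self.tox_dose_uM <= 0:
            raise ValidationError("ec50_uM, hill and tox_dose_uM must be positive")


ZERO_EFFECT_MODEL = DoseResponseModel()


@dataclass
class FieldGroundTruth:
    n_nuclei: int
    nucleus_centroids: list
    total_gfp_in_puncta: float
    total_gfp_in_reticulum: float
    cell_mask_area_px: int

    def __post_init__(self) -> None:
        if self.n_nuclei != len(self.nucleus_centroids):
            raise ValidationError("n_nuclei must match the centroid list")

    @property
    def puncta_fraction(self) -> float:
        total = self.total_gfp_in_puncta + self.total_gfp_in_reticulum
        return self.total_gfp_in_puncta / total if total > 0 else float("nan")


def hill_fraction(dose_uM: float, model: DoseResponseModel) -> float:
    """Occupancy fraction d^h / (d^h + ec50^h), 0 at dose 0."""
    if dose_uM < 0:
        raise ValidationError("dose must be non-negative")
    if dose_uM == 0:
        return 0.0
    if math.isinf(dose_uM):
        return 1.0
    dh = dose_uM ** model.hill
    return dh / (dh + model.ec50_uM ** model.hill)


def theta_from_dose(dose_uM: float, model: DoseResponseModel) -> float:
    """Hill response: theta_min + range * d^h / (d^h + ec50^h)."""
    return model.theta_min + (model.theta_max - model.theta_min) * \
        hill_fraction(dose_uM, model)


def expected_cells(n_cells: int, dose_uM: float, model: DoseResponseModel) -> int:
    """Cell count thinned by the saturable toxicity term dose/(dose+tox)."""
    if math.isinf(model.tox_dose_uM):
        return n_cells
    survive = 1.0 - dose_uM / (dose_uM + model.tox_dose_uM)
    return int(round(n_cells * survive))


def field_seed(master_seed: int, plate: str, well: str, fld: int) -> int:
    """Stable 31-bit per-field seed derived from the master seed."""
    key = f"{master_seed}|{plate}|{well}|{fld}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


# geometry helpers -----------------------------------------------------------

def _place_nuclei(rng: np.random.Generator, n: int, height: int, width: int,
                  margin: int, min_sep: float):
    """Dart-throwing placement with a minimum centre separation."""
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = max(200 * n, 1000)
    while len(centers) < n and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(margin, height - margin)
        c = rng.uniform(margin, width - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep ** 2 for r0, c0 in centers):
            centers.append((r, c))
    if len(centers) < n:
        raise ValidationError(
            f"field {height}x{width} too small to place {n} cells "
            f"(min separation {min_sep} px)")
    return centers


def _add_ellipse(canvas: np.ndarray, center, area: float, aspect: float,
                 angle: float, intensity: float) -> None:
    r0, c0 = center
    b = math.sqrt(area / math.pi / aspect)   # semi-minor
    a = b * aspect                            # semi-major
    ext = int(math.ceil(a)) + 1
    rr = np.arange(max(0, int(r0) - ext), min(canvas.shape[0], int(r0) + ext + 1))
    cc = np.arange(max(0, int(c0) - ext), min(canvas.shape[1], int(c0) + ext + 1))
    if rr.size == 0 or cc.size == 0:
        return
    R, C = np.meshgrid(rr - r0, cc - c0, indexing="ij")
    u = R * math.cos(angle) + C * math.sin(angle)
    v = -R * math.sin(angle) + C * math.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[np.ix_(rr, cc)] += intensity * inside


def _add_gaussian_spot(canvas: np.ndarray, center, sigma: float,
                       total: float) -> float:
    """Add a Gaussian spot normalized (after border clipping) to ``total``.
    Returns the mass actually deposited."""
    r0, c0 = center
    ext = int(math.ceil(4 * sigma))
    rr = np.arange(max(0, int(r0) - ext), min(canvas.shape[0], int(r0) + ext + 1))
    cc = np.arange(max(0, int(c0) - ext), min(canvas.shape[1], int(c0) + ext + 1))
    if rr.size == 0 or cc.size == 0:
        return 0.0
    R, C = np.meshgrid(rr - r0, cc - c0, indexing="ij")
    g = np.exp(-(R ** 2 + C ** 2) / (2 * sigma ** 2))
    s = g.sum()
    if s <= 0:
        return 0.0
    canvas[np.ix_(rr, cc)] += g * (total / s)
    return total


def _filament_trail(rng: np.random.Generator, center, r_start: float,
                    r_max: float, height: int, width: int,
                    n_walks: int = 4, steps: int = 180) -> np.ndarray:
    """Persistent random walks anchored around a nucleus; returns (m, 2) int
    pixel coordinates of the visited trail (confined to the field)."""
    r0, c0 = center
    pts = []
    for _ in range(n_walks):
        ang = rng.uniform(0, 2 * math.pi)
        pos = np.array([r0 + r_start * math.sin(ang), c0 + r_start * math.cos(ang)])
        direction = rng.uniform(0, 2 * math.pi)
        for _ in range(steps):
            direction += rng.normal(0.0, 0.45)
            pos = pos + 1.4 * np.array([math.sin(direction), math.cos(direction)])
            d = math.hypot(pos[0] - r0, pos[1] - c0)
            if d > r_max or not (1 <= pos[0] < height - 1 and 1 <= pos[1] < width - 1):
                # steer back toward the cell centre
                direction = math.atan2(r0 - pos[0], c0 - pos[1]) + rng.normal(0, 0.3)
                pos[0] = min(max(pos[0], 1.0), height - 2.0)
                pos[1] = min(max(pos[1], 1.0), width - 2.0)
            pts.append((int(round(pos[0])), int(round(pos[1]))))
    arr = np.array(pts, dtype=np.intp)
    arr[:, 0] = np.clip(arr[:, 0], 1, height - 2)
    arr[:, 1] = np.clip(arr[:, 1], 1, width - 2)
    return arr


def _render_reticulum(canvas: np.ndarray, rng: np.random.Generator, center,
                      r_nuc: float, r_cell: float, total: float) -> np.ndarray:
    """Deposit ``total`` signal as dilated filaments plus a diffuse haze.
    Returns the filament trail coordinates (used to anchor puncta)."""
    h, w = canvas.shape
    pts = _filament_trail(rng, center, 0.8 * r_nuc, r_cell, h, w)
    if total <= 0:
        return pts
    diffuse_total = RETICULUM_DIFFUSE_FRACTION * total
    filament_total = total - diffuse_total
    rmin, rmax = pts[:, 0].min(), pts[:, 0].max()
    cmin, cmax = pts[:, 1].min(), pts[:, 1].max()
    local = np.zeros((rmax - rmin + 3, cmax - cmin + 3))
    np.add.at(local, (pts[:, 0] - rmin + 1, pts[:, 1] - cmin + 1), 1.0)
    # dilate the trail to a 2-3 px wide ribbon, then soften
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=np.float64)
    local = ndi.convolve(np.minimum(local, 1.0), cross, mode="constant")
    local = ndi.gaussian_filter(local, sigma=0.6, mode="constant")
    s = local.sum()
    if s > 0:
        canvas[rmin - 1:rmax + 2, cmin - 1:cmax + 2] += local * (filament_total / s)
    else:
        diffuse_total = total
    _add_gaussian_spot(canvas, center, 0.45 * r_cell, diffuse_total)
    return pts


def render_field(params: PhenotypeParams, height: int = 512, width: int = 512,
                 seed: int = 0, min_sep_px: float = 46.0, margin_px: int = 52,
                 cell_states: list | None = None):
    """Render one synthetic (GFP, Hoechst) field pair.

    Returns ``(gfp, hoechst, truth)``.  Per-cell GFP signal
    (expression_scale * UNIT_SIGNAL) is split as (1 - theta) into the
    reticular component and theta into ``puncta_per_cell`` Gaussian puncta
    scattered in a perinuclear annulus; i.i.d. Gaussian noise is added and
    the image clipped to [0, 1].  Ground-truth totals are pre-noise,
    pre-clip.

    ``cell_states`` optionally assigns each cell its own
    ``(theta, expression_scale)`` pair (cell-to-cell response
    heterogeneity); by default every cell uses the field-level parameters.
    """
    if height < 256 or width < 256:
        raise ValidationError("render_field requires height, width >= 256")
    if cell_states is not None and len(cell_states) != params.n_cells:
        raise ValidationError("cell_states must have one entry per cell")
    rng = np.random.default_rng(seed)
    gfp = np.zeros((height, width))
    hoechst = np.zeros((height, width))
    cell_mask = np.zeros((height, width), dtype=bool)

    centers = _place_nuclei(rng, params.n_cells, height, width,
                            margin_px, min_sep_px)
    total_puncta = 0.0
    total_reticulum = 0.0
    for i, (r0, c0) in enumerate(centers):
        theta_i, expr_i = (cell_states[i] if cell_states is not None
                           else (params.theta, params.expression_scale))
        s_cell = expr_i * UNIT_SIGNAL
        nuc_area = rng.uniform(2000.0, 5000.0)
        aspect = rng.uniform(1.0, 1.3)
        angle = rng.uniform(0, math.pi)
        _add_ellipse(hoechst, (r0, c0), nuc_area, aspect, angle,
                     rng.uniform(0.55, 0.8))
        r_nuc = math.sqrt(nuc_area / math.pi)
        r_cell = r_nuc + 22.0

        ret_total = (1.0 - theta_i) * s_cell
        trail = _render_reticulum(gfp, rng, (r0, c0), r_nuc, r_cell, ret_total)
        total_reticulum += ret_total

        # puncta bud along the perinuclear ER network: anchor each spot at a
        # jittered filament-trail point so vesicles sit in the same annulus
        # the reticulum occupies
        per_punctum = theta_i * s_cell / params.puncta_per_cell
        for _ in range(params.puncta_per_cell):
            anchor = trail[rng.integers(0, len(trail))]
            pr = float(anchor[0]) + rng.normal(0.0, 2.0)
            pc = float(anchor[1]) + rng.normal(0.0, 2.0)
            total_puncta += _add_gaussian_spot(gfp, (pr, pc),
                                               params.puncta_radius_px, per_punctum)
        rr, cc = np.ogrid[:height, :width]
        cell_mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= r_cell ** 2

    truth = FieldGroundTruth(
        n_nuclei=len(centers),
        nucleus_centroids=[(float(r), float(c)) for r, c in centers],
        total_gfp_in_puncta=float(total_puncta),
        total_gfp_in_reticulum=float(total_reticulum),
        cell_mask_area_px=int(cell_mask.sum()),
    )
    if params.noise_sd > 0:
        gfp = gfp + rng.normal(0.0, params.noise_sd, gfp.shape)
        hoechst = hoechst + rng.normal(0.0, params.noise_sd, hoechst.shape)
    gfp_img = ImageField(np.clip(gfp, 0.0, 1.0), Channel.GFP)
    hoechst_img = ImageField(np.clip(hoechst, 0.0, 1.0), Channel.HOECHST)
    return gfp_img, hoechst_img, truth


def render_filipin_field(accum_fraction: float, n_cells: int, seed: int = 0,
                         height: int = 512, width: int = 512):
    """Render a filipin-style field: near-zero background, moderate diffuse
    cytoplasm, and bright puncta carrying ``accum_fraction`` of each cell's
    filipin signal."""
    if not 0.0 <= accum_fraction <= 1.0:
        raise ValidationError("accum_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    img = np.zeros((height, width))
    cell_mask = np.zeros((height, width), dtype=bool)
    centers = _place_nuclei(rng, n_cells, height, width, margin=48,
                            min_sep=70.0) if n_cells else []
    total_puncta = 0.0
    total_diffuse = 0.0
    for (r0, c0) in centers:
        r_cell = rng.uniform(32.0, 46.0)
        rr, cc = np.ogrid[:height, :width]
        disk_mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= r_cell ** 2
        cell_mask |= disk_mask
        area = disk_mask.sum()
        diffuse = (1.0 - accum_fraction) * FILIPIN_UNIT
        img[disk_mask] += FILIPIN_CELL_BASE + diffuse / area
        total_diffuse += diffuse
        # accumulation recruits more (similarly bright) LE/L puncta rather
        # than brightening a fixed set, so the puncta population stays well
        # above the cytoplasm population even at low accumulation
        n_puncta = int(round(18 * accum_fraction))
        if accum_fraction > 0 and n_puncta == 0:
            n_puncta = 1
        if n_puncta > 0:
            per_punctum = accum_fraction * FILIPIN_UNIT / n_puncta
            for _ in range(n_puncta):
                rad = rng.uniform(0.15, 0.8) * r_cell
                ang = rng.uniform(0, 2 * math.pi)
                total_puncta += _add_gaussian_spot(
                    img, (r0 + rad * math.sin(ang), c0 + rad * math.cos(ang)),
                    2.2, per_punctum)
    truth = FieldGroundTruth(
        n_nuclei=len(centers),
        nucleus_centroids=[(float(r), float(c)) for r, c in centers],
        total_gfp_in_puncta=float(total_puncta),
        total_gfp_in_reticulum=float(total_diffuse),
        cell_mask_area_px=int(cell_mask.sum()),
    )
    img = img + rng.normal(0.0, 0.015, img.shape)
    return ImageField(np.clip(img, 0.0, 1.0), Channel.FILIPIN), truth


# plate-scale generation -----------------------------------------------------

@dataclass(frozen=True)
class WellCondition:
    """Rendering condition for one well: the field-expected parameters plus
    the Hill occupancy (fraction of responding cells) and its model."""

    params: PhenotypeParams
    theta: float
    responder_fraction: float
    model: DoseResponseModel


def well_phenotype(treatment: str, dose_uM: float, role: str,
                   models: dict[str, DoseResponseModel],
                   base: PhenotypeParams) -> WellCondition:
    """Map a layout well to its rendering condition.

    Vehicle and blank wells fall back to a zero-effect model at dose 0; any
    other role requires a model for its treatment.
    """
    if role in (Role.VEHICLE.value, Role.BLANK.value):
        model = models.get(treatment, ZERO_EFFECT_MODEL)
        dose = 0.0
    else:
        if treatment not in models:
            raise ValidationError(f"no dose-response model for treatment {treatment!r}")
        model = models[treatment]
        dose = dose_uM
    frac = hill_fraction(dose, model)
    theta = theta_from_dose(dose, model)
    expr = base.expression_scale * (1.0 + model.expr_gain * frac)
    params = PhenotypeParams(theta=theta,
                             expression_scale=expr,
                             n_cells=expected_cells(base.n_cells, dose, model),
                             puncta_per_cell=base.puncta_per_cell,
                             puncta_radius_px=base.puncta_radius_px,
                             noise_sd=base.noise_sd)
    return WellCondition(params, theta, frac, model)


def sample_cell_states(cond: WellCondition, base: PhenotypeParams,
                       rng: np.random.Generator) -> list:
    """Draw per-cell (theta, expression) pairs for one field.

    Cells respond to the compound all-or-none (the usual picture for
    pharmacological chaperones at sub-saturating dose): a cell converts to
    the punctate phenotype with probability equal to the Hill occupancy,
    trafficking its GFP to puncta (theta_max) at elevated expression; the
    rest keep the vehicle phenotype.  The field-level expectation matches
    the Hill dose-response curves for both theta and expression.
    """
    model = cond.model
    n = cond.params.n_cells
    responder = rng.random(n) < cond.responder_fraction
    lo = (model.theta_min, base.expression_scale)
    hi = (model.theta_max, base.expression_scale * (1.0 + model.expr_gain))
    return [hi if r else lo for r in responder]


def generate_plate(layout: PlateLayout, models: dict[str, DoseResponseModel],
                   base: PhenotypeParams, seed: int, out_dir: str | os.PathLike,
                   height: int = 512, width: int = 512):
    """Render every field of a layout to TIFFs plus a ground-truth CSV.

    Vehicle and blank wells fall back to a zero-effect model (theta at
    theta_min); any other treatment must have an entry in ``models``.
    Returns ``(layout_with_paths, truth_table)``.
    """
    os.makedirs(out_dir, exist_ok=True)
    df = layout.table.copy()
    truths = []
    new_paths = {}
    for (plate, well, fld), sub in df.groupby(["plate", "well", "field"], sort=True):
        meta = sub.iloc[0]
        cond = well_phenotype(meta["treatment"], float(meta["dose_uM"]),
                              meta["role"], models, base)
        fseed = field_seed(seed, str(plate), str(well), int(fld))
        states = sample_cell_states(cond, base, np.random.default_rng((fseed, 1)))
        gfp, hoechst, truth = render_field(cond.params, height, width,
                                           seed=fseed, cell_states=states)
        theta = cond.theta
        for channel, img in ((Channel.GFP, gfp), (Channel.HOECHST, hoechst)):
            fname = f"{plate}_{well}_f{fld}_{channel.value}.tif"
            write_field_image(os.path.join(out_dir, fname), img.pixels)
            new_paths[(plate, well, fld, channel.value)] = fname
        truths.append({"plate": plate, "well": well, "field": fld,
                       "theta": theta, "n_nuclei": truth.n_nuclei,
                       "total_gfp_in_puncta": truth.total_gfp_in_puncta,
                       "total_gfp_in_reticulum": truth.total_gfp_in_reticulum,
                       "cell_mask_area_px": truth.cell_mask_area_px})
    df["path"] = [
        new_paths.get((r["plate"], r["well"], r["field"], r["channel"]), r["path"])
        for _, r in df.iterrows()
    ]
    out_layout = PlateLayout(df, max_fields=layout.max_fields)
    truth_df = pd.DataFrame(truths)
    out_layout.to_csv(os.path.join(out_dir, "layout.csv"))
    truth_df.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return out_layout, truth_df


# layout builders ------------------------------------------------------------

def _well_rows(plate: str, well: str, n_fields: int, treatment: str,
               dose: float, role: str) -> list[dict]:
    rows = []
    for fld in range(1, n_fields + 1):
        for ch in (Channel.GFP.value, Channel.HOECHST.value):
            rows.append({"plate": plate, "well": well, "field": fld,
                         "channel": ch, "path": "", "treatment": treatment,
                         "dose_uM": dose, "role": role})
    return rows


def _well_ids(n: int, start: int = 0) -> list[str]:
    ids = []
    for i in range(start, start + n):
        ids.append(f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}")
    return ids


def qc_plate_layout(n_vehicle: int = 8, n_positive: int = 8,
                    n_fields: int = 6, plate_id: str = "QC1",
                    positive_dose_uM: float = 3.0,
                    treatment: str = "mo56HC") -> PlateLayout:
    """Assay-quality plate: vehicle wells vs. positive-control wells at a
    saturating dose of the control chaperone."""
    rows = []
    wells = _well_ids(n_vehicle + n_positive)
    for w in wells[:n_vehicle]:
        rows += _well_rows(plate_id, w, n_fields, "DMSO", 0.0, Role.VEHICLE.value)
    for w in wells[n_vehicle:]:
        rows += _well_rows(plate_id, w, n_fields, treatment,
                          positive_dose_uM, Role.POSITIVE_CONTROL.value)
    return PlateLayout(pd.DataFrame(rows, columns=LAYOUT_COLUMNS), max_fields=n_fields)


def screen_layout(n_plates: int = 4, vehicles_per_plate: int = 15,
                  blanks_per_plate: int = 4, library_per_plate: int = 0,
                  control_doses=(0.3, 3.0), marginal_dose_uM: float = 0.03,
                  duplicates: int = 2, n_fields: int = 6,
                  treatment: str = "mo56HC") -> PlateLayout:
    """Screen-style layout: vehicles and blanks (the negative controls) plus
    a duplicate positive-control dose series and duplicate marginally active
    control wells on every plate."""
    rows = []
    for p in range(1, n_plates + 1):
        plate = f"P{p}"
        idx = 0
        wells = _well_ids(vehicles_per_plate + blanks_per_plate + library_per_plate
                          + duplicates * (len(control_doses) + 1))
        for _ in range(vehicles_per_plate):
            rows += _well_rows(plate, wells[idx], n_fields, "DMSO", 0.0,
                               Role.VEHICLE.value)
            idx += 1
        for _ in range(blanks_per_plate):
            rows += _well_rows(plate, wells[idx], n_fields, "none", 0.0,
                               Role.BLANK.value)
            idx += 1
        for i in range(library_per_plate):
            rows += _well_rows(plate, wells[idx], n_fields, f"lib{p}_{i:03d}",
                               10.0, Role.LIBRARY.value)
            idx += 1
        for _ in range(duplicates):
            rows += _well_rows(plate, wells[idx], n_fields, treatment,
                               marginal_dose_uM, Role.MARGINAL_POSITIVE.value)
            idx += 1
        for dose in control_doses:
            for _ in range(duplicates):
                rows += _well_rows(plate, wells[idx], n_fields, treatment,
                                   dose, Role.POSITIVE_CONTROL.value)
                idx += 1
    return PlateLayout(pd.DataFrame(rows, columns=LAYOUT_COLUMNS), max_fields=n_fields)
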