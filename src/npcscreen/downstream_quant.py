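"""Filipin cholesterol-accumulation quantification and GFP-marker
colocalization, with their group-comparison statistics.

Filipin images carry three intensity populations: background (no cells),
moderate diffuse in-cell signal, and bright cholesterol-laden puncta.  A
seeded pixel subsample pooled across images is partitioned by 1-D k-means
(k = 3, quantile-initialized, deterministic); the lower threshold is the
midpoint of the background and cell cluster means, the higher threshold the
midpoint of the cell and puncta means.  The readout per image is the
relative filipin intensity: summed intensity over puncta pixels divided by
summed intensity over cell pixels.

Colocalization is a per-image Pearson correlation of the two channels over
cell-mask pixels (Spearman available).  Group comparisons follow either a
Kruskal-Wallis omnibus with Dunn's pairwise z tests and Benjamini-Hochberg
adjustment, or Dunnett's two-sided many-to-one comparison with Shapiro-Wilk
and Bartlett preconditions reported (never enforced as gates).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io_plate import ImageField, ValidationError


class DegenerateClusteringError(ValueError):
    """Fewer distinct intensity values than clusters requested."""


@dataclass(frozen=True)
class FilipinThresholds:
    """Cluster means (ascending) and the two midpoints separating them."""

    cluster_means: tuple[float, float, float]
    lower_threshold: float
    higher_threshold: float

    def __post_init__(self) -> None:
        bg, cell, puncta = self.cluster_means
        if not (bg < self.lower_threshold < cell <
                self.higher_threshold < puncta):
            raise ValidationError(
                "thresholds must interleave the ascending cluster means")


@dataclass
class FilipinResult:
    relative_filipin: float
    cell_area_px: int
    puncta_area_px: int
    qc: str = "ok"


def filipin_cluster_thresholds(images: list[ImageField], k: int = 3,
                               subsample: int = 50000,
                               seed: int = 0) -> FilipinThresholds:
    """Derive intensity thresholds from a pooled, seeded pixel subsample.

    The subsample is clustered by 1-D k-means with deterministic quantile
    initialization; thresholds are the arithmetic midpoints of adjacent
    cluster means.
    """
    if not images:
        raise ValidationError("need at least one image")
    if subsample < 10 * k:
        raise ValidationError(f"subsample must be >= {10 * k}")
    rng = np.random.default_rng(seed)
    pools = []
    per_image = max(subsample // len(images), 1)
    for img in images:
        flat = img.pixels.ravel()
        take = min(per_image, flat.size)
        pools.append(rng.choice(flat, size=take, replace=False))
    sample = np.concatenate(pools)
    if np.unique(sample).size < k:
        raise DegenerateClusteringError(
            f"fewer than {k} distinct intensity values in the subsample")
    init = np.quantile(sample, np.linspace(0.1, 0.9, k))[:, None]
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300)
    km.fit(sample[:, None])
    means = np.sort(km.cluster_centers_.ravel())
    return FilipinThresholds(
        cluster_means=tuple(float(m) for m in means),
        lower_threshold=float((means[0] + means[1]) / 2.0),
        higher_threshold=float((means[1] + means[2]) / 2.0),
    )


def relative_filipin_intensity(img: ImageField,
                               t: FilipinThresholds) -> FilipinResult:
    """Fraction of in-cell filipin intensity lying in bright puncta.

    The image is lightly smoothed (disc mean filter, diameter 3) to
    suppress salt noise before thresholding; the cell region is every pixel
    above the lower threshold, the puncta region every cell pixel above the
    higher threshold.  Intensities summed are the smoothed ones, so the
    readout is invariant to a uniform gain applied jointly to image and
    thresholds.
    """
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=np.float64)
    sm = ndi.convolve(img.pixels, cross / cross.sum(), mode="nearest")
    cell = sm > t.lower_threshold
    puncta = cell & (sm > t.higher_threshold)
    cell_area = int(cell.sum())
    if cell_area == 0:
        return FilipinResult(float("nan"), 0, 0, qc="no_cells")
    total = float(sm[cell].sum())
    in_puncta = float(sm[puncta].sum())
    return FilipinResult(in_puncta / total, cell_area, int(puncta.sum()))


def coloc_correlation(gfp: ImageField, marker: ImageField,
                      cells: np.ndarray, method: str = "pearson") -> float:
    """Correlation of two channels' intensities over cell-mask pixels.

    Returns NaN when either channel has zero variance within the mask.
    """
    if gfp.pixels.shape != marker.pixels.shape or gfp.pixels.shape != cells.shape:
        raise ValidationError("image and mask shapes differ")
    if int(np.count_nonzero(cells)) < 100:
        raise ValidationError("cell mask must cover >= 100 px")
    a = gfp.pixels[cells]
    b = marker.pixels[cells]
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValidationError("method must be 'pearson' or 'spearman'")


@dataclass
class GroupComparison:
    method: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame
    preconditions: pd.DataFrame | None = None


def _dunn_pairwise(values_by_group: dict) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with tie correction and BH
    adjustment of the two-sided p values."""
    names = list(values_by_group)
    all_vals = np.concatenate([np.asarray(values_by_group[g], float) for g in names])
    n_total = all_vals.size
    ranks = stats.rankdata(all_vals)
    mean_ranks = {}
    start = 0
    for g in names:
        n_g = len(values_by_group[g])
        mean_ranks[g] = ranks[start:start + n_g].mean()
        start += n_g
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        n1, n2 = len(values_by_group[g1]), len(values_by_group[g2])
        se = np.sqrt(var_base * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"].values, method="fdr_bh")[1]
    return df


def compare_groups(values_by_group: dict, method: str = "kruskal_dunn_bh",
                   control: str | None = None) -> GroupComparison:
    """Compare >= 2 groups of per-image measurements.

    ``kruskal_dunn_bh``: Kruskal-Wallis omnibus plus Dunn's pairwise z
    tests with Benjamini-Hochberg-adjusted p values.  ``dunnett``:
    two-sided Dunnett many-to-one comparison against ``control`` (defaults
    to the first group), with Shapiro-Wilk and Bartlett precondition tests
    reported alongside.
    """
    if len(values_by_group) < 2:
        raise ValidationError("need >= 2 groups")
    for g, v in values_by_group.items():
        if len(v) < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 values")
    arrays = {g: np.asarray(v, dtype=np.float64) for g, v in values_by_group.items()}
    if all(a.std() == 0.0 for a in arrays.values()) and \
            np.unique(np.concatenate(list(arrays.values()))).size == 1:
        raise ValidationError("all values identical; rank test undefined")

    if method == "kruskal_dunn_bh":
        stat, p = stats.kruskal(*arrays.values())
        return GroupComparison("kruskal_dunn_bh", float(stat), float(p),
                               _dunn_pairwise(arrays))
    if method == "dunnett":
        names = list(arrays)
        control = control if control is not None else names[0]
        if control not in arrays:
            raise ValidationError(f"control group {control!r} not found")
        treatments = [g for g in names if g != control]
        res = stats.dunnett(*[arrays[g] for g in treatments],
                            control=arrays[control], alternative="two-sided")
        pairwise = pd.DataFrame({
            "group": treatments, "control": control,
            "statistic": res.statistic, "p_adj": res.pvalue,
        })
        pre_rows = []
        for g, a in arrays.items():
            sw = stats.shapiro(a)
            pre_rows.append({"test": "shapiro_wilk", "group": g,
                             "statistic": float(sw.statistic), "p": float(sw.pvalue)})
        bart = stats.bartlett(*arrays.values())
        pre_rows.append({"test": "bartlett", "group": "all",
                         "statistic": float(bart.statistic), "p": float(bart.pvalue)})
        f_stat, f_p = stats.f_oneway(*arrays.values())
        return GroupComparison("dunnett", float(f_stat), float(f_p),
                               pairwise, pd.DataFrame(pre_rows))
    raise ValidationError("method must be 'kruskal_dunn_bh' or 'dunnett'")
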