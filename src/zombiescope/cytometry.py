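"""Image cytometry: detection, gating and classification of FISH signals.

Implements the counting rules of the zombie-cell assay on three-channel
fields (DNA / 16S rRNA / phage gene):

* total cells   — DNA-positive objects of cellular size
* SAR11 cells   — overlapping DNA and 16S rRNA signal
* infected      — SAR11 cells with an additional phage signal
* zombie        — DNA-positive, phage-positive cells *without* 16S rRNA,
                  larger than the free-phage size gate (zombies contain DNA
                  and are too large to be individual phage particles)
* free phage / vesicles — phage-positive objects at or below the size gate
* dividing      — cells with exactly two local DNA maxima (FDC numerator)

Objects are 8-connected components of the union of per-channel threshold
masks; thresholds default to modal background + k robust sigma (MAD-based).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .synthetic_imaging import CHANNELS, FieldImage, SceneSpec, render_field

LABELS = ("total_only", "sar11", "infected_sar11", "zombie",
          "free_phage_or_vesicle", "rejected")


@dataclass(frozen=True)
class GateConfig:
    """Detection and gating settings.

    Area gates are in µm² of thresholded support.  ``free_phage_max_area``
    defaults to 0.05 µm² (equivalent diameter ~0.25 µm, far above phage
    capsid size); use :func:`calibrate_gates` to size the gates to a scene's
    optics, since PSF blur inflates measured supports.
    """

    threshold_mode: str = "robust"           # "robust" | "absolute"
    k_sigma: float = 5.0
    #: floor on the threshold offset above modal background; guards the
    #: zero-noise degenerate case where the robust sigma collapses to 0.
    min_threshold_offset: float = 2.0
    absolute_thresholds: dict | None = None  # per-channel, "absolute" mode
    connectivity: int = 2                    # skimage convention: 2 == 8-conn
    min_cell_area: float = 0.06
    max_cell_area: float = 50.0
    free_phage_max_area: float = 0.05
    positivity: str = "mean"                 # "mean" | "max"
    maxima_smooth_sigma_px: float = 1.0
    maxima_prominence: float = 10.0
    #: interpret the rRNA channel as an all-bacteria (EUB I-III) probe:
    #: gating logic is unchanged, but "sar11" counts then mean "bacteria
    #: with ribosomes"; used for the probe-specificity comparison.
    eub_mode: bool = False

    def validate(self) -> None:
        if self.threshold_mode not in ("robust", "absolute"):
            raise ValueError("threshold_mode must be 'robust' or 'absolute'")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if not 0 < self.free_phage_max_area < self.min_cell_area < self.max_cell_area:
            raise ValueError(
                "need 0 < free_phage_max_area < min_cell_area < max_cell_area")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
        if self.positivity not in ("mean", "max"):
            raise ValueError("positivity must be 'mean' or 'max'")

    def replace(self, **kwargs) -> "GateConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CellObject:
    """One segmented connected component with per-channel statistics."""

    id: int
    mask: np.ndarray           # bool, bbox-local
    bbox: tuple[int, int, int, int]   # (y0, x0, y1, x1)
    area: float                # µm²
    equivalent_diameter: float  # µm
    centroid: tuple[float, float]
    mean_intensity: dict[str, float]
    max_intensity: dict[str, float]
    positive: dict[str, bool]
    dna_maxima_count: int = -1   # filled on demand
    label: str | None = None


@dataclass
class CytometryResult:
    """Pooled counts and the study's derived relative abundances.

    Derived ratios use the published denominators: infected / SAR11,
    zombie / total, SAR11 / total, dividing / total.  A ratio whose
    denominator is zero is NaN and flagged in ``undefined``.
    """

    total_cells: int
    sar11_cells: int
    infected_cells: int
    zombie_cells: int
    dividing_cells: int
    total_only_cells: int
    free_phage_objects: int
    rejected_objects: int
    excluded_small_objects: int
    n_objects: int
    rel_infected: float
    rel_zombie: float
    rel_sar11: float
    fdc: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def estimate_threshold(plane: np.ndarray, cfg: GateConfig,
                       channel: str | None = None) -> float:
    """Per-channel detection threshold.

    Robust mode: modal background (median) + max(k * 1.4826*MAD,
    min_threshold_offset).  The median/MAD are taken over the whole plane;
    valid while objects cover a minority of pixels.
    """
    if cfg.threshold_mode == "absolute":
        if not cfg.absolute_thresholds or channel not in cfg.absolute_thresholds:
            raise ValueError(f"no absolute threshold configured for {channel!r}")
        return float(cfg.absolute_thresholds[channel])
    med = float(np.median(plane))
    sigma = 1.4826 * float(np.median(np.abs(plane - med)))
    return med + max(cfg.k_sigma * sigma, cfg.min_threshold_offset)


def segment_objects(field: FieldImage, cfg: GateConfig) -> list[CellObject]:
    """Segment connected components of the union of channel masks.

    Each object carries per-channel mean/max intensities over its mask and
    positivity flags (``mean`` rule by default: channel-positive when the
    mean intensity over the mask exceeds that channel's threshold).
    """
    cfg.validate()
    thresholds = {ch: estimate_threshold(field.channel(ch), cfg, ch)
                  for ch in CHANNELS}
    union = np.zeros(field.shape, dtype=bool)
    for ch in CHANNELS:
        union |= field.channel(ch) > thresholds[ch]
    if not union.any():
        return []
    lab = measure.label(union, connectivity=cfg.connectivity)
    objects: list[CellObject] = []
    px_area = field.pixel_size ** 2
    for region in measure.regionprops(lab):
        y0, x0, y1, x1 = region.bbox
        mask = region.image
        means, maxes, pos = {}, {}, {}
        for ch in CHANNELS:
            crop = field.channel(ch)[y0:y1, x0:x1][mask]
            means[ch] = float(crop.mean())
            maxes[ch] = float(crop.max())
            stat = means[ch] if cfg.positivity == "mean" else maxes[ch]
            pos[ch] = bool(stat > thresholds[ch])
        area = region.num_pixels * px_area
        objects.append(CellObject(
            id=int(region.label), mask=mask, bbox=(y0, x0, y1, x1),
            area=area,
            equivalent_diameter=float(np.sqrt(4.0 * area / np.pi)),
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
            mean_intensity=means, max_intensity=maxes, positive=pos,
        ))
    return objects


def classify_object(obj: CellObject, cfg: GateConfig) -> str:
    """Assign exactly one gating label to a segmented object.

    The partition follows the assay's definitions: SAR11 = DNA+rRNA;
    infected = DNA+rRNA+phage; zombie = DNA+phage without rRNA and larger
    than the free-phage size gate; phage-positive objects at or below the
    gate are free phage or vesicles; DNA-only objects of cellular size enter
    the total count only.
    """
    dna, rrna, phage = (obj.positive[ch] for ch in CHANNELS)
    small = obj.area <= cfg.free_phage_max_area
    if phage and small:
        return "free_phage_or_vesicle"
    if small:
        return "rejected"  # sub-cellular speck, excluded from totals
    if dna and rrna and phage:
        return "infected_sar11"
    if dna and rrna:
        return "sar11"
    if dna and phage and not rrna:
        return "zombie"
    if dna:
        return "total_only"
    return "rejected"


def classify_objects(objects: Iterable[CellObject], cfg: GateConfig) -> list[CellObject]:
    for obj in objects:
        obj.label = classify_object(obj, cfg)
    return list(objects)


def count_dna_maxima(obj: CellObject, dna_plane: np.ndarray,
                     cfg: GateConfig) -> int:
    """Number of local DNA maxima inside an object's mask.

    The DNA plane is Gaussian-smoothed, then h-maxima with
    ``h = maxima_prominence`` are extracted; plateau maxima merge into a
    single connected component, each of which counts once.  A cell with
    exactly two maxima is scored as dividing.
    """
    if not obj.mask.any():
        raise ValueError("empty object mask")
    pad = int(np.ceil(3 * cfg.maxima_smooth_sigma_px)) + 2
    y0, x0, y1, x1 = obj.bbox
    h, w = dna_plane.shape
    Y0, X0 = max(y0 - pad, 0), max(x0 - pad, 0)
    Y1, X1 = min(y1 + pad, h), min(x1 + pad, w)
    crop = dna_plane[Y0:Y1, X0:X1].astype(float)
    if cfg.maxima_smooth_sigma_px > 0:
        crop = ndimage.gaussian_filter(crop, cfg.maxima_smooth_sigma_px)
    hmax = morphology.h_maxima(crop, cfg.maxima_prominence)
    full_mask = np.zeros_like(crop, dtype=bool)
    full_mask[y0 - Y0:y1 - Y0, x0 - X0:x1 - X0] = obj.mask
    lab, n = ndimage.label(hmax)
    count = 0
    for i in range(1, n + 1):
        if np.any((lab == i) & full_mask):
            count += 1
    obj.dna_maxima_count = count
    return count


def _tabulate_counts(counts: dict, n_objects: int) -> CytometryResult:
    total = (counts["total_only"] + counts["sar11"]
             + counts["infected_sar11"] + counts["zombie"])
    sar11 = counts["sar11"] + counts["infected_sar11"]
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return CytometryResult(
        total_cells=total,
        sar11_cells=sar11,
        infected_cells=counts["infected_sar11"],
        zombie_cells=counts["zombie"],
        dividing_cells=counts["dividing"],
        total_only_cells=counts["total_only"],
        free_phage_objects=counts["free_phage_or_vesicle"],
        rejected_objects=counts["rejected"],
        excluded_small_objects=counts["free_phage_or_vesicle"] + counts["small_rejected"],
        n_objects=n_objects,
        rel_infected=ratio(counts["infected_sar11"], sar11, "rel_infected"),
        rel_zombie=ratio(counts["zombie"], total, "rel_zombie"),
        rel_sar11=ratio(sar11, total, "rel_sar11"),
        fdc=ratio(counts["dividing"], total, "fdc"),
        undefined=tuple(undefined),
    )


def tabulate(objects: Sequence[CellObject], cfg: GateConfig,
             dividing_cells: int | None = None) -> CytometryResult:
    """Pool labelled objects into counts and the published ratios.

    ``total_cells`` counts every DNA-positive object above the free-phage
    size gate; ``rel_infected`` divides by SAR11 (infected cells *are*
    SAR11 cells), ``rel_zombie`` and ``fdc`` divide by total cells.
    """
    counts = {lbl: 0 for lbl in LABELS}
    counts["small_rejected"] = 0
    for obj in objects:
        if obj.label is None:
            raise ValueError("objects must be classified before tabulation")
        counts[obj.label] += 1
        if obj.label == "rejected" and obj.area <= cfg.free_phage_max_area:
            counts["small_rejected"] += 1
    counts["dividing"] = int(dividing_cells or 0)
    return _tabulate_counts(counts, len(objects))


def analyze_field(field: FieldImage, cfg: GateConfig,
                  count_dividing: bool = True) -> tuple[list[CellObject], dict]:
    """Segment + classify one field; returns objects and a count dict."""
    objects = classify_objects(segment_objects(field, cfg), cfg)
    counts = {lbl: 0 for lbl in LABELS}
    counts["small_rejected"] = 0
    counts["dividing"] = 0
    cell_labels = ("total_only", "sar11", "infected_sar11", "zombie")
    for obj in objects:
        counts[obj.label] += 1
        if obj.label == "rejected" and obj.area <= cfg.free_phage_max_area:
            counts["small_rejected"] += 1
        if count_dividing and obj.label in cell_labels:
            if count_dna_maxima(obj, field.dna, cfg) == 2:
                counts["dividing"] += 1
    return objects, counts


def run_cytometry(fields: Sequence[FieldImage], cfg: GateConfig,
                  count_dividing: bool = True) -> CytometryResult:
    """Per-sample cytometry: pool object counts across fields, then derive
    ratios (the study records many fields of view per sample)."""
    if len(fields) == 0:
        raise ValueError("need at least one field")
    pooled = None
    n_objects = 0
    for field in fields:
        _, counts = analyze_field(field, cfg, count_dividing=count_dividing)
        n_objects += sum(counts[lbl] for lbl in LABELS)
        if pooled is None:
            pooled = counts
        else:
            for k, v in counts.items():
                pooled[k] += v
    return _tabulate_counts(pooled, n_objects)


def objects_to_frame(objects: Sequence[CellObject],
                     pixel_size: float) -> pd.DataFrame:
    rows = []
    for o in objects:
        row = {"id": o.id, "label": o.label, "y": o.centroid[0],
               "x": o.centroid[1], "area_um2": o.area,
               "equivalent_diameter_um": o.equivalent_diameter,
               "dna_maxima": o.dna_maxima_count}
        for ch in CHANNELS:
            row[f"mean_{ch}"] = o.mean_intensity[ch]
            row[f"max_{ch}"] = o.max_intensity[ch]
            row[f"{ch}_pos"] = o.positive[ch]
        rows.append(row)
    return pd.DataFrame(rows)


def calibrate_gates(spec: SceneSpec, cfg: GateConfig | None = None) -> GateConfig:
    """Size the area gates to a scene's optics.

    PSF blur dilates thresholded supports, so the free-phage/cell size gate
    must sit between the *measured* area of a blurred point source and that
    of the smallest blurred cell.  Renders one isolated free phage and one
    isolated minimum-diameter cell (noise-free) under the spec's optics,
    measures their thresholded areas, and places the gate at the geometric
    mean.  Thresholds themselves stay data-driven (robust mode).
    """
    cfg = cfg or GateConfig()
    tile = max(64, int(12 * max(spec.cell_diameter_range) / spec.pixel_size))

    def _measured_area(counts, diameter_range=None, free_phage=False):
        kw = dict(field_shape=(tile, tile), counts=counts, noise_sd=0.0,
                  seed=12345, dividing_fraction=0.0,
                  ribosome_continuum_fraction=0.0)
        if diameter_range is not None:
            kw["cell_diameter_range"] = diameter_range
        probe = spec.replace(**kw)
        field, _ = render_field(probe)
        meas_cfg = cfg.replace(free_phage_max_area=1e-9, min_cell_area=2e-9,
                               max_cell_area=1e9)
        objs = segment_objects(field, meas_cfg)
        if len(objs) != 1:
            raise RuntimeError("calibration render did not yield one object")
        return objs[0].area

    d_lo = spec.cell_diameter_range[0]
    a_phage = _measured_area({"free_phage": 1})
    a_cell = _measured_area({"uninfected_sar11": 1}, (d_lo, d_lo))
    gate = float(np.sqrt(a_phage * a_cell))
    return cfg.replace(free_phage_max_area=gate,
                       min_cell_area=max(0.8 * a_cell, 1.01 * gate),
                       max_cell_area=max(cfg.max_cell_area, 100 * a_cell))
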