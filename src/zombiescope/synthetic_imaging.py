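"""Ground-truthed synthetic multi-channel FISH fields.

Emulates epifluorescence fields of marine bacterioplankton hybridized with a
three-channel FISH stack: a DNA stain (DAPI analog), a 16S rRNA probe
(CARD-FISH analog, SAR11-specific by default), and a phage-gene probe
(direct-geneFISH analog).  Five object classes are rendered:

* ``uninfected_sar11`` — DNA + rRNA signal
* ``infected_sar11``   — DNA + rRNA + phage signal
* ``zombie``           — DNA + phage signal, no detectable rRNA
* ``other_bacteria``   — DNA only (rRNA optional for an all-bacteria probe)
* ``free_phage``       — phage signal only, sub-cellular size

Cells are axis-aligned ellipses; a configurable fraction is rendered as
dividing cells with two DNA foci inside one elongated envelope.  Optics are an
isotropic Gaussian point-spread function plus constant background and
additive Gaussian read noise clipped at zero.  Every rendered object is
recorded in a ground-truth table so downstream cytometry can be validated
object-by-object without any real microscopy data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

CHANNELS = ("dna", "rrna", "phage")

CELL_CLASSES = ("uninfected_sar11", "infected_sar11", "zombie", "other_bacteria")
OBJECT_CLASSES = CELL_CLASSES + ("free_phage",)

#: default mean amplitude (8-bit intensity units above background) per class
#: and channel; zero means the class carries no signal in that channel.
DEFAULT_AMPLITUDES: dict[str, dict[str, float]] = {
    "uninfected_sar11": {"dna": 160.0, "rrna": 140.0, "phage": 0.0},
    "infected_sar11": {"dna": 160.0, "rrna": 140.0, "phage": 120.0},
    "zombie": {"dna": 160.0, "rrna": 0.0, "phage": 120.0},
    "other_bacteria": {"dna": 160.0, "rrna": 0.0, "phage": 0.0},
    "free_phage": {"dna": 0.0, "rrna": 0.0, "phage": 120.0},
}


class PackingError(RuntimeError):
    """Objects could not be placed without violating the overlap budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one synthetic microscopy field.

    Lengths are in micrometres, intensities in arbitrary (8-bit scale)
    units.  ``counts`` maps each object class to the number of objects to
    render; ``dividing_fraction`` is the fraction of *cells* (all classes
    except free phage) drawn with two DNA foci.
    """

    field_shape: tuple[int, int] = (600, 600)
    pixel_size: float = 0.05
    counts: Mapping[str, int] = dc_field(
        default_factory=lambda: {c: 0 for c in OBJECT_CLASSES}
    )
    dividing_fraction: float = 0.0
    cell_diameter_range: tuple[float, float] = (0.4, 0.8)
    free_phage_diameter: float = 0.15
    channel_amplitudes: Mapping[str, Mapping[str, float]] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AMPLITUDES.items()}
    )
    background_level: float = 20.0
    noise_sd: float = 2.0
    psf_sigma: float = 0.1
    ribosome_continuum_fraction: float = 0.0
    other_bacteria_rrna_amplitude: float = 0.0
    #: extra clearance (px) added around each object when enforcing zero
    #: overlap; sized so PSF-dilated supports stay disjoint after threshold.
    extra_margin_px: float | None = None
    max_place_attempts: int = 2000
    seed: int = 0

    def count(self, cls: str) -> int:
        return int(self.counts.get(cls, 0))

    @property
    def n_objects(self) -> int:
        return sum(self.count(c) for c in OBJECT_CLASSES)

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    @property
    def margin_px(self) -> float:
        if self.extra_margin_px is not None:
            return self.extra_margin_px
        return 4.0 * self.psf_sigma_px + 1.0

    def validate(self) -> None:
        if len(self.field_shape) != 2 or min(self.field_shape) < 8:
            raise ValueError("field_shape must be (H, W) with H, W >= 8")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for cls in self.counts:
            if cls not in OBJECT_CLASSES:
                raise ValueError(f"unknown object class {cls!r}")
            if self.count(cls) < 0:
                raise ValueError(f"negative count for class {cls!r}")
        for frac_name in ("dividing_fraction", "ribosome_continuum_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must lie in [0, 1]")
        lo, hi = self.cell_diameter_range
        if not 0 < lo <= hi:
            raise ValueError("cell_diameter_range must satisfy 0 < lo <= hi")
        if not 0 < self.free_phage_diameter < lo:
            raise ValueError("free_phage_diameter must be positive and below "
                             "the minimum cell diameter")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background and noise must be non-negative")
        for cls, amps in self.channel_amplitudes.items():
            for ch, a in amps.items():
                if a < 0:
                    raise ValueError(f"negative amplitude for {cls}/{ch}")

    def replace(self, **kwargs) -> "SceneSpec":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["counts"] = dict(self.counts)
        d["channel_amplitudes"] = {k: dict(v) for k, v in self.channel_amplitudes.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SceneSpec":
        with open(path) as fh:
            d = json.load(fh)
        d["field_shape"] = tuple(d["field_shape"])
        d["cell_diameter_range"] = tuple(d["cell_diameter_range"])
        return cls(**d)


@dataclass
class FieldImage:
    """Three co-registered intensity planes plus the pixel size (µm/px)."""

    dna: np.ndarray
    rrna: np.ndarray
    phage: np.ndarray
    pixel_size: float

    def __post_init__(self):
        if not (self.dna.shape == self.rrna.shape == self.phage.shape):
            raise ValueError("channel planes must share one shape")
        for ch in CHANNELS:
            if np.any(self.channel(ch) < 0):
                raise ValueError("intensities must be non-negative")

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dna.shape

    def to_stack(self) -> np.ndarray:
        return np.stack([self.dna, self.rrna, self.phage])


def write_field(path, field: FieldImage, dtype: str = "uint8") -> None:
    """Write a field as a multi-page grayscale TIFF (one page per channel)."""
    info = np.iinfo(np.dtype(dtype))
    stack = np.clip(np.rint(field.to_stack()), info.min, info.max).astype(dtype)
    meta = {"channels": list(CHANNELS), "pixel_size_um": field.pixel_size}
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps(meta))


def read_field(path) -> FieldImage:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray().astype(float)
        meta = json.loads(tif.pages[0].description)
    order = meta["channels"]
    planes = {ch: stack[order.index(ch)] for ch in CHANNELS}
    return FieldImage(pixel_size=float(meta["pixel_size_um"]), **planes)


# ---------------------------------------------------------------------------
# rendering

_GT_COLUMNS = ["id", "label", "x", "y", "diameter_um", "dividing",
               "dna", "rrna", "phage"]


def _empty_ground_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=_GT_COLUMNS).astype(
        {"id": int, "x": float, "y": float, "diameter_um": float,
         "dividing": bool, "dna": bool, "rrna": bool, "phage": bool}
    )


def _place_objects(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping object geometry.

    Returns a list of dicts with center, semi-axes (px) and class label.
    Raises :class:`PackingError` when the overlap budget cannot be met.
    """
    h, w = spec.field_shape
    margin = spec.margin_px
    lo_px = spec.cell_diameter_range[0] / spec.pixel_size
    hi_px = spec.cell_diameter_range[1] / spec.pixel_size
    placed: list[dict] = []
    centers = np.empty((0, 2))
    radii = np.empty((0,))

    order: list[str] = []
    for cls in OBJECT_CLASSES:
        order.extend([cls] * spec.count(cls))

    for idx, cls in enumerate(order):
        if cls == "free_phage":
            a = b = 0.5 * spec.free_phage_diameter / spec.pixel_size
            dividing = False
        else:
            dividing = bool(rng.random() < spec.dividing_fraction)
            if dividing:
                # pre-division cells sit in the upper half of the size range
                d = rng.uniform(0.5 * (lo_px + hi_px), hi_px)
            else:
                d = rng.uniform(lo_px, hi_px)
            aspect = rng.uniform(1.0, 1.25)
            a, b = 0.5 * d * aspect, 0.5 * d / aspect
            if dividing:
                a *= 1.6  # septating cells are elongated
        r_ex = max(a, b) + margin
        if 2 * r_ex >= min(h, w):
            raise PackingError("object exclusion zone exceeds the field")
        for _ in range(spec.max_place_attempts):
            cy = rng.uniform(r_ex, h - 1 - r_ex)
            cx = rng.uniform(r_ex, w - 1 - r_ex)
            if centers.shape[0]:
                d2 = (centers[:, 0] - cy) ** 2 + (centers[:, 1] - cx) ** 2
                if np.any(d2 < (radii + r_ex) ** 2):
                    continue
            break
        else:
            raise PackingError(
                f"could not place object {idx} ({cls}) after "
                f"{spec.max_place_attempts} attempts — field too crowded"
            )
        centers = np.vstack([centers, [cy, cx]])
        radii = np.append(radii, r_ex)
        placed.append(dict(id=idx, label=cls, cy=cy, cx=cx, a=a, b=b,
                           dividing=dividing,
                           diameter_um=2 * np.sqrt(a * b) * spec.pixel_size))
    return placed


def _ellipse_mask(shape, cy, cx, a, b):
    y0, y1 = int(np.floor(cy - a - 1)), int(np.ceil(cy + a + 2))
    x0, x1 = int(np.floor(cx - a - 1)), int(np.ceil(cx + a + 2))
    y0, x0 = max(y0, 0), max(x0, 0)
    y1, x1 = min(y1, shape[0]), min(x1, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    return (slice(y0, y1), slice(x0, x1)), mask


def _render(spec: SceneSpec, rng: np.random.Generator, phage_active: bool):
    spec.validate()
    h, w = spec.field_shape
    amps_maps = {ch: np.zeros((h, w)) for ch in CHANNELS}
    placed = _place_objects(spec, rng)

    records = []
    det_equiv = 5.0 * spec.noise_sd  # threshold-equivalent rRNA amplitude
    for obj in placed:
        cls = obj["label"]
        amps = dict(spec.channel_amplitudes[cls])
        if cls == "other_bacteria" and spec.other_bacteria_rrna_amplitude > 0:
            amps["rrna"] = spec.other_bacteria_rrna_amplitude
        depleted = False
        if cls == "infected_sar11" and spec.ribosome_continuum_fraction > 0:
            if rng.random() < spec.ribosome_continuum_fraction:
                # partially depleted ribosome content: sub-threshold rRNA
                amps["rrna"] = rng.uniform(0.0, det_equiv)
                depleted = True
        sl, env = _ellipse_mask((h, w), obj["cy"], obj["cx"], obj["a"], obj["b"])
        for ch in CHANNELS:
            amp = amps.get(ch, 0.0)
            if ch == "phage" and not phage_active:
                amp = 0.0
            if amp <= 0:
                continue
            if ch == "dna" and obj["dividing"]:
                # dim DNA throughout the envelope plus two bright condensed
                # nucleoid foci along the long axis: keeps the segmented
                # mask connected while guaranteeing two local maxima
                amps_maps[ch][sl][env] += 0.4 * amp
                # foci are continuous Gaussian blobs: sub-pixel placement
                # then cannot unbalance the two blurred peak heights
                s_f = 0.55 * 0.40 * obj["b"]
                sep = min(1.15 * obj["a"], 2 * obj["a"] - 2 * s_f - 1.0)
                for off in (-sep / 2, +sep / 2):
                    rad = int(np.ceil(4 * s_f)) + 1
                    fy, fx = obj["cy"], obj["cx"] + off
                    y0 = max(int(fy) - rad, 0)
                    x0 = max(int(fx) - rad, 0)
                    y1 = min(int(fy) + rad + 1, h)
                    x1 = min(int(fx) + rad + 1, w)
                    yy, xx = np.mgrid[y0:y1, x0:x1]
                    blob = np.exp(-((yy - fy) ** 2 + (xx - fx) ** 2)
                                  / (2 * s_f * s_f))
                    amps_maps[ch][y0:y1, x0:x1] += 2.0 * amp * blob
            else:
                amps_maps[ch][sl][env] += amp
        records.append({
            "id": obj["id"], "label": cls, "x": obj["cx"], "y": obj["cy"],
            "diameter_um": obj["diameter_um"], "dividing": obj["dividing"],
            "dna": amps.get("dna", 0.0) > 0,
            "rrna": amps.get("rrna", 0.0) > 0 and not depleted,
            "phage": amps.get("phage", 0.0) > 0 and phage_active,
        })

    planes = {}
    sigma_px = spec.psf_sigma_px
    for ch in CHANNELS:
        img = ndimage.gaussian_filter(amps_maps[ch], sigma=sigma_px)
        img = img + spec.background_level
        img = img + rng.normal(0.0, 1.0, size=img.shape) * spec.noise_sd
        planes[ch] = np.clip(img, 0.0, None)

    truth = pd.DataFrame(records, columns=_GT_COLUMNS) if records \
        else _empty_ground_truth()
    return FieldImage(pixel_size=spec.pixel_size, **planes), truth


def render_field(spec: SceneSpec) -> tuple[FieldImage, pd.DataFrame]:
    """Render one field and its ground-truth table.

    Deterministic for a fixed ``spec.seed``.  Raises :class:`PackingError`
    when the requested objects cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    return _render(spec, rng, phage_active=True)


def render_negative_control(spec: SceneSpec) -> tuple[FieldImage, pd.DataFrame]:
    """Render a field whose phage channel carries background + noise only.

    Emulates control samples never exposed to the phage-probe mix: object
    placement and the DNA/rRNA channels are identical to :func:`render_field`
    at the same seed; ground truth keeps the class labels but flags the phage
    channel as absent.
    """
    rng = np.random.default_rng(spec.seed)
    return _render(spec, rng, phage_active=False)


def render_fields(spec: SceneSpec, n_fields: int) -> list[tuple[FieldImage, pd.DataFrame]]:
    """Render ``n_fields`` independent fields from one spec (seeds derived)."""
    out = []
    for i in range(n_fields):
        out.append(render_field(spec.replace(seed=int(spec.seed) + 10_000 * i + i)))
    return out


def render_timeseries(
    day_specs: Sequence[tuple[float, SceneSpec]],
    fields_per_day: int = 1,
):
    """Render one sample (one or more fields) per day plus a truth table.

    Days must be strictly increasing.  The truth table reports the per-day
    *true* infected / zombie / SAR11 / dividing fractions implied by the
    integer class counts of each day's spec.
    """
    if len(day_specs) == 0:
        raise ValueError("empty day sequence")
    days = [d for d, _ in day_specs]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing (no duplicates)")

    fields: dict[float, list[tuple[FieldImage, pd.DataFrame]]] = {}
    rows = []
    for day, spec in day_specs:
        fields[day] = render_fields(spec, fields_per_day)
        n_cells = sum(spec.count(c) for c in CELL_CLASSES) * fields_per_day
        n_sar11 = (spec.count("uninfected_sar11")
                   + spec.count("infected_sar11")) * fields_per_day
        n_inf = spec.count("infected_sar11") * fields_per_day
        n_zom = spec.count("zombie") * fields_per_day
        n_div = sum(int(t["dividing"].sum()) for _, t in fields[day])
        rows.append({
            "day": day,
            "n_cells": n_cells,
            "true_infected_frac": n_inf / n_sar11 if n_sar11 else np.nan,
            "true_zombie_frac": n_zom / n_cells if n_cells else np.nan,
            "true_sar11_frac": n_sar11 / n_cells if n_cells else np.nan,
            "true_dividing_frac": n_div / n_cells if n_cells else np.nan,
        })
    return fields, pd.DataFrame(rows)


def scene_for_fractions(
    n_cells: int,
    infected_frac: float = 0.0,
    zombie_frac: float = 0.0,
    sar11_frac: float = 1.0,
    dividing_fraction: float = 0.0,
    n_free_phage: int = 0,
    seed: int = 0,
    **spec_kwargs,
) -> SceneSpec:
    """Build a SceneSpec whose class counts realize the given fractions.

    ``infected_frac`` is relative to SAR11 cells (the study's denominator);
    ``zombie_frac`` and ``sar11_frac`` are relative to total cells.
    Fractions are realized by rounding to integer counts.
    """
    n_sar11 = int(round(sar11_frac * n_cells))
    n_zombie = int(round(zombie_frac * n_cells))
    n_inf = int(round(infected_frac * n_sar11))
    n_other = n_cells - n_sar11 - n_zombie
    if min(n_sar11 - n_inf, n_other) < 0:
        raise ValueError("inconsistent fractions")
    counts = {
        "uninfected_sar11": n_sar11 - n_inf,
        "infected_sar11": n_inf,
        "zombie": n_zombie,
        "other_bacteria": n_other,
        "free_phage": n_free_phage,
    }
    if "field_shape" not in spec_kwargs:
        # size the field so zero-overlap rejection sampling stays feasible
        # (~4000 px^2 of exclusion area per object at the default optics)
        side = max(256, int(np.ceil(np.sqrt((n_cells + n_free_phage) * 4000))))
        spec_kwargs["field_shape"] = (side, side)
    return SceneSpec(counts=counts, dividing_fraction=dividing_fraction,
                     seed=seed, **spec_kwargs)
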