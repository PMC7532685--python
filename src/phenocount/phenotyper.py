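"""Rule-based identification, filtering and enumeration of cell phenotypes.

Per field of view the chain is:

1. binarise the nucleus channel (preprocess + Triangle threshold,
   optionally ML-corrected) and split touching nuclei by watershed;
2. purge non-nucleic objects by morphology: area outside [200, 2000] px
   or eccentricity > 0.8;
3. binarise every cytoplasm marker channel and build one combinatorial
   cytoplasmic mask per phenotype (product of marker masks, inverting
   channels whose pattern sign is '-');
4. apply each cytoplasmic mask to the filtered nucleus mask and run the
   region-growing area-ratio filter: an object whose masked/filtered area
   ratio is < 0.6 has a nucleus larger than its cytoplasm and is removed;
5. enumerate surviving cells by blob (connected-component) detection and
   export counts, positions, overlays and optional 120 x 120 thumbnails.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.measure import regionprops

from . import binarize as bz
from .registry import PhenotypeSpec
from .simgen import FOVChannelSet

__all__ = [
    "EnumerationConfig", "CellRecord", "CountTable",
    "filter_nucleus_objects", "build_cytoplasm_mask", "area_ratio_filter",
    "binarize_channels", "enumerate_phenotype", "enumerate_all",
    "export_results", "measure_diameter",
]


@dataclass
class EnumerationConfig:
    """Tunable rule parameters; defaults follow the reference morphology rules.

    Area bounds are magnification-dependent and therefore exposed.
    """

    method: str = "triangle"
    correction_model: object | None = None
    min_area: int = 200
    max_area: int = 2000
    max_eccentricity: float = 0.8
    ratio_cutoff: float = 0.6
    connectivity: int = 2       # 2 = 8-connected (default), 1 = 4-connected
    watershed_min_distance: int = 5
    spatial_sigma: float = 3.0
    range_sigma: float = 0.1
    clahe_tiles: int = 8
    clahe_clip: float = 0.01


@dataclass(frozen=True)
class CellRecord:
    """One identified cell."""

    id: int
    x: float
    y: float
    area: float                 # px^2, of the filtered nucleus object
    eccentricity: float
    equivalent_diameter_um: float
    phenotype: str


@dataclass
class CountTable:
    rows: pd.DataFrame          # columns: fov_id, phenotype, count

    def totals(self) -> pd.Series:
        return self.rows.groupby("phenotype")["count"].sum()


def measure_diameter(area_px: float, pixel_size_um: float) -> float:
    """Area-equivalent diameter in micrometres: 2 sqrt(area/pi) * pixel size."""
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    return 2.0 * np.sqrt(area_px / np.pi) * pixel_size_um


def filter_nucleus_objects(labels: np.ndarray, min_area: int = 200,
                           max_area: int = 2000,
                           max_eccentricity: float = 0.8) -> np.ndarray:
    """Keep labelled objects with min_area <= area <= max_area and
    eccentricity <= max_eccentricity; labels are re-compacted from 1."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for rp in regionprops(labels):
        if rp.area < min_area or rp.area > max_area:
            continue
        if rp.eccentricity > max_eccentricity:
            continue
        out[labels == rp.label] = next_label
        next_label += 1
    return out


def build_cytoplasm_mask(marker_masks, pattern: dict[int, str]) -> np.ndarray:
    """Product of marker masks per the sign pattern ('-' inverts; absent = ignore)."""
    if not marker_masks:
        shape = None
    else:
        shape = np.asarray(marker_masks[0]).shape
        for m in marker_masks:
            if np.asarray(m).shape != shape:
                raise ValueError("marker masks have mismatched dimensions")
    if shape is None:
        raise ValueError("at least one marker mask is required")
    out = np.ones(shape, dtype=bool)
    for ch, sign in pattern.items():
        if ch >= len(marker_masks):
            raise ValueError(f"pattern references channel {ch} beyond available masks")
        m = np.asarray(marker_masks[ch], dtype=bool)
        out &= m if sign == "+" else ~m
    return out


def area_ratio_filter(masked_nucleus: np.ndarray, filtered_nucleus: np.ndarray,
                      ratio_cutoff: float = 0.6, connectivity: int = 2):
    """Region-growing two-mask area-ratio filter.

    For every object of the masked image a region is grown from its
    centroid in both the masked and the filtered nucleus image; objects
    whose masked/filtered area ratio is strictly below ``ratio_cutoff``
    are removed.  Returns ``(surviving_mask, ratios)`` where ratios maps
    the seed (row, col) to the computed ratio.
    """
    masked = np.asarray(masked_nucleus, dtype=bool)
    filtered = np.asarray(filtered_nucleus)
    if masked.shape != filtered.shape:
        raise ValueError("masks derive from the same FOV and must share dimensions")
    structure = ndi.generate_binary_structure(2, connectivity)
    if filtered.dtype == bool:
        lab_f, _ = ndi.label(filtered, structure=structure)
    else:
        # a labelled (watershed-split) image: growing stops at label borders
        lab_f = filtered.astype(np.int64)
    # masked objects additionally split along the filtered-object borders, so
    # a masked piece never straddles two split nuclei
    lab_m0, _ = ndi.label(masked, structure=structure)
    pair = lab_m0.astype(np.int64) * (np.int64(lab_f.max()) + 1) + lab_f
    pair[~masked] = 0
    keys = np.unique(pair[masked])
    lab_m = np.searchsorted(keys, pair) + 1
    lab_m[~masked] = 0
    area_m = np.bincount(lab_m.ravel())
    area_f = np.bincount(lab_f.ravel())
    out = np.zeros(masked.shape, dtype=bool)
    ratios: dict[tuple[int, int], float] = {}
    for rp in regionprops(lab_m):
        seed = tuple(int(round(v)) for v in rp.centroid)
        if not masked[seed]:
            # concave object: snap the seed to the object's nearest pixel
            ys, xs = np.nonzero(lab_m == rp.label)
            k = np.argmin((ys - rp.centroid[0]) ** 2 + (xs - rp.centroid[1]) ** 2)
            seed = (int(ys[k]), int(xs[k]))
        f_label = lab_f[seed]
        if f_label == 0:
            warnings.warn(f"seed {seed} falls on background in the filtered image; "
                          "object removed")
            continue
        ratio = float(area_m[rp.label]) / float(area_f[f_label])
        ratios[seed] = ratio
        if ratio < ratio_cutoff:
            continue
        out[lab_m == rp.label] = True
    return out, ratios


def binarize_channels(fov: FOVChannelSet, config: EnumerationConfig | None = None):
    """Preprocess and binarise the nucleus and marker channels of one FOV.

    Returns ``(filtered_nucleus_labels, marker_masks, decisions)`` where
    the nucleus labelling has already been watershed-split and
    morphology-filtered.
    """
    config = config or EnumerationConfig()

    def _mask(img):
        a = bz._to_float01(np.asarray(img))
        # background-only channel: CLAHE would stretch pure noise into
        # spurious structure, so an effectively flat channel yields an
        # empty mask (contrast floor = a few CCD-noise SDs)
        if float(np.percentile(a, 99.9) - np.median(a)) < 0.05:
            return np.zeros(a.shape, dtype=bool), bz.ThresholdDecision(
                config.method, float(a.max()) + 1.0, 1.0)
        pre = bz.preprocess(a, config.spatial_sigma, config.range_sigma,
                            config.clahe_tiles, config.clahe_clip)
        dec = bz.decide_threshold(pre, config.method, config.correction_model)
        return bz.binarize(pre, dec.final_threshold), dec

    nuc_mask, nuc_dec = _mask(fov.nucleus)
    labels = bz.watershed_split(nuc_mask, min_distance=config.watershed_min_distance)
    filtered = filter_nucleus_objects(labels, config.min_area, config.max_area,
                                      config.max_eccentricity)
    marker_masks, decisions = [], {"NUC": nuc_dec}
    for j, m in enumerate(fov.markers):
        mm, dec = _mask(m)
        marker_masks.append(mm)
        decisions[f"C{j + 1}"] = dec
    return filtered, marker_masks, decisions


def _records_for_pattern(filtered_labels, marker_masks, pattern, phenotype_name,
                         pixel_size_um, config, start_id=1):
    filtered_mask = filtered_labels > 0
    if pattern:
        cyto = build_cytoplasm_mask(marker_masks, pattern)
        masked = filtered_mask & cyto
    else:  # nucleus-only run with no marker channels
        masked = filtered_mask
    surviving, _ = area_ratio_filter(masked, filtered_labels,
                                     config.ratio_cutoff, config.connectivity)
    # blob detection: each surviving connected component is one cell,
    # attributed to (at most) one filtered nucleus object
    structure = ndi.generate_binary_structure(2, config.connectivity)
    lab_s, n_s = ndi.label(surviving, structure=structure)
    hit_labels = sorted(set(np.unique(filtered_labels[surviving])) - {0})
    props = {rp.label: rp for rp in regionprops(filtered_labels)}
    records = []
    overlay = np.zeros(filtered_labels.shape, dtype=np.int32)
    for i, lbl in enumerate(hit_labels, start=start_id):
        rp = props[lbl]
        records.append(CellRecord(
            id=i, x=float(rp.centroid[1]), y=float(rp.centroid[0]),
            area=float(rp.area), eccentricity=float(rp.eccentricity),
            equivalent_diameter_um=measure_diameter(rp.area, pixel_size_um),
            phenotype=phenotype_name,
        ))
        overlay[filtered_labels == lbl] = i
    return records, overlay


def enumerate_phenotype(fov: FOVChannelSet, spec: PhenotypeSpec,
                        config: EnumerationConfig | None = None):
    """Full chain for one phenotype on one FOV.

    Returns ``(records, count, overlay)``; the overlay labels each
    detected cell with its running index.
    """
    config = config or EnumerationConfig()
    required = [ch for ch, s in enumerate(spec.pattern) if s == "+"]
    missing = [ch for ch in required if ch >= len(fov.markers)]
    if missing:
        raise ValueError(f"phenotype {spec.name} requires marker channel(s) "
                         f"{missing} not present in this FOV")
    pattern = spec.active_pattern(len(fov.markers))
    filtered, marker_masks, _ = binarize_channels(fov, config)
    records, overlay = _records_for_pattern(filtered, marker_masks, pattern,
                                            spec.name, fov.pixel_size_um, config)
    return records, len(records), overlay


def enumerate_all(fov: FOVChannelSet, specs, config: EnumerationConfig | None = None,
                  fov_id: str = "fov"):
    """Enumerate several phenotypes on one FOV, binarising channels once.

    Returns ``(records, CountTable, overlays)``.
    """
    config = config or EnumerationConfig()
    filtered, marker_masks, _ = binarize_channels(fov, config)
    all_records, rows, overlays = [], [], {}
    for spec in specs:
        pattern = spec.active_pattern(len(fov.markers))
        records, overlay = _records_for_pattern(filtered, marker_masks, pattern,
                                                spec.name, fov.pixel_size_um, config,
                                                start_id=1)
        all_records += records
        rows.append({"fov_id": fov_id, "phenotype": spec.name, "count": len(records)})
        overlays[spec.name] = overlay
    return all_records, CountTable(pd.DataFrame(rows)), overlays


# --------------------------------------------------------------- export

def _thumbnail(img: np.ndarray, y: float, x: float, size: int = 120) -> np.ndarray:
    """size x size crop centred on (y, x); borders are mirror-padded."""
    half = size // 2
    pad = np.pad(img, half, mode="reflect")
    yi, xi = int(round(y)) + half, int(round(x)) + half
    return pad[yi - half: yi - half + size, xi - half: xi - half + size]


def export_results(records, counts: CountTable, overlays, out_dir,
                   thumbnails: bool = False, fov_images=None,
                   thumbnail_size: int = 120):
    """Write count and position CSVs, overlay PNGs and optional thumbnails."""
    import imageio.v3 as iio
    from skimage.color import label2rgb

    os.makedirs(out_dir, exist_ok=True)
    counts.rows.to_csv(os.path.join(out_dir, "counts.csv"), index=False)
    pos = pd.DataFrame(
        [{"id": r.id, "x": r.x, "y": r.y, "area_px": r.area,
          "eccentricity": r.eccentricity,
          "equivalent_diameter_um": r.equivalent_diameter_um,
          "phenotype": r.phenotype} for r in records],
        columns=["id", "x", "y", "area_px", "eccentricity",
                 "equivalent_diameter_um", "phenotype"],
    )
    pos.to_csv(os.path.join(out_dir, "positions.csv"), index=False)
    written = [os.path.join(out_dir, "counts.csv"), os.path.join(out_dir, "positions.csv")]
    for name, overlay in (overlays or {}).items():
        rgb = (label2rgb(overlay, bg_label=0) * 255).astype(np.uint8)
        path = os.path.join(out_dir, f"overlay_{name}.png")
        iio.imwrite(path, rgb)
        written.append(path)
    if thumbnails:
        if fov_images is None:
            raise ValueError("thumbnails require the source image(s)")
        img = fov_images.nucleus if isinstance(fov_images, FOVChannelSet) else np.asarray(fov_images)
        for r in records:
            thumb = _thumbnail(img, r.y, r.x, thumbnail_size)
            path = os.path.join(out_dir, f"thumb_{r.phenotype}_{r.id}.png")
            iio.imwrite(path, (np.clip(thumb, 0, 1) * 255).astype(np.uint8))
            written.append(path)
    return written
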