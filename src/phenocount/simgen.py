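"""Synthetic multi-channel fluorescent fields of view with exact ground truth.

Each field of view (FOV) contains elliptical nuclei (one per cell) and,
per cytoplasm marker channel, a larger concentric ellipse painted only
for cells whose phenotype expresses that marker.  Marker intensity is
drawn per cell, modulated by a multiplicative smooth ("Perlin-style")
texture field, blurred by a small optical PSF and degraded by additive
Gaussian CCD noise.  Default population parameters: nuclear radius 13 px,
eccentricity 0.5, variation 0.1; cytoplasm radius 18 px, eccentricity
0.5, variation 0.3; marker level 0.5 +/- 0.2; texture amplitude 0.2 with
length scale 6 px and falloff frequency 0.0025 cycles/px; clustering
probability 25%; CCD noise variance 1e-4.

The module also builds splice forgeries (pasting up to three mask objects
from a donor image), mirrored augmentations, and gross out-of-distribution
anomaly images for exercising the forensics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.ndimage as ndi

from .registry import PhenotypeSpec, default_registry, full_patterns

__all__ = [
    "NucleusPopulationSpec", "MarkerSpec", "FOVSpec", "FOVChannelSet",
    "CellTruth", "GroundTruth", "ForgeryRecord", "PlacementError",
    "generate_fov", "generate_phenotype_set", "splice_tamper",
    "augment_mirror", "make_anomaly", "write_fov", "write_ground_truth",
]


class PlacementError(RuntimeError):
    """Requested cells cannot be placed within the retry budget."""


@dataclass(frozen=True)
class NucleusPopulationSpec:
    """Nucleus geometry and placement statistics for one population."""

    mean_radius: float = 13.0           # px (area-equivalent)
    eccentricity: float = 0.5
    variation_extent: float = 0.1       # fractional jitter on radius/eccentricity
    count_distribution: tuple[float, float] = (5.0, 0.0)  # (mean, dispersion) per phenotype
    clustering_probability: float = 0.25

    def __post_init__(self):
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be positive")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must be in [0, 1)")
        if not 0.0 <= self.clustering_probability <= 1.0:
            raise ValueError("clustering_probability must be in [0, 1]")


@dataclass(frozen=True)
class MarkerSpec:
    """Per-channel cytoplasm rendering parameters."""

    mean_level: float = 0.5             # intensity fraction
    level_sd: float = 0.2
    texture: dict = dc_field(default_factory=lambda: {
        "amplitude": 0.2, "length_scale": 6.0,
        "falloff_frequency": 0.0025, "mode": "multiplicative",
    })
    cell_radius: float = 18.0           # px
    cell_eccentricity: float = 0.5
    variation_extent: float = 0.3

    def __post_init__(self):
        if self.texture.get("amplitude", 0.0) < 0:
            raise ValueError("texture amplitude must be >= 0")
        if not 0.0 <= self.mean_level <= 1.0:
            raise ValueError("mean_level must be in [0, 1]")


@dataclass(frozen=True)
class FOVSpec:
    """One field of view: geometry, channel layout, phenotype counts, noise."""

    width: int = 512
    height: int = 512
    n_marker_channels: int = 3
    phenotype_mix: dict = dc_field(default_factory=dict)  # name -> exact cell count
    ccd_noise_variance: float = 1e-4
    seed: int = 0
    background: float = 0.05
    pixel_size_um: float = 0.5
    channel_ids: tuple = (0, 1, 2)      # registry channel behind each marker slot

    def __post_init__(self):
        if self.n_marker_channels not in (0, 1, 2, 3):
            raise ValueError("n_marker_channels must be 0..3")
        if any(v < 0 for v in self.phenotype_mix.values()):
            raise ValueError("phenotype counts must be >= 0")


@dataclass
class FOVChannelSet:
    """Rendered channels of one FOV, float images in [0, 1]."""

    nucleus: np.ndarray
    markers: list[np.ndarray]
    bright_field: np.ndarray | None = None
    pixel_size_um: float = 0.5
    channel_ids: tuple = (0, 1, 2)


@dataclass(frozen=True)
class CellTruth:
    x: float            # column, px
    y: float            # row, px
    nucleus_radius: float
    phenotype: str


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    counts: dict[str, int]
    tamper_mask: np.ndarray | None = None

    def __post_init__(self):
        tally: dict[str, int] = {k: 0 for k in self.counts}
        for c in self.cells:
            tally[c.phenotype] = tally.get(c.phenotype, 0) + 1
        for k, v in tally.items():
            if self.counts.get(k, 0) != v:
                raise ValueError("counts do not tally the cell phenotypes")


@dataclass(frozen=True)
class ForgeryRecord:
    source_image_id: str
    donor_image_id: str
    n_objects_pasted: int
    tamper_mask: np.ndarray
    tampered_pixel_fraction: float


# --------------------------------------------------------------- rendering

def _smooth_noise(shape, length_scale, falloff_frequency, rng) -> np.ndarray:
    """Band-limited zero-mean field with unit SD, clipped to [-3, 3]/3 -> [-1, 1]."""
    w = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    spectrum = np.exp(-((np.pi * f * length_scale) ** 2))
    if falloff_frequency > 0:
        spectrum = spectrum / (1.0 + f / falloff_frequency)
    spectrum[0, 0] = 0.0  # remove DC so the field is zero-mean
    fld = np.real(np.fft.ifft2(np.fft.fft2(w) * spectrum))
    sd = fld.std()
    if sd > 0:
        fld /= sd
    return np.clip(fld, -3.0, 3.0) / 3.0


def _ellipse_axes(equiv_radius: float, ecc: float) -> tuple[float, float]:
    """Semi-axes (a, b) with area pi*r^2 and eccentricity e = sqrt(1-(b/a)^2)."""
    q = (1.0 - ecc**2) ** 0.25
    return equiv_radius / q, equiv_radius * q


def _paint_ellipse(img, cy, cx, a, b, theta, value):
    ext = int(np.ceil(max(a, b))) + 1
    y0, y1 = max(0, int(cy) - ext), min(img.shape[0], int(cy) + ext + 1)
    x0, x1 = max(0, int(cx) - ext), min(img.shape[1], int(cx) + ext + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    region = img[y0:y1, x0:x1]
    region[inside] = np.maximum(region[inside], value)


def _truncated_normal(rng, mean, sd):
    z = np.clip(rng.standard_normal(), -3.0, 3.0)
    return float(np.clip(mean + sd * z, 0.0, 1.0))


def _place_cells(spec: FOVSpec, nucleus: NucleusPopulationSpec, phenos, rng):
    order = []
    for name, n in spec.phenotype_mix.items():
        order += [name] * int(n)
    rng.shuffle(order)
    margin = nucleus.mean_radius * (1.0 + nucleus.variation_extent) + 2.0
    if spec.width <= 2 * margin or spec.height <= 2 * margin:
        raise PlacementError("FOV too small for the nucleus radius")
    cells = []
    budget = 200 * max(len(order), 1)
    for name in order:
        r = nucleus.mean_radius * (1.0 + nucleus.variation_extent * rng.uniform(-1, 1))
        e = float(np.clip(
            nucleus.eccentricity * (1.0 + nucleus.variation_extent * rng.uniform(-1, 1)),
            0.0, 0.9))
        theta = rng.uniform(0.0, np.pi)
        placed = False
        # clusters are clonal: populations are laid down one phenotype at a
        # time, so a clustered cell attaches to a parent of its own phenotype
        kin = [c for c in cells if c["phenotype"] == name]
        clustered = kin and rng.uniform() < nucleus.clustering_probability
        attempts = 0
        while budget > 0:
            budget -= 1
            attempts += 1
            if clustered and attempts > 50:
                clustered = False  # no room near any parent; place freely
            if clustered:
                parent = kin[rng.integers(len(kin))]
                # clustered neighbours touch and partially overlap (bounded
                # overlap, as in HCS population simulators)
                d = rng.uniform(1.2, 1.5) * nucleus.mean_radius
                ang = rng.uniform(0.0, 2 * np.pi)
                cx = parent["x"] + d * np.cos(ang)
                cy = parent["y"] + d * np.sin(ang)
                if not (margin <= cx <= spec.width - margin
                        and margin <= cy <= spec.height - margin):
                    continue
                # bounded overlap: keep at least the cluster spacing from
                # every cell, not just the chosen parent
                if any(np.hypot(cx - c["x"], cy - c["y"]) < 1.2 * nucleus.mean_radius
                       for c in cells):
                    continue
            else:
                cx = rng.uniform(margin, spec.width - margin)
                cy = rng.uniform(margin, spec.height - margin)
                too_close = any(
                    np.hypot(cx - c["x"], cy - c["y"]) < r + c["r"] + 2.0
                    for c in cells
                )
                if too_close:
                    continue
            cells.append({"x": cx, "y": cy, "r": r, "e": e,
                          "theta": theta, "phenotype": name})
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place {len(order)} cells in a "
                f"{spec.width}x{spec.height} FOV within the retry budget"
            )
    return cells


def generate_fov(spec: FOVSpec, nucleus: NucleusPopulationSpec | None = None,
                 markers: list[MarkerSpec] | None = None,
                 phenotypes: dict[str, PhenotypeSpec] | None = None,
                 nucleus_marker: MarkerSpec | None = None,
                 psf_sigma: float = 1.0,
                 ) -> tuple[FOVChannelSet, GroundTruth]:
    """Render one FOV and its exact ground truth.

    ``phenotypes`` maps the names in ``spec.phenotype_mix`` to patterns in
    FOV-slot order; by default the 20-phenotype registry restricted to the
    FOV's ``channel_ids`` is used.  Identical (spec, seed) inputs yield
    bit-identical pixels.
    """
    nucleus = nucleus or NucleusPopulationSpec()
    markers = markers if markers is not None else [MarkerSpec()] * spec.n_marker_channels
    if len(markers) != spec.n_marker_channels:
        raise ValueError("markers length must equal n_marker_channels")
    nucleus_marker = nucleus_marker or MarkerSpec()
    if phenotypes is None:
        ids = tuple(spec.channel_ids[: spec.n_marker_channels])
        phenotypes = {p.name: p for p in full_patterns(ids)}
        missing = set(spec.phenotype_mix) - set(phenotypes)
        if missing:
            raise KeyError(f"phenotypes {sorted(missing)} not defined for channels {ids}")
    rng = np.random.default_rng(spec.seed)
    cells = _place_cells(spec, nucleus, phenotypes, rng)

    shape = (spec.height, spec.width)
    nuc = np.zeros(shape)
    mk = [np.zeros(shape) for _ in range(spec.n_marker_channels)]
    footprint = np.zeros(shape)
    for c in cells:
        a, b = _ellipse_axes(c["r"], c["e"])
        level = _truncated_normal(rng, nucleus_marker.mean_level, nucleus_marker.level_sd)
        _paint_ellipse(nuc, c["y"], c["x"], a, b, c["theta"], level)
        pat = phenotypes[c["phenotype"]].pattern
        for j, mspec in enumerate(markers):
            cr = mspec.cell_radius * (1.0 + mspec.variation_extent * rng.uniform(-1, 1))
            ce = float(np.clip(
                mspec.cell_eccentricity * (1.0 + mspec.variation_extent * rng.uniform(-1, 1)),
                0.0, 0.9))
            clevel = _truncated_normal(rng, mspec.mean_level, mspec.level_sd)
            if j < len(pat) and pat[j] == "+":
                ca, cb = _ellipse_axes(cr, ce)
                _paint_ellipse(mk[j], c["y"], c["x"], ca, cb, c["theta"], clevel)
                _paint_ellipse(footprint, c["y"], c["x"], ca, cb, c["theta"], 1.0)
        _paint_ellipse(footprint, c["y"], c["x"], a, b, c["theta"], 1.0)

    def _finish(img: np.ndarray, mspec: MarkerSpec) -> np.ndarray:
        tx = mspec.texture
        if tx.get("amplitude", 0.0) > 0:
            noise = _smooth_noise(shape, tx.get("length_scale", 6.0),
                                  tx.get("falloff_frequency", 0.0), rng)
            img = img * (1.0 + tx["amplitude"] * noise)
        img = np.clip(img + spec.background, 0.0, 1.0)
        if psf_sigma > 0:
            img = ndi.gaussian_filter(img, psf_sigma)
        img = img + rng.normal(0.0, np.sqrt(spec.ccd_noise_variance), shape)
        return np.clip(img, 0.0, 1.0)

    nuc_img = _finish(nuc, nucleus_marker)
    mk_imgs = [_finish(m, mspec) for m, mspec in zip(mk, markers)]
    bf = 0.85 - 0.15 * ndi.gaussian_filter(footprint, 2.0)
    bf = np.clip(bf + rng.normal(0.0, np.sqrt(spec.ccd_noise_variance), shape), 0.0, 1.0)

    counts = {name: 0 for name in spec.phenotype_mix}
    truth_cells = []
    for c in cells:
        counts[c["phenotype"]] += 1
        truth_cells.append(CellTruth(c["x"], c["y"], c["r"], c["phenotype"]))
    fov = FOVChannelSet(nucleus=nuc_img, markers=mk_imgs, bright_field=bf,
                        pixel_size_um=spec.pixel_size_um,
                        channel_ids=tuple(spec.channel_ids[: spec.n_marker_channels]))
    return fov, GroundTruth(cells=truth_cells, counts=counts)


# --------------------------------------------------------------- image sets

_GROUP_CHANNELS = [
    [(0,), (1,), (2,)],            # single-marker runs, cycling the channel
    [(0, 1), (0, 2), (1, 2)],      # channel-pair runs, cycling the pair
    [(0, 1, 2)],
    [(0, 1, 2)],
]


def generate_phenotype_set(n_fov_per_group: int, seed: int = 0,
                           size: tuple[int, int] = (512, 512),
                           nucleus: NucleusPopulationSpec | None = None,
                           marker: MarkerSpec | None = None,
                           ccd_noise_variance: float = 1e-4,
                           ) -> list[tuple[FOVChannelSet, GroundTruth]]:
    """Four groups of FOVs jointly covering the 20-phenotype registry.

    Groups use 1, 2, 3 and 3 marker channels; each three-marker group
    draws 5 of its 8 full patterns once, smaller groups use all their
    patterns.  Per-FOV per-phenotype counts are Poisson with the nucleus
    population's count mean.  ``n_fov_per_group=100`` yields the 400-FOV
    reference scale.
    """
    if n_fov_per_group < 1:
        raise ValueError("n_fov_per_group must be >= 1")
    nucleus = nucleus or NucleusPopulationSpec()
    marker = marker or MarkerSpec()
    master = np.random.default_rng(seed)
    count_mean = nucleus.count_distribution[0]
    out = []
    for group, cycle in enumerate(_GROUP_CHANNELS):
        # fixed per-group phenotype selection, as in a grouped study design
        selections = {}
        for ids in cycle:
            pats = full_patterns(ids)
            if len(pats) > 5:
                idx = master.choice(len(pats), size=5, replace=False)
                pats = [pats[i] for i in sorted(idx)]
            selections[ids] = pats
        for i in range(n_fov_per_group):
            ids = cycle[i % len(cycle)]
            pats = selections[ids]
            mix = {p.name: int(master.poisson(count_mean)) for p in pats}
            spec = FOVSpec(
                width=size[1], height=size[0], n_marker_channels=len(ids),
                phenotype_mix=mix, ccd_noise_variance=ccd_noise_variance,
                seed=int(master.integers(2**31)), channel_ids=ids,
            )
            out.append(generate_fov(
                spec, nucleus=nucleus, markers=[marker] * len(ids),
                phenotypes={p.name: p for p in pats},
            ))
    return out


# --------------------------------------------------------------- forgeries & co

def splice_tamper(target: np.ndarray, donor: np.ndarray, donor_mask: np.ndarray,
                  max_objects: int = 3, seed: int = 0,
                  source_image_id: str = "target", donor_image_id: str = "donor",
                  ) -> tuple[np.ndarray, ForgeryRecord]:
    """Paste 1..max_objects donor-mask components into the target at random.

    The returned tamper mask marks exactly the pasted pixels; outside the
    mask the output equals the target bit for bit.
    """
    if max_objects < 1:
        raise ValueError("max_objects must be >= 1")
    target = np.asarray(target)
    donor = np.asarray(donor)
    if target.ndim != 2 or donor.ndim != 2:
        raise ValueError("images must be single-channel")
    lab, n_obj = ndi.label(np.asarray(donor_mask, dtype=bool))
    if n_obj == 0:
        raise ValueError("donor mask has no connected components")
    rng = np.random.default_rng(seed)
    n_paste = int(rng.integers(1, max_objects + 1))
    n_paste = min(n_paste, n_obj)
    chosen = rng.choice(np.arange(1, n_obj + 1), size=n_paste, replace=False)
    out = target.copy()
    tamper = np.zeros(target.shape, dtype=bool)
    slices = ndi.find_objects(lab)
    for obj in chosen:
        sl = slices[obj - 1]
        patch = donor[sl]
        pmask = lab[sl] == obj
        h, w = patch.shape
        if h > target.shape[0] or w > target.shape[1]:
            raise ValueError("donor object larger than the target image")
        y = int(rng.integers(0, target.shape[0] - h + 1))
        x = int(rng.integers(0, target.shape[1] - w + 1))
        region = out[y:y + h, x:x + w]
        region[pmask] = patch[pmask]
        tamper[y:y + h, x:x + w] |= pmask
    frac = float(tamper.sum()) / tamper.size
    rec = ForgeryRecord(source_image_id, donor_image_id, n_paste, tamper, frac)
    return out, rec


def augment_mirror(image: np.ndarray) -> list[np.ndarray]:
    """[original, horizontal flip, vertical flip, both] - augmentation factor 4."""
    a = np.asarray(image)
    return [a.copy(), a[:, ::-1].copy(), a[::-1, :].copy(), a[::-1, ::-1].copy()]


ANOMALY_MODES = ("blank", "saturated", "noise", "off_modality")


def make_anomaly(base: np.ndarray, mode: str, seed: int = 0) -> np.ndarray:
    """An image far outside the fluorescent-image feature distribution.

    Modes: ``blank`` (all zero), ``saturated`` (all at max), ``noise``
    (i.i.d. uniform), ``off_modality`` (smooth diagonal ramp, e.g. a
    misloaded non-fluorescent capture).
    """
    base = np.asarray(base, dtype=np.float64)
    rng = np.random.default_rng(seed)
    if mode == "blank":
        return np.zeros_like(base)
    if mode == "saturated":
        # sensor saturation: >= 99% of pixels pinned at max, with residual
        # hot-pixel / readout speckle
        out = np.ones_like(base)
        speckle = rng.uniform(0.0, 1.0, base.shape) < 0.005
        out[speckle] = rng.uniform(0.0, 1.0, int(speckle.sum()))
        return out
    if mode == "noise":
        return rng.uniform(0.0, 1.0, base.shape)
    if mode == "off_modality":
        yy, xx = np.mgrid[0 : base.shape[0], 0 : base.shape[1]]
        ramp = (yy + xx) / (base.shape[0] + base.shape[1] - 2)
        return 0.1 + 0.8 * ramp
    raise ValueError(f"unknown anomaly mode {mode!r}; choose from {ANOMALY_MODES}")


# --------------------------------------------------------------- export

_CHANNEL_TAGS = ("C1", "C2", "C3")


def write_fov(out_dir, fov_id: str, fov: FOVChannelSet, fmt: str = "tif",
              bit_depth: int = 8) -> list[str]:
    """Write per-channel images named {fovID}_{BF|NUC|C1|C2|C3}.{tif|png}."""
    import os
    import imageio.v3 as iio
    import tifffile

    os.makedirs(out_dir, exist_ok=True)
    scale = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16

    def _save(tag, img):
        arr = np.clip(np.asarray(img) * scale, 0, scale).astype(dtype)
        path = os.path.join(out_dir, f"{fov_id}_{tag}.{fmt}")
        if fmt == "tif":
            tifffile.imwrite(path, arr)
        else:
            iio.imwrite(path, arr)
        return path

    paths = []
    if fov.bright_field is not None:
        paths.append(_save("BF", fov.bright_field))
    paths.append(_save("NUC", fov.nucleus))
    for j, m in enumerate(fov.markers):
        paths.append(_save(_CHANNEL_TAGS[j], m))
    return paths


def write_ground_truth(out_dir, truths: dict[str, GroundTruth]) -> tuple[str, str]:
    """Per-cell CSV (fov, x, y, radius, phenotype) and per-FOV count CSV."""
    import os
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    cell_rows, count_rows = [], []
    for fov_id, gt in truths.items():
        for c in gt.cells:
            cell_rows.append({"fov": fov_id, "x": c.x, "y": c.y,
                              "radius": c.nucleus_radius, "phenotype": c.phenotype})
        for name, n in gt.counts.items():
            count_rows.append({"fov": fov_id, "phenotype": name, "count": n})
    cells_path = os.path.join(out_dir, "cells.csv")
    counts_path = os.path.join(out_dir, "counts.csv")
    pd.DataFrame(cell_rows, columns=["fov", "x", "y", "radius", "phenotype"]
                 ).to_csv(cells_path, index=False)
    pd.DataFrame(count_rows, columns=["fov", "phenotype", "count"]
                 ).to_csv(counts_path, index=False)
    return cells_path, counts_path
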