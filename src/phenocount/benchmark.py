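"""End-to-end evaluation experiments on generated image sets.

These drive the full generator -> binarisation -> enumeration chain and
summarise performance with the evaluation statistics; they are used both
by the test suite and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import evalstats as ev
from . import phenotyper as ph
from . import simgen as sg
from .registry import full_patterns


def run_enumeration_benchmark(n_fov_per_group: int = 25, seed: int = 1,
                              size: tuple[int, int] = (512, 512),
                              config: ph.EnumerationConfig | None = None,
                              bootstrap: int = 0) -> dict:
    """Generate a 4-group phenotype set and score the enumeration chain.

    Returns pooled cell-level sensitivity and specificity (greedy centroid
    matching within the true nucleus radius) and the pooled mean
    percentage count error over (FOV, phenotype) units with a non-zero
    reference count.
    """
    fovs = sg.generate_phenotype_set(n_fov_per_group, seed=seed, size=size)
    per_fov, ref_counts, pred_counts = [], [], []
    for i, (fov, gt) in enumerate(fovs):
        specs = [s for s in full_patterns(fov.channel_ids) if s.name in gt.counts]
        records, counts, _ = ph.enumerate_all(fov, specs, config=config,
                                              fov_id=f"fov{i:04d}")
        preds = [dict(x=r.x, y=r.y, phenotype=r.phenotype) for r in records]
        truths = [dict(x=c.x, y=c.y, phenotype=c.phenotype,
                       radius=c.nucleus_radius) for c in gt.cells]
        per_fov.append((preds, truths))
        by = counts.rows.set_index("phenotype")["count"]
        for name, x in gt.counts.items():
            ref_counts.append(x)
            pred_counts.append(int(by.get(name, 0)))
    det = ev.detection_metrics(per_fov, bootstrap=bootstrap, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-truth units are expected
        _, mean_err, sd_err = ev.percentage_error(ref_counts, pred_counts)
    return {
        "n_fov": len(fovs),
        "n_cells": int(sum(len(t) for _, t in per_fov)),
        "sensitivity": det.sensitivity,
        "specificity": det.specificity,
        "sensitivity_ci": det.sensitivity_ci,
        "specificity_ci": det.specificity_ci,
        "mean_percentage_error": mean_err,
        "sd_percentage_error": sd_err,
        "confusion": {"tp": det.tp, "fp": det.fp, "tn": det.tn, "fn": det.fn},
    }


def make_forgery_corpus(n_pairs: int, seed: int = 0, size: int = 112):
    """Pristine/forged image pairs for detector training.

    Donors are rendered under a different condition (no marker texture,
    quadrupled CCD noise), mirroring splices across image sets; donor
    objects are its thresholded nuclei.
    """
    imgs, labels = [], []
    flat = sg.MarkerSpec(texture={"amplitude": 0.0})
    for i in range(n_pairs):
        t_spec = sg.FOVSpec(width=size, height=size, n_marker_channels=1,
                            phenotype_mix={"P2": 2, "P1": 1},
                            seed=seed + 2 * i, channel_ids=(0,))
        target = sg.generate_fov(t_spec)[0].nucleus
        d_spec = sg.FOVSpec(width=size, height=size, n_marker_channels=1,
                            phenotype_mix={"P2": 2, "P1": 1},
                            seed=seed + 2 * i + 1, channel_ids=(0,),
                            ccd_noise_variance=4e-4)
        donor = sg.generate_fov(d_spec, nucleus_marker=flat, markers=[flat])[0].nucleus
        forged, _ = sg.splice_tamper(target, donor, donor > 0.25, seed=seed + i)
        imgs += [target, forged]
        labels += [0, 1]
    return imgs, np.asarray(labels)
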