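"""End-to-end pipeline: simulate -> segment -> classify -> tether -> contacts -> fusion.

Each stage reads/writes files in one workspace directory, every output
CSV carries the hash of the configuration that produced it, and a run
manifest records config, seed and package version, so a rerun with the
same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .fusion import average_curves, measure_spread
from .io import (
    RunConfig,
    objects_to_frame,
    read_annotation_csv,
    read_stack,
    write_annotation_csv,
    write_stack,
)
from .contacts import extract_contacts, summarize
from .morphology import classify_cell, summarize_classes
from .segmentation import preprocess, segment, shape_descriptors
from .synthetic import (
    EMSceneSpec,
    MorphologySpec,
    PAGFPSpec,
    TimelapseSpec,
    gen_em_scene,
    gen_morphology_image,
    gen_pagfp_series,
    gen_timelapse,
)
from .tethering import extract_events, detect_foci, link_tracks, segment_mito_frames, tether_stats

STAGES = ("simulate", "segment", "classify", "tether", "contacts", "fusion")

# simulated demo: class composition per phenotype
_CLASS_SPECS = {
    "Elongated": dict(n_tubules=12, n_blobs=0),
    "Fragmented": dict(n_tubules=0, n_blobs=16),
    "Hyperfused": dict(n_tubules=10, n_blobs=3, hyperfused=True),
    "Collapsed": dict(n_tubules=0, n_blobs=12, blob_radius_px=4.0, collapsed=True),
}


def _tag(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.config_hash
    return df


def run_pipeline(
    config: RunConfig,
    stages: list[str],
    outdir: str | Path,
    n_cells_per_class: int = 2,
    n_replicates: int = 2,
) -> dict[str, Path]:
    """Run the requested stages in order; returns paths of written outputs."""
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}; expected one of {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    rng = np.random.default_rng(config.seed)
    # per-stage derived seeds, stable regardless of which stages run
    stage_seeds = {st: int(np.random.default_rng([config.seed, i]).integers(2**31))
                   for i, st in enumerate(STAGES)}

    if "simulate" in stages:
        cells_dir = outdir / "cells"
        cells_dir.mkdir(exist_ok=True)
        index_rows = []
        k = 0
        for rep in range(n_replicates):
            for cls, kw in _CLASS_SPECS.items():
                for i in range(n_cells_per_class):
                    spec = MorphologySpec(seed=stage_seeds["simulate"] + k, **kw)
                    sample = gen_morphology_image(spec)
                    name = f"cell_r{rep}_{cls.lower()}_{i}.tif"
                    tifffile.imwrite(cells_dir / name, sample.image.astype(np.float32))
                    index_rows.append(
                        {"cell_id": name.removesuffix(".tif"), "condition": "synthetic",
                         "replicate": rep, "true_class": cls, "path": f"cells/{name}"}
                    )
                    k += 1
        idx = _tag(pd.DataFrame(index_rows), config)
        idx.to_csv(outdir / "cell_index.csv", index=False)
        written["cell_index"] = outdir / "cell_index.csv"

        tl = gen_timelapse(TimelapseSpec(seed=stage_seeds["simulate"]))
        write_stack(outdir / "timelapse.tif", tl.stack)
        _tag(tl.events, config).to_csv(outdir / "timelapse_truth.csv", index=False)
        written["timelapse"] = outdir / "timelapse.tif"

        em = gen_em_scene(
            EMSceneSpec(
                n_mito=3,
                er_segments=((0, 10.0, 300.0), (0, 40.0, 500.0), (1, 25.0, 400.0), (2, 100.0, 400.0)),
                seed=stage_seeds["simulate"],
            )
        )
        write_annotation_csv([em.scene], outdir / "em_scene.csv")
        _tag(em.contacts, config).to_csv(outdir / "em_truth.csv", index=False)
        written["em_scene"] = outdir / "em_scene.csv"

        pa = gen_pagfp_series(PAGFPSpec(seed=stage_seeds["simulate"]))
        write_stack(outdir / "pagfp.tif", pa.frames[:, None])
        tifffile.imwrite(outdir / "pagfp_mask.tif", pa.mito_mask.astype(np.uint8))
        json.dump(
            {"roi": list(pa.roi), "timepoints_min": list(pa.timepoints_min)},
            (outdir / "pagfp_roi.json").open("w"),
        )
        written["pagfp"] = outdir / "pagfp.tif"

    if "segment" in stages:
        idx = pd.read_csv(outdir / "cell_index.csv")
        labels_dir = outdir / "labels"
        labels_dir.mkdir(exist_ok=True)
        frames = []
        for _, row in idx.iterrows():
            image = read_stack(outdir / row["path"])[0, 0]
            labels = segment(preprocess(image, config.segmentation), config.segmentation)
            tifffile.imwrite(labels_dir / f"{row['cell_id']}.tif", labels.astype(np.int32))
            frames.append(
                objects_to_frame(shape_descriptors(labels, config.um_per_px), row["cell_id"])
            )
        objects = _tag(pd.concat(frames, ignore_index=True), config)
        objects.to_csv(outdir / "objects.csv", index=False)
        written["objects"] = outdir / "objects.csv"

    if "classify" in stages:
        idx = pd.read_csv(outdir / "cell_index.csv").set_index("cell_id")
        rows = []
        for cell_id in idx.index:
            labels = tifffile.imread(outdir / "labels" / f"{cell_id}.tif")
            cm = classify_cell(
                shape_descriptors(labels, config.um_per_px), labels,
                config.classification, cell_id=cell_id,
            )
            rows.append(
                {"cell_id": cell_id, "condition": idx.loc[cell_id, "condition"],
                 "replicate": idx.loc[cell_id, "replicate"],
                 "morphology_class": cm.morphology_class,
                 "tubular_fraction": cm.tubular_fraction,
                 "largest_component_fraction": cm.largest_component_fraction,
                 "clumping_index": cm.clumping_index, "mean_ar": cm.mean_ar}
            )
        classes = _tag(pd.DataFrame(rows), config)
        classes.to_csv(outdir / "classes.csv", index=False)
        summary = _tag(summarize_classes(classes), config)
        summary.to_csv(outdir / "class_summary.csv", index=False)
        written["classes"] = outdir / "classes.csv"

    if "tether" in stages:
        stack = read_stack(outdir / "timelapse.tif")
        spots = [detect_foci(frame, config.tracking) for frame in stack[:, 0]]
        tracks = link_tracks(spots, config.tracking)
        label_maps = segment_mito_frames(stack[:, 1])
        events = extract_events(tracks, label_maps, config.tracking)
        ev = _tag(
            pd.DataFrame(
                [
                    {"event_id": e.event_id, "start_s": e.start_frame * config.tracking.dt_s,
                     "duration_s": e.duration_s, "outcome": e.outcome,
                     "partner_a": e.partner_labels[0], "partner_b": e.partner_labels[1]}
                    for e in events
                ]
            ),
            config,
        )
        ev.to_csv(outdir / "events.csv", index=False)
        _tag(tether_stats({"synthetic": events}), config).to_csv(
            outdir / "tether_summary.csv", index=False
        )
        written["events"] = outdir / "events.csv"

    if "contacts" in stages:
        scenes = read_annotation_csv(outdir / "em_scene.csv")
        contact_rows, summary_rows = [], []
        for scene in scenes:
            contacts = extract_contacts(
                scene, step_nm=config.contact_step_nm, max_gap_nm=config.contact_max_gap_nm
            )
            for c in contacts:
                contact_rows.append(
                    {"cell_id": scene.cell_id, "contact_id": c.contact_id, "er_id": c.er_id,
                     "mito_id": c.mito_id, "length_nm": c.length_nm, "gap_nm": c.gap_nm,
                     "gap_bin": c.gap_bin}
                )
            s = summarize(contacts, scene)
            summary_rows.append(
                {"cell_id": s.cell_id, "n_mito": s.n_mito, "n_contacts": s.n_contacts,
                 "contacts_per_mito": s.contacts_per_mito,
                 "mean_contact_length_nm": s.mean_contact_length_nm,
                 "mean_mito_perimeter_nm": s.mean_mito_perimeter_nm,
                 "percent_perimeter_covered": s.percent_perimeter_covered}
            )
        _tag(pd.DataFrame(contact_rows), config).to_csv(outdir / "contacts.csv", index=False)
        _tag(pd.DataFrame(summary_rows), config).to_csv(
            outdir / "contact_summary.csv", index=False
        )
        written["contacts"] = outdir / "contacts.csv"

    if "fusion" in stages:
        frames = read_stack(outdir / "pagfp.tif")[:, 0]
        mask = tifffile.imread(outdir / "pagfp_mask.tif").astype(bool)
        meta = json.load((outdir / "pagfp_roi.json").open())
        curve = measure_spread(
            frames, mask, tuple(meta["roi"]), meta["timepoints_min"],
            threshold_fraction=config.fusion_threshold_fraction, cell_id="synthetic",
        )
        df = _tag(
            pd.DataFrame(
                {"cell_id": curve.cell_id, "timepoint_min": curve.timepoints_min,
                 "area_px": curve.area_px, "normalized_area": curve.normalized_area}
            ),
            config,
        )
        df.to_csv(outdir / "fusion_curves.csv", index=False)
        _tag(average_curves([curve]), config).to_csv(outdir / "fusion_summary.csv", index=False)
        written["fusion"] = outdir / "fusion_curves.csv"

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": list(stages),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = outdir / "manifest.json"
    return written
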