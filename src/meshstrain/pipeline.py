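"""End-to-end analysis runs: segmentation -> lattice -> mechanics/frequency.

``analyze_series`` is the in-memory spine (used by the CLI, the tests and
the validation script); ``run_pipeline`` wraps it with file I/O, a run
manifest, and config handling so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as _field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import ImageSeries, MeshSpec, make_field, make_uniaxial_series, \
    make_oscillatory_movie
from .segment import MeshMask, NodeSet, binarize, skeletonize, detect_nodes
from .lattice import LatticeGraph, NodeTracks, build_lattice, track_nodes
from . import mechanics
from .frequency import dominant_frequency_map

__all__ = ["RunConfig", "PipelineResult", "analyze_series", "run_pipeline"]


@dataclass
class PipelineResult:
    """In-memory products of one analysis run."""

    masks: list
    nodesets: list
    graph: LatticeGraph
    tracks: NodeTracks
    strain: pd.DataFrame
    elements: pd.DataFrame | None = None
    dilation: pd.DataFrame | None = None


def analyze_series(series: ImageSeries, *, pitch: float, line_width: float,
                   reference: int = 0, gate: float | None = None,
                   threshold_method: str = "otsu",
                   background_subtract: bool = False,
                   fixed_threshold: float | None = None,
                   interpolate: bool = False,
                   min_ref_length: float | None = None,
                   elements: bool = True,
                   dilation_mode: str | None = None) -> PipelineResult:
    """Run segmentation, lattice reconstruction, tracking and strain.

    ``pitch`` and ``line_width`` are the mesh geometry hints in
    micrometres.  The tracking gate defaults to 0.45 * pitch; segments
    shorter than 4 pixels at the reference are excluded from strain (the
    localisation floor) unless ``min_ref_length`` overrides it.
    """
    if gate is None:
        gate = 0.45 * pitch
    if min_ref_length is None:
        min_ref_length = 4.0 * series.pixel_size
    masks, nodesets = [], []
    for t in range(series.n_frames):
        frame = series.frame(t)
        mm = skeletonize(binarize(frame, method=threshold_method,
                                  background_subtract=background_subtract,
                                  threshold=fixed_threshold))
        stack = series.frames[t] if series.is_stack else None
        ns = detect_nodes(mm, frame, pixel_size=series.pixel_size,
                          pitch_hint=pitch, line_width=line_width,
                          frame_index=t, stack=stack,
                          z_step=series.z_step or 1.0)
        masks.append(mm)
        nodesets.append(ns)
    graph = build_lattice(masks[reference], nodesets[reference],
                          line_width=line_width)
    tracks = track_nodes(nodesets, graph, gate=gate, reference=reference,
                         interpolate=interpolate)
    tracks.dt = series.dt
    strain = mechanics.segment_strain(tracks, graph, reference=reference,
                                      min_ref_length=min_ref_length)
    result = PipelineResult(masks, nodesets, graph, tracks, strain)
    if elements and graph.cells:
        result.elements = mechanics.element_strain(tracks, graph.cells,
                                                   reference=reference)
    if dilation_mode:
        result.dilation = mechanics.dilation(
            tracks, graph.cells, reference=reference, mode=dilation_mode,
            masks=masks if dilation_mode == "mask_projection" else None,
            pixel_size=series.pixel_size)
    return result


# ---------------------------------------------------------------------------
# Configured runs
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of one reproducible run; everything is echoed into the
    run manifest so defaulted values are auditable."""

    output_dir: str = "meshstrain_out"
    input: str | None = None
    pixel_size: float | None = None
    dt: float | None = None
    pitch: float | None = None
    line_width: float | None = None
    reference: int = 0
    threshold_method: str = "otsu"
    background_subtract: bool = False
    fixed_threshold: float | None = None
    gate: float | None = None
    interpolate: bool = False
    modulus_pa: float | None = None
    strain: bool = True
    dilation_mode: str | None = None
    frequency: bool = False
    downsample: int = 4
    blur_sigma: float = 1.0
    sg_window: int = 9
    sg_order: int = 3
    seed: int | None = None
    simulate: dict | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None and self.input is None:
            raise ValueError("config needs either an input path or a simulate block")
        if self.simulate is not None:
            noisy = float(self.simulate.get("noise_sigma", 0.0)) > 0
            if noisy and self.seed is None:
                raise ValueError("config rejected: noise enabled without a seed")


def _simulate_from_config(cfg: RunConfig):
    sim = dict(cfg.simulate)
    mesh = MeshSpec(**sim.pop("mesh"))
    kind = sim.pop("kind", "uniaxial_series")
    sim.setdefault("seed", cfg.seed)
    if kind == "uniaxial_series":
        return make_uniaxial_series(mesh, **sim)
    if kind == "oscillatory_movie":
        sim["periods"] = [tuple(p) for p in sim["periods"]]
        return make_oscillatory_movie(mesh, **sim)
    raise ValueError(f"unknown simulate kind {kind!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages, writing CSV/TIFF outputs plus a run
    manifest; rerunning the same config reproduces the outputs exactly for
    deterministic stages."""
    from .io import read_series, write_series, nodes_to_csv

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    truth = None
    if config.simulate is not None:
        series, truth = _simulate_from_config(config)
        write_series(series, out / "simulated.tif")
        truth.to_csv(out)
        outputs["simulated"] = str(out / "simulated.tif")
    else:
        series = read_series(config.input, pixel_size=config.pixel_size,
                             dt=config.dt)
    pitch = config.pitch or (config.simulate or {}).get("mesh", {}).get("pitch")
    line_width = config.line_width or (config.simulate or {}).get(
        "mesh", {}).get("line_width")

    if config.strain:
        from .io import write_masks

        if pitch is None or line_width is None:
            raise ValueError(
                "pitch and line_width are required (config or simulate block)")
        res = analyze_series(series, pitch=pitch, line_width=line_width,
                             reference=config.reference, gate=config.gate,
                             threshold_method=config.threshold_method,
                             background_subtract=config.background_subtract,
                             fixed_threshold=config.fixed_threshold,
                             interpolate=config.interpolate,
                             dilation_mode=config.dilation_mode)
        nodes_to_csv(res.nodesets, out / "nodes.csv")
        write_masks(res.masks, out / "masks.tif")
        outputs["masks"] = str(out / "masks.tif")
        res.graph.segments_table().to_csv(out / "graph.csv", index=False)
        res.graph.cells_table().to_csv(out / "cells.csv", index=False)
        res.tracks.to_frame().to_csv(out / "tracks.csv", index=False)
        strain = res.strain
        if config.modulus_pa:
            strain = mechanics.stress_estimate(strain, config.modulus_pa)
        strain.to_csv(out / "strain.csv", index=False)
        outputs.update({k: str(out / f"{k}.csv") for k in
                        ("nodes", "graph", "cells", "tracks", "strain")})
        if res.elements is not None:
            res.elements.to_csv(out / "elements.csv", index=False)
            outputs["elements"] = str(out / "elements.csv")
        if res.dilation is not None:
            res.dilation.to_csv(out / "dilation.csv", index=False)
            outputs["dilation"] = str(out / "dilation.csv")

    if config.frequency:
        import tifffile
        mask0 = binarize(series.frame(config.reference),
                         method=config.threshold_method,
                         background_subtract=config.background_subtract,
                         threshold=config.fixed_threshold).mask
        fmap = dominant_frequency_map(series, mask0,
                                      downsample=config.downsample,
                                      blur_sigma=config.blur_sigma,
                                      sg_window=config.sg_window,
                                      sg_order=config.sg_order)
        tifffile.imwrite(out / "frequency_map.tif",
                         fmap.frequencies.astype(np.float32))
        fmap.histogram().to_csv(out / "frequency_histogram.csv", index=False)
        (out / "frequency_provenance.json").write_text(
            json.dumps(fmap.provenance, indent=2, sort_keys=True))
        outputs["frequency_map"] = str(out / "frequency_map.tif")

    manifest = {"version": __version__,
                "config": dataclasses.asdict(config),
                "outputs": sorted(outputs)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    outputs["manifest"] = str(out / "manifest.json")
    return outputs
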