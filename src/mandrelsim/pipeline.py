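"""End-to-end pipeline driver: volume → mesh → centerline → catheter
path → shaped path → bending template, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import io as msio
from .catheter_sim import GrowthParams, PickedPoints, grow_catheter
from .centerline import compute_centerline
from .phantom import PhantomSpec, make_phantom, suggest_picks
from .segmentation import extract_surface, levelset_refine, threshold_segment
from .shaping import ShapingParams, make_template, shape_transform

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are kept on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Exactly one of ``phantom`` (a PhantomSpec or its field dict) or
    ``volume_path`` must be given.  Picks can come from a JSON file or,
    for phantoms, be suggested automatically.
    """

    out_dir: str = "mandrelsim_out"
    phantom: Optional[object] = None
    volume_path: Optional[str] = None
    picks_path: Optional[str] = None
    threshold: float = 50.0
    levelset_iters: int = 25
    levelset_smoothing: int = 1
    centerline_step: float = 0.5
    end_at: str = "click"  # or "sac_centroid" (phantom runs only)
    growth: GrowthParams = field(default_factory=GrowthParams)
    shaping_factor: float = 2.0
    shaping_length: float = 15.0
    coarsen_tol: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if (self.phantom is None) == (self.volume_path is None):
            raise ConfigError("give exactly one of phantom or volume_path")
        if self.volume_path is not None:
            if not os.path.exists(self.volume_path):
                raise ConfigError(f"volume not found: {self.volume_path}")
            if self.picks_path is None:
                raise ConfigError("picks_path is required for a volume input")
        if self.picks_path is not None and not os.path.exists(self.picks_path):
            raise ConfigError(f"picks file not found: {self.picks_path}")
        if self.end_at not in ("click", "sac_centroid"):
            raise ConfigError("end_at must be 'click' or 'sac_centroid'")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ConfigError("seed must be a non-negative integer")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> str:
    """Run every stage and return the artifact directory.

    Writes each intermediate artifact plus ``manifest.json`` recording
    the parameters, the seed, and a SHA-256 checksum per artifact, so a
    rerun with the same config is byte-for-byte diffable.
    """
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "setup"

    def save(name: str, writer, *args) -> str:
        path = os.path.join(out, name)
        writer(*args, path)
        artifacts[name] = path
        return path

    try:
        stage = "input"
        spec = None
        if config.phantom is not None:
            spec = (
                config.phantom
                if isinstance(config.phantom, PhantomSpec)
                else PhantomSpec(**dict(config.phantom))
            )
            ph = make_phantom(spec)
            volume = ph.volume
            save("volume.nii.gz", msio.write_volume, volume)
            save("truth_centerline.csv", msio.write_centerline_csv, ph.truth_centerline)
        else:
            volume = msio.read_volume(config.volume_path)

        stage = "segment"
        init = threshold_segment(volume, config.threshold)
        mask = levelset_refine(
            volume, init, config.levelset_iters, config.levelset_smoothing
        )
        mesh = extract_surface(mask, volume.spacing, volume.origin)
        save("mesh.stl", msio.write_mesh, mesh)

        stage = "picks"
        if config.picks_path is not None:
            picks = msio.read_picks(config.picks_path)
        else:
            picks = suggest_picks(ph, variant=config.seed)
            picks["inlet"] = np.zeros(3)
            dome = (
                spec.sac_center
                if spec.kind in ("sidewall_aneurysm", "bifurcation_aneurysm")
                else ph.truth_centerline.points[-1]
            )
            picks["dome"] = dome
        save("picks.json", msio.write_picks, picks)

        stage = "centerline"
        dome_click = picks["dome"]
        if config.end_at == "sac_centroid" and spec is not None:
            dome_click = spec.sac_center
        cl = compute_centerline(
            np.asarray(mask),
            volume.spacing,
            picks["inlet"],
            dome_click,
            origin=volume.origin,
            step=config.centerline_step,
        )
        save("centerline.csv", msio.write_centerline_csv, cl)

        stage = "simulate"
        cath_picks = PickedPoints(
            proximal_s=picks["proximal_s"],
            tip=picks["tip"],
            first_contact=picks["first_contact"],
        )
        path = grow_catheter(mesh, cl, cath_picks, config.growth, seed=config.seed)
        save("path.csv", msio.write_path_csv, path)
        save("path.vtk", msio.write_vtk_polyline, path.points)

        stage = "shape"
        sp = ShapingParams(
            config.shaping_factor,
            min(config.shaping_length, path.total_length),
        )
        shaped = shape_transform(path, sp)
        save("shaped_path.vtk", msio.write_vtk_polyline, shaped.points)
        template = make_template(shaped, config.coarsen_tol)
        save("template.csv", msio.write_template_csv, template)
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        _write_manifest(out, config, artifacts, failed_stage=stage)
        raise StageError(stage, exc) from exc

    _write_manifest(out, config, artifacts)
    return out


def _write_manifest(out, config, artifacts, failed_stage=None) -> None:
    manifest = {
        "parameters": _jsonable(asdict(config)),
        "seed": config.seed,
        "artifacts": {name: _sha256(path) for name, path in artifacts.items()},
    }
    if failed_stage is not None:
        manifest["failed_stage"] = failed_stage
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
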