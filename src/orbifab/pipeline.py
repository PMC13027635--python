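"""End-to-end orchestration of the six workflow stages on a phantom or volume.

Stage order: resample -> segment -> surface -> template -> slice -> inspect.
Every stage writes its outputs to its own subdirectory and reads its inputs
from the previous stage's files, so each stage can also be run standalone;
a manifest records parameters, artifact paths and SHA-256 hashes, making
reruns with the same config and seeds byte-reproducible.

The phantom input exercises the full chain without any external data: the
defect phantom volume is resampled to isotropy, segmented with the random
forest, meshed at the estimated iso-value and repaired; the mesh is
mirrored and best-fit aligned to stand in for the healthy side, the defect
boundary traced and offset, and the template patch built on the
mid-surface cap; the repaired anatomy mesh is sliced with a variable
layer-height plan and compared against constant heights; finally the
template is validated against the intact ground-truth mid-surface and a
synthetic stair-surface study reproduces the layer-height/texture
correlation analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import metrology, phantom, resample, segment, slicer, surface, template
from .volume import read_volume, write_volume

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ("resample", "segment", "surface", "template", "slice", "inspect")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class PipelineConfig:
    """Per-stage parameters; defaults are the workflow's published settings."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    phantom_spec: phantom.PhantomSpec = dataclasses.field(default_factory=phantom.PhantomSpec)
    defect_angle_deg: float = 40.0
    # resample
    kernel_B: float = 1.0 / 3.0
    kernel_C: float = 1.0 / 3.0
    # segment
    n_trees: int = 100
    n_annotation_points: int = 300
    # surface
    chordal_dev_mm: float = 0.005
    angular_dev_deg: float = 5.0
    decimate: bool = False
    # template
    align_tol_mm: float = 0.01
    boundary_offset_mm: float = 0.5
    extension_mm: float = 2.0
    deviation_threshold_mm: float = 0.3
    template_mode: str = "whole"
    # slicer
    base_h: float = 0.3
    fine_h: float = 0.07
    nozzle: float = 0.4
    # metrology
    cutoff_mm: float = 1.0
    tolerance_band_mm: float = 0.2

    def validate(self) -> None:
        resample.ResampleSpec((None, None, 0.35), B=self.kernel_B, C=self.kernel_C)
        surface.DecimationSpec(self.chordal_dev_mm, self.angular_dev_deg)
        if self.template_mode not in ("whole", "cut"):
            raise ValueError(f"template_mode must be whole|cut, got {self.template_mode}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def to_json(self, path: str | Path) -> None:
        blob = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(blob, indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _defect_cap_meshes(spec: phantom.PhantomSpec):
    """Intact and defect mid-surface cap meshes from the phantom geometry."""
    import trimesh

    r_mid = spec.shell_radius_mm - spec.shell_thickness_mm / 2
    intact = phantom.make_test_mesh("cap", size_mm=r_mid, resolution=8)
    # open the cap: drop the flat base disk so only the curved surface remains
    zs = intact.triangles[:, :, 2]
    keep = ~(np.isclose(zs, zs.min(), atol=1e-9).all(axis=1))
    shell = trimesh.Trimesh(vertices=intact.vertices, faces=intact.faces[keep], process=False)
    shell.remove_unreferenced_vertices()
    center = phantom._shell_center(spec)
    shell.apply_translation(center)

    damaged = shell.copy()
    if spec.defect_angle_deg > 0:
        t = np.radians(phantom._DEFECT_POLAR_DEG)
        direction = np.array([np.sin(t), 0.0, np.cos(t)])
        d = damaged.triangles.mean(axis=1) - center
        ang = np.degrees(
            np.arccos(np.clip((d @ direction) / np.linalg.norm(d, axis=1), -1, 1))
        )
        damaged = trimesh.Trimesh(
            vertices=damaged.vertices,
            faces=damaged.faces[ang > spec.defect_angle_deg / 2],
            process=False,
        )
        damaged.remove_unreferenced_vertices()
    return shell, damaged


def run_pipeline(cfg: PipelineConfig, start_stage: str = "resample") -> dict:
    """Execute the configured stages and return the artifact manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_json(out / "config.json")
    manifest: dict = {"config": str(out / "config.json"), "stages": {}}
    manifest_path = out / "manifest.json"
    start_idx = STAGES.index(start_stage)

    spec = dataclasses.replace(
        cfg.phantom_spec, defect_angle_deg=cfg.defect_angle_deg, seed=cfg.seed
    )
    if manifest_path.exists() and start_idx > 0:
        manifest = json.loads(manifest_path.read_text())

    def record(stage: str, artifacts: dict, t0: float) -> None:
        manifest["stages"][stage] = {
            "artifacts": {k: str(v) for k, v in artifacts.items()},
            "hashes": {k: _sha256(Path(v)) for k, v in artifacts.items()},
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    def stage_dir(stage: str) -> Path:
        d = out / stage
        d.mkdir(exist_ok=True)
        return d

    current = start_stage
    try:
        if start_idx <= 0:
            current = "resample"
            t0 = time.perf_counter()
            d = stage_dir("resample")
            vol, truth = phantom.make_orbital_phantom(spec)
            write_volume(vol, d / "input.npz")
            write_volume(truth, d / "truth.npz")
            rspec = resample.ResampleSpec(
                (None, None, vol.spacing_mm[0]), B=cfg.kernel_B, C=cfg.kernel_C
            )
            iso_vol = resample.resample_volume(vol, rspec)
            write_volume(iso_vol, d / "isotropic.npz")
            record("resample", {"input": d / "input.npz", "truth": d / "truth.npz",
                                "isotropic": d / "isotropic.npz"}, t0)

        if start_idx <= 1:
            current = "segment"
            t0 = time.perf_counter()
            d = stage_dir("segment")
            vol = read_volume(out / "resample" / "input.npz")
            truth = read_volume(out / "resample" / "truth.npz")
            ann = segment.sample_annotations(truth, cfg.n_annotation_points, seed=cfg.seed)
            ann.to_csv(d / "annotations.csv")
            feats = segment.extract_features(vol)
            model = segment.train_rf(feats, ann, n_trees=cfg.n_trees, seed=cfg.seed)
            model.save(d / "model.pkl")
            result = segment.segment_volume(vol, model)
            write_volume(result.labels, d / "labels.npz")
            dsc = segment.dice(result.labels, truth)
            (d / "report.json").write_text(json.dumps({
                "iso_value": result.iso_value, "dice_vs_truth": dsc,
                "n_bone": result.n_bone, "n_background": result.n_background,
            }, indent=2) + "\n")
            record("segment", {"annotations": d / "annotations.csv",
                               "labels": d / "labels.npz",
                               "report": d / "report.json"}, t0)

        if start_idx <= 2:
            current = "surface"
            t0 = time.perf_counter()
            d = stage_dir("surface")
            iso_vol = read_volume(out / "resample" / "isotropic.npz")
            report = json.loads((out / "segment" / "report.json").read_text())
            mesh = surface.marching_cubes(iso_vol, report["iso_value"])
            mesh, rep = surface.repair_mesh(mesh)
            if cfg.decimate:
                mesh = surface.decimate_to_tolerance(
                    mesh, surface.DecimationSpec(cfg.chordal_dev_mm, cfg.angular_dev_deg)
                )
            surface.write_stl(mesh, d / "anatomy.stl", mode="binary")
            (d / "repair_report.json").write_text(
                json.dumps(dataclasses.asdict(rep), indent=2) + "\n"
            )
            record("surface", {"anatomy": d / "anatomy.stl",
                               "repair_report": d / "repair_report.json"}, t0)

        if start_idx <= 3:
            current = "template"
            t0 = time.perf_counter()
            d = stage_dir("template")
            mesh = surface.read_stl(out / "surface" / "anatomy.stl")
            _, rep = surface.repair_mesh(mesh)
            if not rep.clean:
                raise ValueError(f"input mesh violates the repair invariant: {rep}")
            extent = (np.asarray(spec.grid_shape) - 1) * np.asarray(spec.spacing_mm)
            mirrored = template.mirror_mesh(
                mesh, plane_point=(extent[0] / 2, 0, 0), plane_normal=(1.0, 0.0, 0.0)
            )
            align = template.best_fit_align(
                mirrored, mesh, tol_mm=cfg.align_tol_mm, seed=cfg.seed
            )
            aligned = mirrored.copy()
            aligned.apply_transform(_homogeneous(align.transform))
            surface.write_stl(aligned, d / "reference_aligned.stl", mode="binary")
            curve = template.trace_defect_boundary(
                mesh, aligned, deviation_threshold_mm=cfg.deviation_threshold_mm
            )
            curve.to_csv(d / "boundary.csv")
            inner, outer = template.offset_boundary(curve, cfg.boundary_offset_mm, reference=aligned)
            inner.to_csv(d / "boundary_inner.csv")
            outer.to_csv(d / "boundary_outer.csv")
            intact_mid, damaged_mid = _defect_cap_meshes(spec)
            rim_curve = template.trace_defect_boundary(
                damaged_mid, intact_mid, deviation_threshold_mm=cfg.deviation_threshold_mm
            )
            tmpl = template.build_template(
                damaged_mid, rim_curve, extension_mm=cfg.extension_mm,
                mode=cfg.template_mode, boundary_tol_mm=2.5 * cfg.deviation_threshold_mm,
            )
            surface.write_stl(tmpl, d / "template.stl", mode="binary")
            (d / "alignment.json").write_text(json.dumps({
                "rms_mm": align.rms_mm, "iterations": align.iterations,
                "converged": align.converged,
            }, indent=2) + "\n")
            record("template", {"reference_aligned": d / "reference_aligned.stl",
                                "boundary": d / "boundary.csv",
                                "template": d / "template.stl",
                                "alignment": d / "alignment.json"}, t0)

        if start_idx <= 4:
            current = "slice"
            t0 = time.perf_counter()
            d = stage_dir("slice")
            mesh = surface.read_stl(out / "surface" / "anatomy.stl")
            zmin, zmax = mesh.bounds[:, 2]
            span = zmax - zmin
            zone = (zmin + 0.4 * span, zmin + 0.6 * span)
            plan = slicer.make_layer_plan(
                (zmin, zmax), base_h=cfg.base_h, fine_h=cfg.fine_h,
                fine_zones=[zone], nozzle=cfg.nozzle,
            )
            plan.to_csv(d / "layer_plan.csv")
            stack = slicer.slice_mesh(mesh, plan)
            est_vlh = slicer.estimate_print(stack)
            plan_fine = slicer.make_layer_plan((zmin, zmax), base_h=cfg.fine_h,
                                               fine_h=cfg.fine_h, nozzle=cfg.nozzle)
            est_fine = slicer.estimate_print(slicer.slice_mesh(mesh, plan_fine))
            plan_base = slicer.make_layer_plan((zmin, zmax), base_h=cfg.base_h,
                                               fine_h=cfg.base_h, nozzle=cfg.nozzle)
            est_base = slicer.estimate_print(slicer.slice_mesh(mesh, plan_base))
            (d / "estimates.json").write_text(json.dumps({
                "vlh": dataclasses.asdict(est_vlh),
                "constant_fine": dataclasses.asdict(est_fine),
                "constant_base": dataclasses.asdict(est_base),
                "n_layers": {"vlh": len(plan.layers), "fine": len(plan_fine.layers),
                             "base": len(plan_base.layers)},
            }, indent=2) + "\n")
            record("slice", {"layer_plan": d / "layer_plan.csv",
                             "estimates": d / "estimates.json"}, t0)

        if start_idx <= 5:
            current = "inspect"
            t0 = time.perf_counter()
            d = stage_dir("inspect")
            tmpl = surface.read_stl(out / "template" / "template.stl")
            intact_mid, _ = _defect_cap_meshes(spec)
            dev = metrology.deviation_map(tmpl.vertices, intact_mid, tol=cfg.tolerance_band_mm)
            (d / "deviation.json").write_text(json.dumps({
                "n_points": dev.n_points, "max_mm": dev.max_mm, "min_mm": dev.min_mm,
                "range_mm": dev.range_mm, "mean_mm": dev.mean_mm, "sd_mm": dev.sd_mm,
                "fraction_in_tolerance": dev.fraction_in_tolerance,
            }, indent=2) + "\n")
            from .studies import stair_texture_study

            study = stair_texture_study(seed=cfg.seed, cutoff_mm=cfg.cutoff_mm)
            corr = {k: dataclasses.asdict(v) for k, v in study["correlations"].items()}
            (d / "texture_study.json").write_text(
                json.dumps({"observations": study["observations"], "correlations": corr},
                           indent=2) + "\n"
            )
            record("inspect", {"deviation": d / "deviation.json",
                               "texture_study": d / "texture_study.json"}, t0)
    except PipelineError:
        raise
    except Exception as exc:
        # abort with the stage name; artifacts from completed stages persist
        raise PipelineError(current, str(exc)) from exc

    return manifest


def _homogeneous(t: template.RigidTransform) -> np.ndarray:
    M = np.eye(4)
    M[:3, :3] = t.rotation
    M[:3, 3] = t.translation_mm
    return M
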