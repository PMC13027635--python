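"""Synthetic validation studies: the phantom-based analogues of the
workflow's published validation.

Clinical CT scans, printed parts and optical measurements cannot be shipped
with code, so each study regenerates its inputs from seeded phantoms and
measures the corresponding quantity: segmentation quality against a
thresholding baseline, resampling gains, rigid-registration recovery,
template patch accuracy, layer-plan economy, and the layer-height versus
surface-texture correlations.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import metrology, phantom, segment, slicer, template
from .volume import LabelVolume

__all__ = [
    "segmentation_study",
    "stair_texture_study",
    "template_recovery_study",
    "vlh_economy_study",
]


def segmentation_study(
    seed: int = 0,
    n_train: int = 20,
    n_points: int = 300,
    n_trees: int = 100,
) -> dict:
    """Pooled-forest segmentation of a held-out phantom vs best threshold.

    Trains one forest on ``n_train`` seeded phantoms (``n_points``
    annotations each, the multi-dataset protocol) and evaluates Dice on a
    held-out phantom, alongside the best Dice any single global intensity
    threshold can reach on that same volume (a grid-search oracle).
    """
    X, y = [], []
    for i in range(n_train):
        spec = phantom.PhantomSpec(seed=seed + 50 + i)
        vol, truth = phantom.make_orbital_phantom(spec)
        feats = segment.extract_features(vol)
        ann = segment.sample_annotations(truth, n_points, seed=seed + 200 + i)
        X.append(feats.at(ann.indices()))
        y.append(ann.labels())
    from sklearn.ensemble import RandomForestClassifier

    forest = RandomForestClassifier(n_trees, random_state=seed, n_jobs=1)
    forest.fit(np.vstack(X), np.concatenate(y))
    model = segment.RFModel(forest=forest, schema=segment.FEATURE_SCHEMA, seed=seed)

    spec = phantom.PhantomSpec(seed=seed + 3)
    vol, truth = phantom.make_orbital_phantom(spec)
    feats = segment.extract_features(vol)
    pred = segment.classify(model, feats, spacing_mm=vol.spacing_mm)
    truth_l = LabelVolume(truth.data, vol.spacing_mm)
    return {
        "dice_rf": segment.dice(pred, truth_l),
        "dice_best_threshold": segment.best_threshold_dice(vol, truth),
        "n_train_voxels": int(sum(len(v) for v in y)),
    }


def stair_texture_study(seed: int = 0, replicates: int = 3, cutoff_mm: float = 1.0) -> dict:
    """Layer-height vs texture-parameter correlations on stair phantoms.

    Generates ``replicates`` seeded surfaces at layer heights 0.07/0.2/0.3,
    filters, computes Sa, Spk+Sk+Svk and Rsm, and correlates each with the
    layer height (the synthetic twin of the printed-replica study design).
    """
    rows = []
    for h in (0.07, 0.2, 0.3):
        for rep in range(replicates):
            spec = phantom.StairSurfaceSpec(
                layer_height_mm=h, seed=seed + 100 * rep + int(h * 1000)
            )
            hm = metrology.highpass_surface(phantom.make_stair_surface(spec), cutoff_mm)
            tp = metrology.texture_params(hm)
            rows.append(
                {
                    "layer_mm": h,
                    "Sa_um": tp.Sa_um,
                    "Spk_Sk_Svk_um": tp.Spk_um + tp.Sk_um + tp.Svk_um,
                    "Rsm_um": tp.Rsm_um,
                }
            )
    xs = [r["layer_mm"] for r in rows]
    corr = {
        key: metrology.pearson_r(xs, [r[key] for r in rows])
        for key in ("Sa_um", "Spk_Sk_Svk_um", "Rsm_um")
    }
    return {"observations": rows, "correlations": corr}


def template_recovery_study(seed: int = 0) -> dict:
    """Rigid-transform recovery and defect-patch accuracy on cap phantoms."""
    from .pipeline import _defect_cap_meshes

    cap = phantom.make_test_mesh("cap", size_mm=10, resolution=3)
    cap.apply_scale([1.0, 0.7, 1.0])  # break rotational symmetry
    ang = np.radians(5.0)
    R = np.array(
        [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
    )
    gt = template.RigidTransform(R, np.array([0.3, 0.0, 0.0]))
    src = cap.copy()
    M = np.eye(4)
    M[:3, :3] = gt.rotation
    M[:3, 3] = gt.translation_mm
    src.apply_transform(M)
    res = template.best_fit_align(src, cap, tol_mm=1e-4, seed=seed)
    pts = np.asarray(src.vertices)
    rms_vs_truth = float(
        np.sqrt(np.mean(np.sum((res.transform.apply(pts) - gt.inverse().apply(pts)) ** 2, axis=1)))
    )

    spec = phantom.PhantomSpec(defect_angle_deg=40, seed=seed)
    intact, damaged = _defect_cap_meshes(spec)
    curve = template.trace_defect_boundary(damaged, intact, deviation_threshold_mm=0.3)
    tmpl = template.build_template(
        damaged, curve, extension_mm=2.0, mode="whole", boundary_tol_mm=0.75
    )
    dev = metrology.deviation_map(np.asarray(tmpl.vertices), intact, tol=0.2)
    patch = dev.deviations_mm[len(damaged.vertices):]
    return {
        "icp_recovery_rms_mm": rms_vs_truth,
        "patch_mean_abs_dev_mm": float(np.abs(patch).mean()),
        "n_patch_points": int(len(patch)),
    }


def vlh_economy_study(seed: int = 0) -> dict:
    """Print-time comparison: variable layer height vs constant heights."""
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=3, radius=5)
    mesh.apply_translation((0, 0, 5))
    zmin, zmax = mesh.bounds[:, 2]
    times = {}
    for name, (b, f, zones) in {
        "constant_0.3": (0.3, 0.3, []),
        "constant_0.07": (0.07, 0.07, []),
        "vlh": (0.3, 0.07, [(4.0, 6.0)]),
    }.items():
        plan = slicer.make_layer_plan((zmin, zmax), b, f, fine_zones=zones)
        times[name] = slicer.estimate_print(slicer.slice_mesh(mesh, plan)).time_s
    times["vlh_over_constant_fine"] = times["vlh"] / times["constant_0.07"]
    return times
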