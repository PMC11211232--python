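"""End-to-end pipeline: simulate -> physio -> fNAV -> correct -> bin ->
reconstruct -> decode -> combine -> quantify.

Every stage reads its inputs from and persists its outputs to a session
directory, so the stages can be run individually (the CLI wraps exactly
these functions) or all at once with :func:`run_pipeline`.  All randomness
derives from the single config seed; identical config + seed gives an
identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .acquisition import make_coil_maps, simulate_scan
from .flowquant import (
    FlowReport,
    PlaneSpec,
    agreement_stats,
    align_peak_systole,
    contrast_ratio,
    dice_coefficient,
    extract_plane,
    flow_metrics,
    segment_vessel_dynamic,
)
from .moco import MotionModel, apply_respiratory_correction, fit_fnav_coefficients
from .operators import Grid
from .phantom import PhantomConfig, make_phantom, simulate_pt
from .physio import BinningConfig, PhysioRecord, assign_cardiac_phase, extract_physio
from .recon import (
    Cine4D,
    Flow4D,
    ReconConfig,
    combine_synaps,
    decode_velocity,
    gridded_recon,
    kt_sparse_sense,
    normalize_raw,
    reconstruct_flow_segments,
)
from .trajectory import build_schedule, fiss_config, pc_config

__all__ = ["default_config", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("synaps")


def default_config() -> dict:
    """Desk-scale 2D session defaults.

    The schedule structure (24 = 6x4 and 21 = 1 SI + 5x4 readouts per
    interleave) matches the full-scale sequences; interleave counts are
    reduced and the TR stretched so that a desk-scale run still spans many
    cardiac and respiratory cycles.
    """
    return {
        "seed": 0,
        "grid": {"size": 64, "voxel_mm": 2.0, "mode": "2d"},
        "phantom": {
            "heart_rate_hz": 1.2,
            "resp_rate_hz": 0.25,
            "resp_amplitude_mm": [0.0, 0.0, 8.0],
            "stroke_volume_ml": 30.0,
            "vessel_radius_mm": 10.0,
        },
        "n_coils": 4,
        "noise_sd": 0.5,  # complex k-space noise, a.u.
        "fiss": {"n_interleaves": 25, "tr_ms": 50.0},
        "pc": {"n_interleaves": 40, "tr_ms": 40.0, "venc_cm_s": 150.0},
        "gap_s": 1.5,
        "pt": {
            "n_channels": 12,
            "fs": 50.0,
            "noise_sd": 0.1,
            "drift_per_min": 0.5,
            "step_offset": 1.0,
        },
        "n_phases": 20,
        "recon": {
            "fiss": {"lambda_cardiac": 0.03, "lambda_spatial": 0.015},
            "pc": {"lambda_cardiac": 0.0075, "lambda_spatial": 0.015},
            "n_iterations": 30,
            "tolerance": 1e-5,
        },
    }


def load_config(path_or_dict) -> dict:
    cfg = default_config()
    if path_or_dict is None:
        return cfg
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as f:
            user = yaml.safe_load(f) or {}
    else:
        user = dict(path_or_dict)

    def merge(base, upd):
        for k, v in upd.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                merge(base[k], v)
            else:
                base[k] = v

    merge(cfg, user)
    return cfg


def _stage(name):
    def deco(fn):
        def wrapped(cfg, outdir, **kw):
            t0 = time.perf_counter()
            h = hashlib.sha1(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest()[:12]
            log.info("stage %s: seed=%s config_hash=%s", name, cfg.get("seed"), h)
            try:
                out = fn(cfg, Path(outdir), **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            log.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
            return out

        wrapped.__name__ = f"stage_{name}"
        return wrapped

    return deco


def _phantom_from_config(cfg) -> "DynamicPhantom":
    g = cfg["grid"]
    pcfg = PhantomConfig(
        grid_size=g["size"],
        voxel_mm=g["voxel_mm"],
        mode=g["mode"],
        seed=cfg["seed"],
        **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in cfg["phantom"].items()
        },
    )
    return make_phantom(pcfg)


@_stage("simulate")
def stage_simulate(cfg, outdir):
    """Simulate the back-to-back anatomical + flow session with shared PT."""
    outdir.mkdir(parents=True, exist_ok=True)
    phantom = _phantom_from_config(cfg)
    grid = phantom.config.grid
    seq_common = dict(
        fov_mm=grid.fov_mm, resolution_mm=grid.voxel_mm, mode=grid.mode
    )
    f_cfg = fiss_config(**seq_common, **cfg["fiss"])
    fiss_sched = build_schedule(f_cfg, start_time=0.0)
    fiss_end = fiss_sched.timestamps[-1] + f_cfg.tr_ms * 1e-3
    gap = cfg["gap_s"]
    p_cfg = pc_config(**seq_common, **cfg["pc"])
    pc_sched = build_schedule(p_cfg, start_time=fiss_end + gap)
    duration = pc_sched.timestamps[-1] + p_cfg.tr_ms * 1e-3 + 1.0
    pt = simulate_pt(
        phantom,
        n_channels=cfg["pt"]["n_channels"],
        fs=cfg["pt"]["fs"],
        noise_sd=cfg["pt"]["noise_sd"],
        drift_per_min=cfg["pt"]["drift_per_min"],
        duration_s=duration,
        gap_time_s=fiss_end + gap / 2,
        step_offset=cfg["pt"]["step_offset"],
        seed=cfg["seed"] + 101,
    )
    coils = make_coil_maps(cfg["n_coils"], grid, seed=cfg["seed"] + 7)
    raw_fiss = simulate_scan(
        phantom, fiss_sched, cfg["noise_sd"], coil_maps=coils, pt=pt,
        seed=cfg["seed"] + 11,
    )
    raw_pc = simulate_scan(
        phantom, pc_sched, cfg["noise_sd"], coil_maps=coils, pt=pt,
        seed=cfg["seed"] + 13,
    )
    sio.write_raw(outdir / "fiss_raw.h5", raw_fiss)
    sio.write_raw(outdir / "pc_raw.h5", raw_pc)
    manifest = sio.SessionManifest(
        fiss_raw=str(outdir / "fiss_raw.h5"),
        pc_raw=str(outdir / "pc_raw.h5"),
        pt_source="simulated (shared record, both sequences)",
        config_snapshot=cfg,
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest


@_stage("physio")
def stage_physio(cfg, outdir):
    """Extract cardiac triggers + respiratory curve from the shared PT."""
    raw = sio.read_raw(outdir / "fiss_raw.h5")
    rec = extract_physio(raw.pt, raw.pt.fs, gap_time=raw.pt.gap_time_s)
    with h5py.File(outdir / "physio.h5", "w") as f:
        g = f.create_group("physio")
        g.create_dataset("cardiac_signal", data=rec.cardiac_signal)
        g.create_dataset("trigger_times", data=rec.trigger_times)
        g.create_dataset("resp_curve", data=rec.resp_curve)
        g.attrs["fs_hz"] = rec.fs
    np.savetxt(outdir / "triggers_s.txt", rec.trigger_times, fmt="%.6f")
    return rec


def _load_physio(outdir) -> PhysioRecord:
    with h5py.File(Path(outdir) / "physio.h5", "r") as f:
        g = f["physio"]
        return PhysioRecord(
            cardiac_signal=g["cardiac_signal"][()],
            trigger_times=g["trigger_times"][()],
            resp_curve=g["resp_curve"][()],
            fs=float(g.attrs["fs_hz"]),
        )


@_stage("moco")
def stage_moco(cfg, outdir):
    """Fit fNAV on the anatomical data; correct both sequences' k-space."""
    rec = _load_physio(outdir)
    raw_fiss = sio.read_raw(outdir / "fiss_raw.h5")
    raw_pc = sio.read_raw(outdir / "pc_raw.h5")
    model = fit_fnav_coefficients(
        raw_fiss, r=rec.resp_curve, resp_times=rec.times
    )
    (outdir / "motion.json").write_text(
        json.dumps(
            {
                "coeffs_mm": model.coeffs_mm.tolist(),
                "entropy": model.entropy,
                "roi": model.roi,
                "trace": [[list(c), float(h)] for c, h in model.trace],
            },
            indent=2,
        )
    )
    for name, raw in (("fiss", raw_fiss), ("pc", raw_pc)):
        corrected = apply_respiratory_correction(raw, model)
        sio.write_raw(outdir / f"{name}_raw.h5", raw, corrected=corrected.samples)
    return model


def _load_motion(outdir, rec: PhysioRecord) -> MotionModel:
    d = json.loads((Path(outdir) / "motion.json").read_text())
    return MotionModel(
        coeffs_mm=np.asarray(d["coeffs_mm"]),
        resp_times=rec.times,
        resp_values=rec.resp_curve,
        entropy=d["entropy"],
        roi=tuple(tuple(x) for x in d["roi"]) if d["roi"] else None,
    )


@_stage("recon")
def stage_recon(cfg, outdir):
    """Bin, normalize and reconstruct both sequences; decode velocity."""
    rec = _load_physio(outdir)
    binning = BinningConfig(n_phases=cfg["n_phases"])
    rr_s = float(np.median(np.diff(rec.trigger_times)))
    it = cfg["recon"].get("n_iterations", 30)
    tol = cfg["recon"].get("tolerance", 1e-5)
    out = {}
    for name, rcfg_key in (("fiss", "fiss"), ("pc", "pc")):
        raw = sio.read_raw(outdir / f"{name}_raw.h5")  # corrected data if present
        bins = assign_cardiac_phase(raw.schedule.timestamps, rec.trigger_times, binning)
        raw, scale = normalize_raw(raw)
        rcfg = ReconConfig(
            lambda_cardiac=cfg["recon"][rcfg_key]["lambda_cardiac"],
            lambda_spatial=cfg["recon"][rcfg_key]["lambda_spatial"],
            n_iterations=it,
            tolerance=tol,
        )
        if name == "fiss":
            res = kt_sparse_sense(raw, bins, rcfg, n_phases=binning.n_phases)
            cine = Cine4D(
                magnitude=np.abs(res.volumes),
                voxel_mm=raw.grid.voxel_mm,
                rr_s=rr_s,
            )
            np.savez(outdir / "cine_fiss.npz", magnitude=cine.magnitude, rr_s=rr_s)
            sio.export_volumes(cine, outdir / "cine_fiss")
            traces = {"fiss": res.objective_trace}
            out["fiss"] = cine
        else:
            segments, seg_traces = reconstruct_flow_segments(
                raw, bins, rcfg, n_phases=binning.n_phases
            )
            venc = raw.schedule.config.venc_cm_s
            velocity, wrapped = decode_velocity(segments, venc)
            flow = Flow4D(
                velocity=velocity,
                magnitude=np.mean(np.abs(segments), axis=0),
                venc_cm_s=venc,
                voxel_mm=raw.grid.voxel_mm,
                rr_s=rr_s,
                wrapped=wrapped,
            )
            np.savez(
                outdir / "flow_pc.npz",
                velocity=flow.velocity,
                magnitude=flow.magnitude,
                wrapped=wrapped,
                venc=venc,
                rr_s=rr_s,
            )
            sio.export_volumes(flow, outdir / "flow_pc")
            traces = {f"pc_seg{i}": t for i, t in enumerate(seg_traces)}
            out["pc"] = flow
        pd.DataFrame(
            {k: pd.Series(v) for k, v in traces.items()}
        ).to_csv(outdir / f"objective_trace_{name}.csv", index=False)
        bins_path = outdir / f"bins_{name}.npy"
        np.save(bins_path, bins)
    return out


def _load_volumes(outdir):
    outdir = Path(outdir)
    z = np.load(outdir / "cine_fiss.npz")
    cine = Cine4D(magnitude=z["magnitude"], voxel_mm=None, rr_s=float(z["rr_s"]))
    zf = np.load(outdir / "flow_pc.npz")
    flow = Flow4D(
        velocity=zf["velocity"],
        magnitude=zf["magnitude"],
        venc_cm_s=float(zf["venc"]),
        voxel_mm=None,
        rr_s=float(zf["rr_s"]),
        wrapped=zf["wrapped"],
    )
    return cine, flow


@_stage("combine")
def stage_combine(cfg, outdir):
    """SyNAPS combination: anatomical magnitude + flow velocity."""
    cine, flow = _load_volumes(outdir)
    voxel = cfg["grid"]["voxel_mm"]
    cine.voxel_mm = voxel
    flow.voxel_mm = voxel
    combined = combine_synaps(cine, flow)
    np.savez(
        outdir / "synaps_4dflow.npz",
        magnitude=combined.magnitude,
        velocity=combined.velocity,
        venc=combined.venc_cm_s,
        rr_s=combined.rr_s,
    )
    sio.export_volumes(combined, outdir / "synaps_4dflow")
    return combined


def _roi_boxes(phantom):
    """Blood (DAo) and myocardium ROI boxes from the phantom geometry."""
    grid = phantom.config.grid
    n = grid.size
    vox = grid.voxel_mm

    def to_pix(mm):
        return int(round(mm / vox + n / 2))

    from .phantom import _HEART_CENTER, _HEART_OUTER, _POOL_RADIUS

    dao = phantom.vessel_centers_mm()[1]
    by, bz = to_pix(dao[0]), to_pix(dao[1])
    blood = ((by - 2, by + 2), (bz - 2, bz + 2))
    fov = grid.fov_mm
    hc = np.array(_HEART_CENTER) * fov
    ring_mm = 0.5 * (_HEART_OUTER + _POOL_RADIUS) * fov
    my, mz = to_pix(hc[0]), to_pix(hc[1] + ring_mm)
    myo = ((my - 1, my + 1), (mz - 1, mz + 1))
    return blood, myo


@_stage("quantify")
def stage_quantify(cfg, outdir):
    """Segment the vessels, compute flow curves and agreement statistics."""
    phantom = _phantom_from_config(cfg)
    grid = phantom.config.grid
    cine, flow = _load_volumes(outdir)
    voxel = cfg["grid"]["voxel_mm"]
    cine.voxel_mm = voxel
    flow.voxel_mm = voxel
    combined = combine_synaps(cine, flow)
    P = combined.n_phases
    rr_s = combined.rr_s
    n = grid.size

    def to_pix(mm):
        return mm / voxel + n / 2

    centers = phantom.vessel_centers_mm()
    tau_centers = (np.arange(P) + 0.5) / P
    report = {"planes": {}, "contrast": {}, "n_phases": P, "rr_s": rr_s}

    # blood-to-myocardium contrast on the phase-averaged magnitudes
    blood_roi, myo_roi = _roi_boxes(phantom)
    fiss_mag = combined.magnitude.mean(axis=-1)
    pc_mag = flow.magnitude.mean(axis=-1)
    report["contrast"]["fiss_blood_myocardium"] = contrast_ratio(
        fiss_mag, blood_roi, myo_roi
    )
    report["contrast"]["pc_blood_myocardium"] = contrast_ratio(
        pc_mag, blood_roi, myo_roi
    )

    for label, center, sign in (("AAo", centers[0], 1.0), ("DAo", centers[1], -1.0)):
        normal = (sign, 0.0, 0.0)  # physiologic systolic flow positive
        plane = PlaneSpec(axis="x", index=0, normal=normal, label=label)
        mag_syn, v_syn = extract_plane(combined, plane)
        native = Flow4D(
            velocity=flow.velocity,
            magnitude=flow.magnitude,
            venc_cm_s=flow.venc_cm_s,
            voxel_mm=voxel,
            rr_s=rr_s,
        )
        mag_nat, v_nat = extract_plane(native, plane)
        seed = (to_pix(center[0]), to_pix(center[1]))
        masks_syn = segment_vessel_dynamic(mag_syn, seed)
        masks_nat = segment_vessel_dynamic(mag_nat, seed)
        truth_masks = np.stack(
            [
                phantom.true_vessel_mask(
                    tau / phantom.config.heart_rate_hz,
                    vessel=0 if label == "AAo" else 1,
                    include_resp=False,
                )
                for tau in tau_centers
            ],
            axis=-1,
        )
        # ground-truth flow curve, bin-averaged like the reconstruction
        tau_fine = (np.arange(P * 64) + 0.5) / (P * 64)
        q_true = phantom.true_flow_curve(tau_fine).reshape(P, 64).mean(axis=1)
        area_true = (np.pi * phantom.vessel_radius_at(tau_fine) ** 2).reshape(
            P, 64
        ).mean(axis=1)
        m_syn = flow_metrics(masks_syn, v_syn, voxel, rr_s)
        m_nat = flow_metrics(masks_nat, v_nat, voxel, rr_s)
        shifts = align_peak_systole([q_true, m_syn["q_ml_s"], m_nat["q_ml_s"]])
        q_syn = np.roll(m_syn["q_ml_s"], shifts[1])
        a_syn = np.roll(m_syn["area_mm2"], shifts[1])
        q_nat = np.roll(m_nat["q_ml_s"], shifts[2])
        a_nat = np.roll(m_nat["area_mm2"], shifts[2])
        fr = FlowReport(
            label=label,
            area_mm2=m_syn["area_mm2"],
            q_ml_s=m_syn["q_ml_s"],
            net_volume_ml=m_syn["net_volume_ml"],
            peak_flow_ml_s=m_syn["peak_flow_ml_s"],
            stats={
                "synaps_vs_truth_area": agreement_stats(a_syn, area_true),
                "native_vs_truth_area": agreement_stats(a_nat, area_true),
                "synaps_vs_truth_flow": agreement_stats(q_syn, q_true),
            },
        )
        dice_syn = np.mean(
            [dice_coefficient(masks_syn[..., p], truth_masks[..., p]) for p in range(P)]
        )
        dice_nat = np.mean(
            [dice_coefficient(masks_nat[..., p], truth_masks[..., p]) for p in range(P)]
        )
        entry = fr.to_dict()
        entry.update(
            {
                "native_net_volume_ml": m_nat["net_volume_ml"],
                "native_peak_flow_ml_s": m_nat["peak_flow_ml_s"],
                "true_net_volume_ml": phantom.config.stroke_volume_ml,
                "true_peak_flow_ml_s": float(q_true.max()),
                "dice_synaps_vs_truth": float(dice_syn),
                "dice_native_vs_truth": float(dice_nat),
                "area_pearson_synaps": fr.stats["synaps_vs_truth_area"]["pearson_r"],
                "area_pearson_native": fr.stats["native_vs_truth_area"]["pearson_r"],
            }
        )
        report["planes"][label] = entry
        pd.DataFrame(
            {
                "phase": np.arange(P),
                "area_mm2": m_syn["area_mm2"],
                "q_ml_s": m_syn["q_ml_s"],
            }
        ).to_csv(outdir / f"curve_{label}.csv", index=False)
        mask_vol = Cine4D(
            magnitude=masks_syn.astype(np.float32), voxel_mm=voxel, rr_s=rr_s
        )
        sio.export_volumes(mask_vol, outdir / f"mask_{label}")

    n_pairs = 2 * len(report["planes"])  # Bonferroni divisor at reporting level
    report["bonferroni_factor"] = n_pairs
    if (outdir / "motion.json").exists():
        report["motion"] = json.loads((outdir / "motion.json").read_text())
        report["motion"].pop("trace", None)
    (outdir / "flow_report.json").write_text(json.dumps(report, indent=2))
    return report


STAGES = {
    "simulate": stage_simulate,
    "physio": stage_physio,
    "moco": stage_moco,
    "recon": stage_recon,
    "combine": stage_combine,
    "quantify": stage_quantify,
}


def run_pipeline(config, outdir):
    """Run all stages; returns (SessionManifest, flow report dict)."""
    cfg = load_config(config)
    outdir = Path(outdir)
    manifest = stage_simulate(cfg, outdir)
    stage_physio(cfg, outdir)
    stage_moco(cfg, outdir)
    stage_recon(cfg, outdir)
    stage_combine(cfg, outdir)
    report = stage_quantify(cfg, outdir)
    return manifest, report
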