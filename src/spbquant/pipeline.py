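"""End-to-end orchestration: simulate -> fit -> exclude -> realign ->
average -> linescan -> metrics -> report.

Each scene is processed independently and deterministically: the reference
channel is fitted (one or two integrated 3D Gaussians), the edge-slice and
top-view exclusion rules are applied, the stack is realigned on the
old->new axis, plaque intensities are measured by query-channel fits,
the spindle linescan is profiled and mode-classified, and one row per SPB
pair is appended to the result table.  Excluded pairs carry an exclusion
reason and never contribute partial metrics, averages or linescans.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import image_io, linescan, metrics, realign, spotfit, synth
from .average import ClassAverage, average_class
from .config import RunConfig
from .image_io import ImageStack

__all__ = ["SceneOutcome", "RunResult", "process_scene", "run", "save_run"]


@dataclass
class SceneOutcome:
    row: dict
    realigned: Optional[realign.RealignedImage] = None
    profile: Optional[linescan.LineProfile] = None


@dataclass
class RunResult:
    table: pd.DataFrame
    averages: dict[tuple, ClassAverage]
    report: dict
    outcomes: list[SceneOutcome] = field(default_factory=list)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, source_id: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed on {source_id}: "
                         f"{cause}")
        self.stage = stage
        self.source_id = source_id


_ROW_DEFAULTS = dict(
    stage=None, inter_distance_um=np.nan, excluded=False, reason="",
    tie=False, ip_old=np.nan, op_old=np.nan, ratio_old=np.nan,
    ip_new=np.nan, op_new=np.nan, ratio_new=np.nan, asym_index=np.nan,
    mode=None, bridge=np.nan,
)


def _base_row(source_id: str, pair_id: str) -> dict:
    row = {"source_id": source_id, "pair_id": pair_id}
    row.update(_ROW_DEFAULTS)
    return row


def _fit_plaques(stack: ImageStack, center: np.ndarray, op_seed: np.ndarray,
                 config: RunConfig) -> tuple[spotfit.SpotFit, spotfit.SpotFit]:
    """Fit (inner, outer) plaque foci of one SPB in the query channel."""
    opt = config.optics
    roi = spotfit.default_roi(stack, [center, op_seed], opt.psf_sigma_xy,
                              opt.psf_sigma_z)
    sep = np.linalg.norm(np.asarray(op_seed) - np.asarray(center))
    fit_ip, fit_op = spotfit.fit_double(
        stack, config.channels[1], roi, center, op_seed,
        init_sigma_xy=opt.psf_sigma_xy, init_sigma_z=opt.psf_sigma_z,
        sigma_bounds=(0.7, 1.4), center_halfwidth_nm=0.5 * sep)
    return fit_ip, fit_op


def _spindle_profile(img: realign.RealignedImage, config: RunConfig,
                     sep: float) -> linescan.LineProfile:
    proj = img.projection if img.projection is not None else img.max_projection()
    c = img.center_out
    half = img.inter_distance / 2.0 + sep + 250.0
    start = np.array([c[0] - half, c[1]])
    end = np.array([c[0] + half, c[1]])
    return linescan.profile(proj, start, end, config.linescan_width_px,
                            img.voxel_xy, channels=img.channels)


def _classify_from_profile(prof: linescan.LineProfile, img,
                           config: RunConfig, sep: float,
                           op_flux_old: float, op_flux_new: float,
                           ip_flux_old: float, ip_flux_new: float
                           ) -> tuple[Optional[str], linescan.PeakSet]:
    """Mode classification of the outer-plaque label between the SPBs.

    The fold-difference is taken between the fitted outer-plaque fluxes
    (free of inner-plaque tail contamination).  The detection floor for
    "label visible at one outer plaque only" is the linescan noise floor
    (median + 3*MAD over the background margins beyond the outer plaques),
    converted to flux units via the inner-plaque peak; whole-profile
    statistics would be dominated by the plaque signal itself on these
    short, structure-filled profiles.
    """
    qch = prof.channels.index(config.channels[1])
    v = prof.channel_values(qch)
    k = max(3, int(round(200.0 / prof.pixel_nm)))
    margins = np.concatenate([v[:k], v[-k:]])
    floor = linescan.mad_floor(margins, config.thresholds.mad_factor)
    peaks = linescan.find_plaque_peaks(prof, "spindle", channel=qch,
                                       floor=floor)
    h_in = max((h for h in (peaks.height("inner_old"),
                            peaks.height("inner_new")) if h is not None),
               default=None)
    flux_in = max(ip_flux_old, ip_flux_new)
    if h_in is None or h_in <= floor or flux_in <= 0:
        return None, peaks
    floor_flux = floor / h_in * flux_in
    try:
        mode = metrics.classify_mode(op_flux_old, op_flux_new, floor_flux)
    except metrics.NoLabelError:
        mode = None
    return mode, peaks


def process_scene(stack: ImageStack, seed_points: Sequence[np.ndarray],
                  config: RunConfig, pair_id: str = "p0") -> SceneOutcome:
    """Process one stack given 1 or 2 stack-frame seed coordinates (nm)."""
    opt = config.optics
    thr = config.thresholds
    sep = config.geometry.ip_op_separation
    ref_ch, query_ch = config.channels
    row = _base_row(stack.source_id, pair_id)

    if len(seed_points) == 1:
        return _process_single(stack, seed_points[0], config, row)
    if len(seed_points) != 2:
        raise ValueError("a scene needs 1 or 2 seed points")

    # --- reference-channel dual fit -------------------------------------
    try:
        roi = spotfit.default_roi(stack, seed_points, opt.psf_sigma_xy,
                                  opt.psf_sigma_z)
        fit_a, fit_b = spotfit.fit_double(
            stack, ref_ch, roi, seed_points[0], seed_points[1],
            init_sigma_xy=opt.psf_sigma_xy, init_sigma_z=opt.psf_sigma_z)
    except Exception as exc:  # noqa: BLE001 - named stage failure
        raise StageFailure("fit", stack.source_id, exc) from exc

    assignment = realign.assign_old_new(fit_a, fit_b)
    pair = spotfit.SPBPair(fit_old=assignment.old, fit_new=assignment.new,
                           tie=assignment.tie)
    row["tie"] = pair.tie
    d_um = pair.inter_distance / 1000.0
    row["inter_distance_um"] = d_um
    row["stage"] = metrics.stage_by_distance(d_um).label

    pair = spotfit.edge_slice_exclusion(stack, list(config.channels), pair)
    if pair.excluded:
        row["excluded"], row["reason"] = True, pair.reason
        return SceneOutcome(row=row)

    old, new = pair.fit_old, pair.fit_new
    u = (new.center - old.center) / pair.inter_distance
    separated = row["stage"] != "unseparated"

    # --- query-channel plaque measurement -------------------------------
    try:
        if separated:
            ip_old, op_old = _fit_plaques(stack, old.center,
                                          old.center - sep * u, config)
            ip_new, op_new = _fit_plaques(stack, new.center,
                                          new.center + sep * u, config)
            for fi, fo in ((ip_old, op_old), (ip_new, op_new)):
                if metrics.is_top_view(fi, fo, opt.psf_sigma_xy,
                                       thr.overlap_sigma_factor):
                    row["excluded"], row["reason"] = True, "top_view"
                    return SceneOutcome(row=row)
            meas_old = metrics.PlaqueMeasurement(ip_old.amplitude,
                                                 op_old.amplitude, "old")
            meas_new = metrics.PlaqueMeasurement(ip_new.amplitude,
                                                 op_new.amplitude, "new")
        else:
            meas_old, meas_new = _side_by_side_measure(stack, pair, config,
                                                       row)
    except StageFailure:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("plaque_fit", stack.source_id, exc) from exc

    row["ip_old"], row["op_old"] = meas_old.ip_intensity, meas_old.op_intensity
    row["ip_new"], row["op_new"] = meas_new.ip_intensity, meas_new.op_intensity
    r_old = metrics.ip_op_ratio(meas_old)
    r_new = metrics.ip_op_ratio(meas_new)
    row["ratio_old"] = np.nan if r_old is None else r_old
    row["ratio_new"] = np.nan if r_new is None else r_new
    if meas_old.op_intensity + meas_new.op_intensity > 0:
        row["asym_index"] = metrics.asymmetry_index(meas_old.op_intensity,
                                                    meas_new.op_intensity)

    # --- realign + linescan + mode --------------------------------------
    try:
        img = realign.realign_stack(stack, old, new)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("realign", stack.source_id, exc) from exc

    prof = None
    if separated:
        prof = _spindle_profile(img, config, sep)
        mode, _ = _classify_from_profile(prof, img, config, sep,
                                         meas_old.op_intensity,
                                         meas_new.op_intensity,
                                         meas_old.ip_intensity,
                                         meas_new.ip_intensity)
        row["mode"] = mode
    return SceneOutcome(row=row, realigned=img, profile=prof)


def _side_by_side_measure(stack: ImageStack, pair: spotfit.SPBPair,
                          config: RunConfig, row: dict):
    """Plaque measurement for unseparated pairs.

    The inner plaques are fitted jointly at the reference cores; their
    fitted model is subtracted and the cytoplasmic foci (old/new outer
    plaque, bridge pool) are then found and fitted iteratively in the
    residual, classified by proximity to the cores versus the bridge
    midpoint.  This needs no knowledge of the (unobserved) plaque-axis
    orientation.
    """
    from scipy import ndimage as _ndi

    opt = config.optics
    sep = config.geometry.ip_op_separation
    tight = (0.7, 1.4)  # PSF is known: keep fitted widths near it
    old, new = pair.fit_old, pair.fit_new
    half_xy = sep + 4.0 * opt.psf_sigma_xy
    half_z = sep + 3.0 * opt.psf_sigma_z
    roi = spotfit.roi_around(stack, [old.center, new.center], half_xy, half_z)
    vxy, vz = stack.voxel_xy, stack.voxel_z
    roi_offset = np.array([roi.x[0] * vxy, roi.y[0] * vxy, roi.z[0] * vz])
    data = stack.channel_pixels(config.channels[1])[roi.slices()].astype(float)
    full_roi = spotfit.Roi(z=(0, data.shape[0]), y=(0, data.shape[1]),
                           x=(0, data.shape[2]))
    mid = 0.5 * (old.center + new.center)
    a_loc, b_loc = old.center - roi_offset, new.center - roi_offset

    def fit_ips(volume):
        tmp = ImageStack(pixels=volume[None], channels=["q"], voxel_xy=vxy,
                         voxel_z=vz)
        return spotfit.fit_double(tmp, 0, full_roi, a_loc, b_loc,
                                  init_sigma_xy=opt.psf_sigma_xy,
                                  init_sigma_z=opt.psf_sigma_z,
                                  sigma_bounds=tight,
                                  center_halfwidth_nm=0.4 * sep)

    fit_ip_old, fit_ip_new = fit_ips(data)

    def model_of(fits):
        out = np.zeros_like(data)
        for f in fits:
            out += spotfit._spot_image(full_roi, vxy, vz, *_spot_params(f))
        return out

    resid = data - model_of([fit_ip_old, fit_ip_new]) - fit_ip_old.background
    floor = linescan.mad_floor(resid.ravel(), 4.0)
    smooth_sig = (opt.psf_sigma_z / vz / 2, opt.psf_sigma_xy / vxy,
                  opt.psf_sigma_xy / vxy)

    cyto: list[tuple[str, spotfit.SpotFit]] = []
    for _ in range(3):
        sm = _ndi.gaussian_filter(resid, smooth_sig)
        iz, iy, ix = np.unravel_index(np.argmax(sm), sm.shape)
        if resid[iz, iy, ix] <= max(floor, 1e-9):
            break
        seed_local = np.array([(ix + 0.5) * vxy, (iy + 0.5) * vxy,
                               (iz + 0.5) * vz])
        tmp = ImageStack(pixels=(resid - resid.min())[None], channels=["r"],
                         voxel_xy=vxy, voxel_z=vz)
        try:
            fit = spotfit.fit_single(tmp, 0, full_roi, seed_local,
                                     init_sigma_xy=opt.psf_sigma_xy,
                                     init_sigma_z=opt.psf_sigma_z,
                                     sigma_bounds=tight)
        except (ValueError, spotfit.DegenerateRoiError):
            break
        if fit.amplitude <= 0:
            break
        center = fit.center + roi_offset
        d_old = np.linalg.norm(center - old.center)
        d_new = np.linalg.norm(center - new.center)
        d_mid = np.linalg.norm(center - mid)
        which = min((d_old, "op_old"), (d_new, "op_new"), (d_mid, "bridge"))[1]
        cyto.append((which, fit))
        resid = resid - spotfit._spot_image(full_roi, vxy, vz,
                                            *_spot_params(fit))

    if cyto:  # decontaminate the inner-plaque fit and re-measure
        fit_ip_old, fit_ip_new = fit_ips(
            data - model_of([f for _, f in cyto]))

    fluxes = {"op_old": 0.0, "op_new": 0.0, "bridge": np.nan}
    for which, fit in cyto:
        if which == "bridge":
            fluxes["bridge"] = (fit.amplitude if math.isnan(fluxes["bridge"])
                                else fluxes["bridge"] + fit.amplitude)
        else:
            fluxes[which] += fit.amplitude

    row["bridge"] = fluxes["bridge"]
    meas_old = metrics.PlaqueMeasurement(fit_ip_old.amplitude,
                                         fluxes["op_old"], "old")
    meas_new = metrics.PlaqueMeasurement(fit_ip_new.amplitude,
                                         fluxes["op_new"], "new")
    return meas_old, meas_new


def _spot_params(fit: spotfit.SpotFit) -> tuple:
    c = fit.center
    return (c[0], c[1], c[2], fit.sigma_xy, fit.sigma_z, fit.amplitude)


def _process_single(stack: ImageStack, seed: np.ndarray, config: RunConfig,
                    row: dict) -> SceneOutcome:
    """Single unduplicated SPB: fit the reference core, then the query
    inner/outer plaque pair (stronger signal = inner plaque)."""
    opt = config.optics
    thr = config.thresholds
    sep = config.geometry.ip_op_separation
    row["stage"] = "unseparated"
    row["inter_distance_um"] = 0.0

    roi = spotfit.roi_around(stack, [seed], sep + 4 * opt.psf_sigma_xy,
                             sep + 3 * opt.psf_sigma_z)
    ref_fit = spotfit.fit_single(stack, config.channels[0], roi, seed,
                                 init_sigma_xy=opt.psf_sigma_xy,
                                 init_sigma_z=opt.psf_sigma_z)
    # edge-slice rule on a self-paired stand-in
    pair = spotfit.SPBPair(fit_old=ref_fit, fit_new=ref_fit)
    pair.inter_distance = 0.0
    if spotfit.edge_slice_exclusion(stack, list(config.channels),
                                    pair).excluded:
        row["excluded"], row["reason"] = True, "edge_slice"
        return SceneOutcome(row=row)

    seeds_q = spotfit.find_seeds(stack, config.channels[1],
                                 smooth_sigma_nm=opt.psf_sigma_xy,
                                 min_distance_nm=2 * opt.voxel_xy,
                                 threshold_rel=0.1, max_peaks=2)
    if len(seeds_q) >= 2:
        init_a, init_b = seeds_q[0], seeds_q[1]
    else:
        # single lateral focus: plaques may be stacked along z (top view)
        base = seeds_q[0] if seeds_q else ref_fit.center
        init_a = base
        init_b = base + np.array([0.0, 0.0, sep])
    qroi = spotfit.default_roi(stack, [init_a, init_b], opt.psf_sigma_xy,
                               opt.psf_sigma_z)
    fa, fb = spotfit.fit_double(stack, config.channels[1], qroi, init_a,
                                init_b, init_sigma_xy=opt.psf_sigma_xy,
                                init_sigma_z=opt.psf_sigma_z)
    inner, outer, _tie = realign.assign_old_new(fa, fb)
    if metrics.is_top_view(inner, outer, opt.psf_sigma_xy,
                           thr.overlap_sigma_factor):
        row["excluded"], row["reason"] = True, "top_view"
        return SceneOutcome(row=row)

    meas = metrics.PlaqueMeasurement(inner.amplitude, outer.amplitude, "old")
    row["ip_old"], row["op_old"] = meas.ip_intensity, meas.op_intensity
    r = metrics.ip_op_ratio(meas)
    row["ratio_old"] = np.nan if r is None else r
    img = realign.realign_stack(stack, inner, outer)
    return SceneOutcome(row=row, realigned=img)


def run(config: RunConfig) -> RunResult:
    """Run the full synthetic pipeline described by ``config``."""
    scenes = synth.sample_population(
        config.stage_mix, config.n, seed=config.seed,
        asymmetry=config.asymmetry, geometry=config.geometry,
        optics=config.optics, noise=config.noise, ploidy=config.ploidy,
        channels=config.channels)

    outcomes: list[SceneOutcome] = []
    for stack, truth in scenes:
        seeds = [stack.to_stack_coords(truth.old_position)]
        if truth.new_position is not None:
            seeds.append(stack.to_stack_coords(truth.new_position))
        outcome = process_scene(stack, seeds, config)
        outcome.row["truth_stage"] = truth.stage_label
        outcome.row["truth_fold"] = (np.inf if math.isinf(truth.old_new_fold)
                                     else truth.old_new_fold)
        outcome.row["truth_top_view"] = truth.top_view
        outcome.row["genotype"] = config.genotype
        outcomes.append(outcome)

    table = pd.DataFrame([o.row for o in outcomes])
    averages = _build_averages(outcomes, table, config)
    report = build_report(table, config)
    return RunResult(table=table, averages=averages, report=report,
                     outcomes=outcomes)


def _build_averages(outcomes, table, config) -> dict[tuple, ClassAverage]:
    groups: dict[tuple, list] = {}
    for o in outcomes:
        if o.realigned is None or o.row["excluded"]:
            continue
        key = (o.row["stage"], config.genotype)
        groups.setdefault(key, []).append(o.realigned)
    out = {}
    for key, imgs in groups.items():
        shapes = {im.pixels.shape for im in imgs}
        for shape in shapes:
            sub = [im for im in imgs if im.pixels.shape == shape]
            k = key if len(shapes) == 1 else key + (shape,)
            out[k] = average_class(sub, class_key=k)
    return out


def build_report(table: pd.DataFrame, config: RunConfig) -> dict:
    """Per-stage counts, exclusion tallies, mode distributions and centile
    summaries of the main quantities."""
    report: dict = {
        "n_scenes": int(len(table)),
        "n_excluded": int(table["excluded"].sum()),
        "exclusions": table.loc[table["excluded"], "reason"]
        .value_counts().to_dict(),
        "stage_counts": table.loc[~table["excluded"], "stage"]
        .value_counts().to_dict(),
        "modes_by_stage": {},
        "summaries": {},
    }
    retained = table[~table["excluded"]]
    for stage, sub in retained.groupby("stage"):
        modes = sub["mode"].dropna()
        if len(modes):
            report["modes_by_stage"][stage] = modes.value_counts().to_dict()
    for col in ("asym_index", "ratio_old", "ratio_new", "inter_distance_um"):
        vals = retained[col].dropna()
        if len(vals):
            report["summaries"][col] = metrics.summarize_distribution(vals)
    return report


def save_run(result: RunResult, out_dir) -> Path:
    """Write the result table, report and class averages under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image_io.write_result_table(result.table, out / "results.csv")
    (out / "report.json").write_text(
        json.dumps(result.report, indent=1, default=str))
    for key, avg in result.averages.items():
        name = "avg_" + "_".join(str(k) for k in key if not isinstance(k, tuple))
        stack = ImageStack(pixels=avg.mean_image, channels=avg.channels,
                           voxel_xy=avg.voxel_xy, voxel_z=avg.voxel_z,
                           source_id=f"{name}_n{avg.n}")
        image_io.write_stack(stack, out / f"{name}.tif")
    return out
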