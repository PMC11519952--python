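"""Force/image servo control laws, sweep planning and the virtual scan.

The scanning state machine mirrors a clinical four-phase workflow:

- **TS** (thyroid search): coarse lateral sweep (or a trained search
  policy) until the segmented gland area exceeds a visibility threshold;
- **BO**: budgeted Bayesian optimization of the probe tilt with image
  entropy as the objective;
- **IPS** (in-plane scan): stride-wise sweep along the lobe axis with
  per-waypoint force servoing and lateral centering, recording suspected
  nodules;
- **OPS** (out-of-plane scan): for each recorded nodule, a 60-degree probe
  rotation followed by a 12 mm sweep along the principal axis; nodules seen
  in both phases are matched by position inside the gland and scored with
  ACR TI-RADS.

Force control is a wrench-compensated proportional law: the sensor wrench
is gravity-compensated and mapped to the probe frame, the contact force is
its component along the probe axis, and the commanded velocity is
``v = -(lambda_f / k) (t_f - t_f*)`` along that axis, with the contact
force held in the 2.0-4.0 N comfort window and a 4.5 N hard stop.  A
spring-contact model (``f = k_tissue * indentation``) closes the loop in
simulation; with matched stiffness the force error contracts exactly by
``(1 - lambda_f * dt)`` per tick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import orient, quality, tirads
from .phantom import TissueMap, VirtualProbe, render_frame
from .quality import GlandNotVisibleError

S_Y = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# wrench algebra
# ---------------------------------------------------------------------------

def rotation_wrench_transform(rotation: np.ndarray, lever_mm: np.ndarray | None = None) -> np.ndarray:
    """6x6 wrench transform for a rotation and optional lever arm.

    Block-diagonal in the rotation; a lever arm adds the usual skew coupling
    from force into torque.
    """
    r = np.asarray(rotation, dtype=float)
    _check_rotation(r)
    t = np.zeros((6, 6))
    t[:3, :3] = r
    t[3:, 3:] = r
    if lever_mm is not None:
        px, py, pz = np.asarray(lever_mm, dtype=float) / 1000.0
        skew = np.array([[0, -pz, py], [pz, 0, -px], [-py, px, 0]])
        t[3:, :3] = skew @ r
    return t


@dataclass
class TransformSet:
    """Transforms of the gravity-compensation chain.

    ``sensor_to_probe`` maps sensor-frame wrenches into the probe frame;
    ``inertial_to_sensor`` maps the probe gravity wrench (expressed in the
    probe's inertial frame) into the sensor frame; ``gravity_wrench`` is
    that gravity wrench.
    """

    sensor_to_probe: np.ndarray = field(default_factory=lambda: np.eye(6))
    inertial_to_sensor: np.ndarray = field(default_factory=lambda: np.eye(6))
    gravity_wrench: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self) -> None:
        for name in ("sensor_to_probe", "inertial_to_sensor"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (6, 6):
                raise ValueError(f"{name} must be 6x6")
            if abs(np.linalg.det(m)) < 1e-12:
                raise ValueError(f"{name} is not invertible")
            _check_rotation(m[:3, :3])
            _check_rotation(m[3:, 3:])
            setattr(self, name, m)
        self.gravity_wrench = np.asarray(self.gravity_wrench, dtype=float).reshape(6)


def _check_rotation(r: np.ndarray) -> None:
    if r.shape != (3, 3) or not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
        raise ValueError("rotation block is not orthonormal")


def compensate_wrench(wrench: np.ndarray, transforms: TransformSet) -> np.ndarray:
    """Probe-frame wrench: ``pH = pF_f (H - fF_g gH_g)``."""
    h = np.asarray(wrench, dtype=float).reshape(6)
    return transforms.sensor_to_probe @ (
        h - transforms.inertial_to_sensor @ transforms.gravity_wrench
    )


def contact_force(probe_wrench: np.ndarray) -> float:
    """Contact force ``t_f = S_y . pH``: the probe-axis force component."""
    h = np.asarray(probe_wrench, dtype=float)
    if h.shape != (6,):
        raise ValueError("expected a 6-vector wrench")
    return float(S_Y @ h)


@dataclass
class ForceControlParams:
    """Proportional force-servo parameters.

    ``stiffness_n_m`` is the assumed tissue stiffness (125-500 N/m for the
    neck); ``desired_force_n`` defaults to 3.0 N, the midpoint of the
    2.0-4.0 N comfort window; above ``hard_stop_n`` the scan aborts.
    """

    gain_per_s: float = 5.0
    stiffness_n_m: float = 300.0
    desired_force_n: float = 3.0
    force_window_n: tuple[float, float] = (2.0, 4.0)
    hard_stop_n: float = 4.5
    selection: np.ndarray = field(default_factory=lambda: S_Y.copy())

    def __post_init__(self) -> None:
        if not 125.0 <= self.stiffness_n_m <= 500.0:
            raise ValueError("stiffness outside the 125-500 N/m tissue range")
        lo, hi = self.force_window_n
        if not lo <= self.desired_force_n <= hi:
            raise ValueError("desired force outside the comfort window")
        if self.gain_per_s <= 0:
            raise ValueError("gain must be positive")


def force_velocity(
    wrench: np.ndarray, transforms: TransformSet, params: ForceControlParams
) -> np.ndarray:
    """Commanded 6-velocity (mm/s) along the probe axis.

    ``v = -(lambda_f / k)(S_y pF_f (H - fF_g gH_g) - t_f*) S_y^T``; zero when
    the measured force equals the setpoint.  Positive probe-axis direction
    is pressing into tissue, so excess force commands retraction.
    """
    if params.stiffness_n_m <= 0:
        raise ValueError("stiffness must be positive")
    tf = contact_force(compensate_wrench(wrench, transforms))
    v_m_s = -(params.gain_per_s / params.stiffness_n_m) * (tf - params.desired_force_n)
    return v_m_s * 1000.0 * params.selection


def simulate_spring_contact(
    params: ForceControlParams,
    tissue_stiffness_n_m: float,
    initial_force_n: float,
    n_steps: int,
    dt_s: float = 0.1,
) -> np.ndarray:
    """Closed-loop force trajectory against a linear spring contact.

    The plant is ``f = k_tissue * indentation``; each step integrates the
    commanded velocity with explicit Euler.  Returns the force after each of
    ``n_steps`` ticks (length ``n_steps + 1`` including the start).
    """
    transforms = TransformSet()
    indentation_m = initial_force_n / tissue_stiffness_n_m
    forces = [initial_force_n]
    for _ in range(n_steps):
        f = tissue_stiffness_n_m * indentation_m
        wrench = f * S_Y
        v_mm_s = float(S_Y @ force_velocity(wrench, transforms, params))
        indentation_m += (v_mm_s / 1000.0) * dt_s
        forces.append(tissue_stiffness_n_m * indentation_m)
    return np.array(forces)


# ---------------------------------------------------------------------------
# sideway correction
# ---------------------------------------------------------------------------

def rotation_step(theta_step_deg: float) -> np.ndarray:
    """X-axis rotation matrix of the iterative sideway correction."""
    th = np.radians(theta_step_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def sideway_step(r_prev: np.ndarray, theta_step_deg: float) -> np.ndarray:
    """One sideway-correction update: ``R_n = R_step . R_{n-1}``."""
    r = np.asarray(r_prev, dtype=float)
    _check_rotation(r)
    return rotation_step(theta_step_deg) @ r


# ---------------------------------------------------------------------------
# morphometry and sweep planning
# ---------------------------------------------------------------------------

@dataclass
class MorphometryStats:
    """CT-derived gland morphometry (cm) used to size the scan area."""

    height_mean_cm: float = 4.76
    height_sd_cm: float = 0.57
    width_mean_cm: float = 1.48
    thickness_mean_cm: float = 1.52
    probe_width_cm: float = 4.0

    def __post_init__(self) -> None:
        if min(
            self.height_mean_cm,
            self.height_sd_cm,
            self.width_mean_cm,
            self.thickness_mean_cm,
            self.probe_width_cm,
        ) < 0:
            raise ValueError("morphometry values must be non-negative")


def scan_range(stats: MorphometryStats | None = None) -> tuple[float, float]:
    """Rectangular scan area (length, width) in cm.

    Length covers the gland height under the 3-sigma rule (mean + 3 sd);
    width is the probe footprint plus the mean unilateral gland width.
    """
    s = stats or MorphometryStats()
    length = s.height_mean_cm + 3.0 * s.height_sd_cm
    width = s.probe_width_cm + s.width_mean_cm
    return float(length), float(width)


@dataclass
class SweepPlan:
    """Waypoint sequence of one scan phase."""

    waypoints_mm: list[float]
    speed_mm_s: float = 5.0
    stride_mm: float = 2.0
    phase: str = "IPS"
    rotation_deg: float = 0.0
    nodule_center_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.speed_mm_s <= 0:
            raise ValueError("speed must be positive")
        if self.phase not in ("TS", "IPS", "OPS", "MVS"):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def span_mm(self) -> float:
        if not self.waypoints_mm:
            return 0.0
        return max(self.waypoints_mm) - min(self.waypoints_mm)


class GlandNeverVisibleError(RuntimeError):
    """IPS feedback never showed the gland: the search phase must re-run."""


def plan_ips(
    feedback,
    stride_mm: float = 2.0,
    visibility_threshold: float = 0.01,
    z0_mm: float = 0.0,
    z_limits_mm: tuple[float, float] = (0.0, 64.0),
    centering_gain: float = 0.8,
    half_width_mm: float = 20.0,
) -> tuple[SweepPlan, list[float]]:
    """In-plane sweep plan driven by segmentation feedback.

    ``feedback(z_mm)`` must return a mapping with ``area_fraction`` (gland
    area / frame area) and ``centering_error`` (signed fraction of
    half-width, or None).  The plan advances superior from ``z0_mm`` until
    the gland drops below the visibility threshold, then reverses and covers
    the inferior side.  Each waypoint emits a lateral correction (mm) that
    drives the centering error toward zero.
    """
    lo, hi = z_limits_mm
    plan: list[float] = []
    corrections: list[float] = []
    seen = False

    def visit(z: float) -> bool:
        nonlocal seen
        fb = feedback(z)
        plan.append(z)
        err = fb.get("centering_error")
        corrections.append(0.0 if err is None else err * half_width_mm * centering_gain)
        visible = fb["area_fraction"] >= visibility_threshold
        seen = seen or visible
        return visible

    z = z0_mm
    while z <= hi:
        if not visit(z):
            break
        z += stride_mm
    superior_end = z
    z = z0_mm - stride_mm
    while z >= lo:
        if not visit(z):
            break
        z -= stride_mm
    if not seen:
        raise GlandNeverVisibleError(
            "gland never visible during IPS; re-enter the search phase"
        )
    return (
        SweepPlan(waypoints_mm=plan, stride_mm=stride_mm, phase="IPS"),
        corrections,
    )


def plan_ops(
    nodule_centers_mm,
    rotation_deg: float = 60.0,
    span_mm: float = 12.0,
    stride_mm: float = 2.0,
) -> list[SweepPlan]:
    """Out-of-plane re-scan plans: one per recorded nodule, in order.

    Each plan starts with the probe rotation and covers exactly ``span_mm``
    along the principal axis, centred on the nodule.  An empty nodule list
    yields an empty plan list.
    """
    plans = []
    for center in nodule_centers_mm:
        cz = center[0] if np.ndim(center) else float(center)
        n_steps = int(round(span_mm / stride_mm))
        waypoints = [cz - span_mm / 2 + i * stride_mm for i in range(n_steps + 1)]
        plans.append(
            SweepPlan(
                waypoints_mm=waypoints,
                stride_mm=stride_mm,
                phase="OPS",
                rotation_deg=rotation_deg,
                nodule_center_mm=tuple(np.atleast_1d(center).tolist())
                if np.ndim(center)
                else (cz,),
            )
        )
    return plans


# ---------------------------------------------------------------------------
# motion guard
# ---------------------------------------------------------------------------

@dataclass
class MotionGuardThresholds:
    lateral_mm: float = 20.0     # 2 cm left/right
    window_s: float = 1.0        # within 1 s
    anterior_posterior_mm: float = 50.0  # 5 cm forward/backward


def motion_guard(
    pose_history, thresholds: MotionGuardThresholds | None = None
) -> tuple[bool, str]:
    """Patient-motion safety check over a time-stamped pose history.

    ``pose_history`` is a sequence of ``(t_s, lateral_mm, ap_mm)``.  Returns
    ``(True, "continue")`` or ``(False, reason)``; terminate when lateral
    displacement exceeds the limit within any window, or the total
    anterior-posterior excursion exceeds its limit.
    """
    th = thresholds or MotionGuardThresholds()
    hist = [(float(t), float(x), float(y)) for t, x, y in pose_history]
    times = [t for t, _, _ in hist]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("pose history timestamps must be non-decreasing")
    for i in range(len(hist)):
        for j in range(i + 1, len(hist)):
            if hist[j][0] - hist[i][0] > th.window_s:
                break
            if abs(hist[j][1] - hist[i][1]) > th.lateral_mm:
                return False, "lateral motion exceeded"
    if hist:
        ys = [y for _, _, y in hist]
        if max(ys) - min(ys) > th.anterior_posterior_mm:
            return False, "anterior-posterior motion exceeded"
    return True, "continue"


# ---------------------------------------------------------------------------
# end-to-end virtual scan
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    tick_s: float = 0.1                  # 10 Hz command rate
    force: ForceControlParams = field(default_factory=ForceControlParams)
    tissue_stiffness_n_m: float = 300.0
    visibility_threshold: float = 0.01   # gland area fraction ending the search
    stride_mm: float = 2.0
    settle_ticks: int = 2
    centering_gain: float = 0.8
    ts_stride_mm: float = 4.0
    ts_max_ticks: int = 60
    initial_lateral_offset_mm: float = -8.0
    initial_tilt_deg: float = 4.0
    bo_budget: int = 5
    bo_bounds_deg: tuple[float, float] = (-10.0, 10.0)
    ops_rotation_deg: float = 60.0
    ops_span_mm: float = 12.0
    match_max_fraction: float = 0.5      # of nodule width, for cross-view matching
    confidence_shape: tuple[int, int] = (24, 24)
    patient_drift_mm_s: float = 0.0
    guard: MotionGuardThresholds = field(default_factory=MotionGuardThresholds)


@dataclass
class ScanRecord:
    """Complete log of one virtual scan: one row per control tick."""

    ticks: list[dict]
    events: list[dict]
    nodules: list[dict]
    ops_plans: list[SweepPlan]
    bo_trace: orient.BOTrace | None
    seed: int
    completed: bool


def run_virtual_scan(
    tissue: TissueMap, config: ScanConfig | None = None, seed: int = 0
) -> ScanRecord:
    """Execute the TS -> BO -> IPS -> OPS -> scoring state machine.

    All randomness (speckle seeds, BO initial design, patient drift) derives
    from ``seed``; the returned record is reproducible.
    """
    cfg = config or ScanConfig()
    rng = np.random.default_rng(seed)
    s = tissue.spacing_mm
    nz, ny, nx = tissue.shape
    gland = tissue.gland_mask()
    gz, gy, gx = [c.mean() * s for c in np.nonzero(gland)]

    probe = VirtualProbe(
        lateral_mm=gx + cfg.initial_lateral_offset_mm,
        elevation_mm=gz,
        tilt_in_deg=cfg.initial_tilt_deg,
        force_n=0.0,
    )
    indentation_m = 0.0
    transforms = TransformSet()
    ticks: list[dict] = []
    events: list[dict] = []
    patient_history: list[tuple[float, float, float]] = []
    patient_x = 0.0
    completed = True

    def servo_force() -> float:
        nonlocal indentation_m
        f = cfg.tissue_stiffness_n_m * indentation_m
        v_mm_s = float(S_Y @ force_velocity(f * S_Y, transforms, cfg.force))
        indentation_m += (v_mm_s / 1000.0) * cfg.tick_s
        return cfg.tissue_stiffness_n_m * indentation_m

    def tick(phase: str) -> dict | None:
        """Advance one control tick: force servo, render, log, safety."""
        nonlocal patient_x, completed
        force = servo_force()
        probe.force_n = max(force, 0.0)
        if force > cfg.force.hard_stop_n:
            events.append({"t": len(ticks) * cfg.tick_s, "event": "hard_stop",
                           "force_n": force})
            completed = False
            return None
        frame = render_frame(tissue, probe, seed=int(rng.integers(2**31)))
        try:
            cen = quality.centering_error(frame.gland_mask)
        except GlandNotVisibleError:
            cen = None
        rep = quality.report(
            frame.image,
            frame.gland_mask,
            confidence_shape=cfg.confidence_shape,
        )
        if cfg.patient_drift_mm_s:
            patient_x += rng.normal(0, cfg.patient_drift_mm_s * cfg.tick_s)
        t = len(ticks) * cfg.tick_s
        patient_history.append((t, patient_x, 0.0))
        ok, reason = motion_guard(patient_history[-30:], cfg.guard)
        if not ok:
            events.append({"t": t, "event": "motion_guard", "reason": reason})
            completed = False
            return None
        row = {
            "t_s": t,
            "phase": phase,
            "force_n": force,
            "lateral_mm": probe.lateral_mm,
            "elevation_mm": probe.elevation_mm,
            "tilt_deg": probe.tilt_in_deg,
            "entropy_bits": rep.entropy_bits,
            "mean_confidence": rep.mean_confidence,
            "centering_error": cen,
            "gland_area_fraction": float(frame.gland_mask.mean()),
        }
        ticks.append(row)
        return {"frame": frame, "row": row}

    # ---- TS: lateral raster until the gland is sufficiently visible ----
    direction = 1.0
    found = False
    for _ in range(cfg.ts_max_ticks):
        out = tick("TS")
        if out is None:
            return ScanRecord(ticks, events, [], [], None, seed, completed)
        if out["row"]["gland_area_fraction"] >= cfg.visibility_threshold:
            found = True
            break
        probe.lateral_mm += direction * cfg.ts_stride_mm
        if probe.lateral_mm > nx * s or probe.lateral_mm < 0:
            direction *= -1
            probe.lateral_mm += 2 * direction * cfg.ts_stride_mm
    if not found:
        events.append({"t": len(ticks) * cfg.tick_s, "event": "search_failed"})
        return ScanRecord(ticks, events, [], [], None, seed, False)
    events.append({"t": len(ticks) * cfg.tick_s, "event": "search_done"})

    # ---- BO: tilt optimization with entropy objective ----
    bo_render_seed = int(rng.integers(2**31))

    def entropy_objective(tilt_deg: float) -> float:
        probe.tilt_in_deg = float(tilt_deg)
        out = tick("BO")
        if out is None:
            raise RuntimeError("scan aborted during orientation optimization")
        return out["row"]["entropy_bits"]

    bo_cfg = orient.BOConfig(budget=cfg.bo_budget, seed=int(rng.integers(2**31)))
    trace = orient.optimize_orientation(
        entropy_objective, bounds=[cfg.bo_bounds_deg], config=bo_cfg
    )
    probe.tilt_in_deg = float(np.atleast_1d(trace.best_x)[0])
    events.append({"t": len(ticks) * cfg.tick_s, "event": "bo_done",
                   "best_tilt_deg": probe.tilt_in_deg, "best_entropy": trace.best_y})

    # ---- IPS: sweep the lobe axis, centering the gland at each waypoint ----
    detections: dict[int, dict] = {}

    def observe_and_center(phase: str) -> bool:
        for _ in range(cfg.settle_ticks):
            out = tick(phase)
            if out is None:
                return False
            frame = out["frame"]
            err = out["row"]["centering_error"]
            if err is not None:
                probe.lateral_mm += err * (probe.footprint_mm / 2) * cfg.centering_gain
            for nid, mask in frame.nodule_masks.items():
                if not mask.any():
                    continue
                ys, xs_ = np.nonzero(mask)
                x0 = frame.pose.lateral_mm - frame.pose.footprint_mm / 2
                center = (
                    frame.pose.elevation_mm,
                    float(ys.mean() * s),
                    float(x0 + xs_.mean() * s),
                )
                per_phase = detections.setdefault(nid, {}).setdefault(
                    phase, {"area_px": 0}
                )
                if mask.sum() > per_phase["area_px"]:
                    per_phase["area_px"] = int(mask.sum())
                    per_phase["center_mm"] = center
                    per_phase["best_frame"] = frame
                    per_phase["best_mask"] = mask
        return True

    z0 = probe.elevation_mm
    for dz_dir in (+1.0, -1.0):
        probe.elevation_mm = z0 if dz_dir > 0 else z0 - cfg.stride_mm
        while 0 <= probe.elevation_mm <= nz * s:
            if not observe_and_center("IPS"):
                return ScanRecord(ticks, events, [], [], trace, seed, completed)
            if ticks[-1]["gland_area_fraction"] < cfg.visibility_threshold:
                break
            probe.elevation_mm += dz_dir * cfg.stride_mm
    probe.elevation_mm = z0
    events.append({"t": len(ticks) * cfg.tick_s, "event": "ips_done",
                   "n_suspected": len(detections)})

    # ---- OPS: re-scan each recorded nodule from the rotated view ----
    ips_ids = [nid for nid, d in detections.items() if "IPS" in d]
    ops_plans = plan_ops(
        [detections[nid]["IPS"]["center_mm"] for nid in ips_ids],
        rotation_deg=cfg.ops_rotation_deg,
        span_mm=cfg.ops_span_mm,
        stride_mm=cfg.stride_mm,
    )
    if not ops_plans:
        events.append({"t": len(ticks) * cfg.tick_s, "event": "ops_skipped"})
    for plan in ops_plans:
        events.append({"t": len(ticks) * cfg.tick_s, "event": "ops_rotation",
                       "rotation_deg": plan.rotation_deg})
        for z in plan.waypoints_mm:
            probe.elevation_mm = float(np.clip(z, 0, nz * s))
            if not observe_and_center("OPS"):
                return ScanRecord(ticks, events, [], ops_plans, trace, seed, completed)

    events.append(
        {
            "t": len(ticks) * cfg.tick_s,
            "event": "detections",
            "per_nodule": {
                str(nid): {
                    ph: {"center_mm": v.get("center_mm"), "area_px": v["area_px"]}
                    for ph, v in d.items()
                }
                for nid, d in detections.items()
            },
        }
    )

    # ---- cross-view matching and TI-RADS scoring ----
    # A nodule counts as confirmed when its IPS and OPS centroid estimates
    # agree to within half the nodule width inside the gland.
    nodules: list[dict] = []
    for nid in ips_ids:
        d = detections[nid]
        if "OPS" not in d:
            continue
        ips_det, ops_det = d["IPS"], d["OPS"]
        width_px = max(
            np.ptp(np.nonzero(ips_det["best_mask"])[1]) + 1, 1
        )
        width_mm = width_px * s
        offset = float(
            np.linalg.norm(
                np.array(ips_det["center_mm"]) - np.array(ops_det["center_mm"])
            )
        )
        if offset > cfg.match_max_fraction * width_mm:
            continue
        frame = ips_det["best_frame"]
        score = tirads.score_nodule(
            frame.image, frame.gland_mask, ips_det["best_mask"], spacing_mm=s
        )
        nodules.append(
            {
                "nodule_id": nid,
                "center_mm": ips_det["center_mm"],
                "cross_view_offset_mm": offset,
                "matched": True,
                "score": score.as_dict(),
            }
        )
    events.append({"t": len(ticks) * cfg.tick_s, "event": "scan_done",
                   "n_matched": len(nodules)})
    return ScanRecord(ticks, events, nodules, ops_plans, trace, seed, completed)
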