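"""Seeded synthetic cardiac/coronary phantoms.

Each case contains: LA and LV chamber surfaces as jittered ellipsoid
point clouds, a right-dominant coronary tree as smooth parametric
centerlines with ground-truth branch identities and 16-segment labels,
and (on demand) a binary tube-rasterized volume emulating a lumen
segmentation. The geometry is parametric-idealized, not fitted to
population data; it is built so the anatomical premise of the circumflex
rule holds by construction — the LCx runs in the left atrioventricular
groove between the LA and LV, so its centerline is closer to the LA than
the LAD's is — and every generated case verifies that premise.

Coordinates follow the package frame: x toward patient left, y toward
anterior, z toward inferior, in millimetres. Cases are deterministic in
(seed, params).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import Centerline, PointCloud, arc_length, distance_profile
from .labeler import (
    LabeledFragment,
    LabeledTree,
    LabelerConfig,
    split_into_fragments,
    subdivide_main_vessel,
)
from .skeleton import BinaryVolume

__all__ = ["PhantomParams", "PhantomCase", "generate_case", "rasterize", "perturb", "ground_truth_tree"]

#: branch identities a phantom can contain (main vessels + side branches)
BRANCH_NAMES = ("LM", "LAD", "LCX", "RCA", "D1", "D2", "OM1", "OM2", "RI", "R-PDA", "R-PLB")


@dataclass
class PhantomParams:
    """Generator knobs with anatomically plausible defaults.

    Branch prevalences approximate a right-dominant adult population:
    main vessels always present, two diagonals/marginals in most cases,
    a ramus intermedius in roughly a third. ``control_jitter_mm`` moves
    the spline control points of each branch; ``cloud_jitter_mm`` is the
    per-point noise of the chamber surface samples. Defaults keep branch
    separations comfortably above twice the rasterization radius.
    """

    cloud_points_la: int = 300
    cloud_points_lv: int = 500
    cloud_jitter_mm: float = 0.8
    control_jitter_mm: float = 1.5
    translation_jitter_mm: float = 3.0
    sample_spacing_mm: float = 1.0
    diag_count_probs: tuple = (0.05, 0.25, 0.70)  # P(0), P(1), P(2) diagonals
    marg_count_probs: tuple = (0.05, 0.30, 0.65)  # marginals
    ri_prob: float = 0.35
    pda_plb_prob: float = 0.90  # both distal RCA branches present, else neither
    tube_radius_mm: float = 1.25
    grid_spacing_mm: float = 0.625  # isotropic voxel pitch of the rasterized mask

    def __post_init__(self):
        for p in (self.ri_prob, self.pda_plb_prob):
            if not 0 <= p <= 1:
                raise ValueError("branch probabilities must lie in [0, 1]")
        for probs in (self.diag_count_probs, self.marg_count_probs):
            if abs(sum(probs) - 1) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError("count probabilities must be a distribution")
        if self.cloud_jitter_mm < 0 or self.control_jitter_mm < 0:
            raise ValueError("jitter magnitudes must be non-negative")
        if self.sample_spacing_mm <= 0 or self.sample_spacing_mm > 1.0:
            raise ValueError("centerline sample spacing must be in (0, 1] mm")


@dataclass
class PhantomCase:
    """One synthetic heart: chamber clouds, labeled branches, ostia."""

    la_cloud: PointCloud
    lv_cloud: PointCloud
    branches: dict  # name -> Centerline
    ostia: dict  # {"left": Point3, "right": Point3}
    seed: int
    params: PhantomParams
    descriptor: dict = field(default_factory=dict)  # presence flags etc.

    def branch_names(self) -> set:
        return set(self.branches)


# ---------------------------------------------------------------------------
# base geometry (before jitter), world mm
# ---------------------------------------------------------------------------

_LV_CENTER = np.array([48.0, 42.0, 72.0])
_LV_SEMI = np.array([30.0, 27.0, 40.0])
_LA_CENTER = np.array([44.0, 16.0, 32.0])
_LA_SEMI = np.array([20.0, 14.0, 16.0])

_CONTROL = {
    "LM": [(38, 34, 22), (43, 37, 26), (48, 40, 30)],
    "LAD": [(48, 40, 30), (52, 58, 38), (56, 66, 52), (58, 68, 70), (54, 62, 92), (50, 52, 108)],
    "LCX": [(48, 40, 30), (60, 36, 38), (70, 28, 46), (72, 16, 52), (62, 6, 58), (50, 2, 64)],
    "D1": [(54, 62, 46), (67, 64, 57), (75, 62, 68)],
    "D2": [(58, 68, 62), (68, 66, 78), (72, 60, 92)],
    "OM1": [(70, 28, 46), (76, 24, 64), (74, 16, 82)],
    "OM2": [(72, 14, 53), (74, 6, 70), (68, 0, 86)],
    "RI": [(48, 40, 30), (58, 48, 44), (64, 52, 62)],
    "RCA": [(28, 30, 20), (16, 24, 30), (8, 16, 44), (8, 8, 60), (16, 4, 72), (28, 4, 80)],
    "R-PDA": [(28, 4, 80), (36, 8, 94), (42, 16, 106)],
    "R-PLB": [(28, 4, 80), (38, 2, 84), (50, 4, 88)],
}
# side branches attach at a control point of their parent; record which one
_ATTACH = {
    "LAD": ("LM", -1), "LCX": ("LM", -1), "RI": ("LM", -1),
    "D1": ("LAD", 2), "D2": ("LAD", 3),
    "OM1": ("LCX", 2), "OM2": ("LCX", 3),
    "R-PDA": ("RCA", -1), "R-PLB": ("RCA", -1),
}


def _sample_spline(controls: np.ndarray, spacing: float) -> Centerline:
    """Smooth polyline through control points at ~uniform arc spacing."""
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(controls, axis=0), axis=1))])
    cs = CubicSpline(t, controls, axis=0)
    dense = cs(np.linspace(0, t[-1], max(int(t[-1] * 10), 8)))
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    n = max(int(np.ceil(arc[-1] / spacing)) + 1, 3)
    targets = np.linspace(0, arc[-1], n)
    pts = np.column_stack([np.interp(targets, arc, dense[:, k]) for k in range(3)])
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
    return Centerline(pts[keep])


def _ellipsoid_cloud(rng, center, semi, n, jitter) -> np.ndarray:
    """Roughly uniform surface samples of an ellipsoid, with radial jitter."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = center + v * semi
    pts += rng.normal(scale=jitter, size=pts.shape) if jitter > 0 else 0.0
    return pts


def _attachment_adjusted(name, controls, jittered):
    """Pin a side branch's first control to its (jittered) parent position."""
    parent, idx = _ATTACH[name]
    out = controls.copy()
    out[0] = jittered[parent][idx]
    return out


def generate_case(seed: int, params: PhantomParams | None = None) -> PhantomCase:
    """Generate one deterministic synthetic case from a seed."""
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)

    # global translation + per-control-point jitter, fixed draw order
    shift = rng.uniform(-params.translation_jitter_mm, params.translation_jitter_mm, 3)
    jittered: dict[str, np.ndarray] = {}
    order = ["LM", "LAD", "LCX", "RCA", "D1", "D2", "OM1", "OM2", "RI", "R-PDA", "R-PLB"]
    for name in order:
        c = np.asarray(_CONTROL[name], dtype=float) + shift
        j = rng.normal(scale=params.control_jitter_mm, size=c.shape)
        j[0] = 0.0  # keep attachment/ostium points exact
        jittered[name] = c + j
    for name in order:
        if name in _ATTACH:
            jittered[name] = _attachment_adjusted(name, jittered[name], jittered)

    # branch presence (draw order fixed regardless of outcome)
    n_diag = int(rng.choice(3, p=params.diag_count_probs))
    n_marg = int(rng.choice(3, p=params.marg_count_probs))
    has_ri = bool(rng.random() < params.ri_prob)
    has_distal_rca = bool(rng.random() < params.pda_plb_prob)

    present = {"LM", "LAD", "LCX", "RCA"}
    present |= {f"D{i}" for i in range(1, n_diag + 1)}
    present |= {f"OM{i}" for i in range(1, n_marg + 1)}
    if has_ri:
        present.add("RI")
    if has_distal_rca:
        present |= {"R-PDA", "R-PLB"}

    branches = {
        name: _sample_spline(jittered[name], params.sample_spacing_mm)
        for name in order
        if name in present
    }

    la = PointCloud(
        _ellipsoid_cloud(rng, _LA_CENTER + shift, _LA_SEMI, params.cloud_points_la, params.cloud_jitter_mm),
        role="LA",
    )
    lv = PointCloud(
        _ellipsoid_cloud(rng, _LV_CENTER + shift, _LV_SEMI, params.cloud_points_lv, params.cloud_jitter_mm),
        role="LV",
    )

    case = PhantomCase(
        la_cloud=la,
        lv_cloud=lv,
        branches=branches,
        ostia={"left": branches["LM"].points[0].copy(), "right": branches["RCA"].points[0].copy()},
        seed=int(seed),
        params=params,
        descriptor={
            "dominance": "right",
            "n_diagonals": n_diag,
            "n_marginals": n_marg,
            "ri": has_ri,
            "distal_rca": has_distal_rca,
        },
    )
    _check_premise(case)
    return case


def _check_premise(case: PhantomCase):
    """Verify (not assume) the groove premise: LCx closer to the LA than LAD."""
    la, lv = case.la_cloud, case.lv_cloud
    d_lcx = distance_profile(case.branches["LCX"], la, lv).d_min_la.mean()
    d_lad = distance_profile(case.branches["LAD"], la, lv).d_min_la.mean()
    if not d_lcx < d_lad:
        raise RuntimeError(
            f"phantom violates the AV-groove premise (seed {case.seed}): "
            f"mean DminLA LCx {d_lcx:.1f} >= LAD {d_lad:.1f}"
        )


# ---------------------------------------------------------------------------
# ground truth labels
# ---------------------------------------------------------------------------

def ground_truth_tree(case: PhantomCase, cfg: LabelerConfig | None = None) -> LabeledTree:
    """The case's 16-segment ground truth under the labeler's conventions.

    Main vessels are subdivided into equal arc-length thirds; the
    circumflex splits into pCx (ending at the OM1 origin when OM1 exists,
    else at the first third) and LCx. Built directly from the generating
    branch geometry, independent of any graph extraction or selection
    rule.
    """
    cfg = cfg or LabelerConfig()
    b = case.branches
    frags: list = []

    lm = b["LM"]
    frags.append(LabeledFragment("LM", "LM", lm.points, 0.0, arc_length(lm)))
    frags += subdivide_main_vessel(b["LAD"], ["pLAD", "mLAD", "dLAD"], cfg.subdivision_fractions, "LAD")

    cx = b["LCX"]
    if "OM1" in b:
        om1_origin = b["OM1"].points[0]
        d = np.linalg.norm(cx.points - om1_origin, axis=1)
        pcx_end = float(cx.cumulative_lengths()[int(np.argmin(d))])
    else:
        pcx_end = arc_length(cx) * cfg.subdivision_fractions[0]
    frags += split_into_fragments(cx, [pcx_end], ["pCx", "LCx"], "LCx path")

    if "R-PDA" in b or "R-PLB" in b:
        trunk = b["RCA"]
    else:
        trunk = b["RCA"]
    frags += subdivide_main_vessel(trunk, ["pRCA", "mRCA", "dRCA"], cfg.subdivision_fractions, "RCA")

    for name in ("D1", "D2", "OM1", "OM2", "RI", "R-PDA", "R-PLB"):
        if name in b:
            line = b[name]
            frags.append(
                LabeledFragment(name, name, line.points[1:], 0.0, arc_length(line))
            )
    return LabeledTree(frags, {"source": "phantom ground truth", "seed": case.seed}, [])


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize(case: PhantomCase, radius: float | None = None, spacing: float | None = None) -> BinaryVolume:
    """Tube-rasterize all branches into a binary volume.

    A voxel is foreground iff its centre lies within ``radius`` of any
    branch centerline (curves are densely resampled at a quarter of the
    voxel pitch, so the discretization error is below spacing/8). Tube
    ends are therefore hemispherically capped, which keeps thinning free
    of end-face artifacts.
    """
    params = case.params
    radius = params.tube_radius_mm if radius is None else float(radius)
    spacing = params.grid_spacing_mm if spacing is None else float(spacing)
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if radius < spacing:
        raise ValueError("tube radius must be at least one voxel")

    all_pts = np.vstack([c.points for c in case.branches.values()])
    margin = radius + 2.0
    lo = all_pts.min(axis=0) - margin
    hi = all_pts.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    vol = np.zeros(shape, dtype=bool)

    # sphere stamp: offsets whose centre distance is within radius
    r_vox = int(np.ceil(radius / spacing))
    ax = np.arange(-r_vox, r_vox + 1)
    oi, oj, ok = np.meshgrid(ax, ax, ax, indexing="ij")
    stamp = np.stack([oi, oj, ok], axis=-1).reshape(-1, 3)
    stamp = stamp[np.linalg.norm(stamp * spacing, axis=1) <= radius]

    dense_step = spacing / 4.0
    for line in case.branches.values():
        pts = _densify(line.points, dense_step)
        centers = np.round((pts - lo) / spacing).astype(int)
        centers = np.unique(centers, axis=0)
        for c in centers:
            idx = c + stamp
            ok_mask = np.all((idx >= 0) & (idx < shape), axis=1)
            idx = idx[ok_mask]
            vol[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return BinaryVolume(vol, np.full(3, spacing), lo, meta={"phantom_seed": case.seed})


def _densify(pts: np.ndarray, step: float) -> np.ndarray:
    segs = []
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
        t = np.linspace(0, 1, n, endpoint=False)[:, None]
        segs.append(a + t * (b - a))
    segs.append(pts[-1:])
    return np.vstack(segs)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def perturb(case: PhantomCase, ops: list) -> PhantomCase:
    """Apply failure-mode perturbations; ground truth stays consistent.

    ``ops`` is a list of dicts:
    ``{"drop": name}`` removes a branch (and, for OM1/D1, renames nothing —
    absence simply propagates); ``{"truncate": name, "fraction": f}`` keeps
    the proximal fraction of a branch; ``{"jitter": sigma, "seed": s}``
    adds Gaussian noise to every branch point.
    """
    branches = {k: Centerline(v.points.copy()) for k, v in case.branches.items()}
    descriptor = dict(case.descriptor)
    for op in ops:
        if "drop" in op:
            name = op["drop"]
            if name not in BRANCH_NAMES:
                raise ValueError(f"unknown branch {name!r}")
            branches.pop(name, None)
            descriptor[f"dropped_{name}"] = True
        elif "truncate" in op:
            name = op["truncate"]
            if name not in branches:
                raise ValueError(f"unknown or absent branch {name!r}")
            frac = float(op["fraction"])
            if not 0 < frac <= 1:
                raise ValueError("truncation fraction must be in (0, 1]")
            line = branches[name]
            cum = line.cumulative_lengths()
            keep = cum <= cum[-1] * frac
            keep[: 2] = True
            branches[name] = Centerline(line.points[keep])
            descriptor[f"truncated_{name}"] = frac
        elif "jitter" in op:
            rng = np.random.default_rng(op.get("seed", case.seed + 1))
            sigma = float(op["jitter"])
            for k in branches:
                branches[k] = Centerline(branches[k].points + rng.normal(scale=sigma, size=branches[k].points.shape))
        else:
            raise ValueError(f"unknown perturbation {op!r}")
    return replace(case, branches=branches, descriptor=descriptor)
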