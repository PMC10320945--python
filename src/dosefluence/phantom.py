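"""Synthetic nasopharyngeal-like digital phantoms and a desk-scale dose engine.

Each generated case mimics the data layout of a clinical nine-beam
head-and-neck IMRT plan: a CT volume (HU) on an isocenter-centered 2.5 mm
grid, five planning target volumes (nested GTV/PTV-1/PTV-2 plus two lateral
nodal targets) encoded as a prescription-dose mask, seventeen organ-at-risk
masks, a reference fluence stack obtained by projected-gradient plan
optimization, and the corresponding dose volume.

The forward dose engine is deliberately simple — per-beamlet inverse-square
weighting, exponential attenuation along the radiological depth, and an
optional Gaussian penumbra blur.  It creates a physically plausible,
learnable anatomy->dose/fluence mapping; fidelity to a clinical
convolution/superposition algorithm is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy import ndimage

from .geometry import (
    DEFAULT_ANGLES,
    BeamGeometry,
    GridSpec,
    ProjectionOperator,
    bev_target_mask,
    build_all_operators,
    gantry_source_position,
)

__all__ = [
    "OAR_NAMES",
    "PTV_NAMES",
    "PRESCRIPTION_COMBOS",
    "NODAL_LEVELS",
    "PhantomConfig",
    "PatientCase",
    "DoseEngine",
    "hu_to_density",
    "generate_anatomy",
    "forward_dose",
    "optimize_reference_fluence",
    "generate_case",
    "sample_prescriptions",
]

OAR_NAMES = (
    "body",
    "brainstem",
    "spinal_cord",
    "chiasm",
    "tongue",
    "optic_nerve_l",
    "optic_nerve_r",
    "lens_l",
    "lens_r",
    "temporal_lobe_l",
    "temporal_lobe_r",
    "mandible_l",
    "mandible_r",
    "tmj_l",
    "tmj_r",
    "parotid_l",
    "parotid_r",
)

PTV_NAMES = ("ptv_gtv", "ptv_1", "ptv_2", "ptv_ln_l", "ptv_ln_r")

# allowed prescription triplets for PTV-GTV / PTV-1 / PTV-2 (cGy)
PRESCRIPTION_COMBOS = ((7000.0, 6400.0, 5800.0), (7000.0, 6000.0, 5400.0))
# allowed nodal (PTV-LN) prescription levels (cGy)
NODAL_LEVELS = (6000.0, 6200.0, 6400.0, 6600.0, 6800.0, 7000.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, anatomy-sampling and dose-engine parameters of a profile."""

    grid_shape: tuple[int, int, int] = (64, 224, 224)
    spacing_mm: float = 2.5
    fluence_shape: tuple[int, int] = (160, 160)
    fluence_pitch_mm: float = 2.5
    sad_mm: float = 1000.0
    gantry_angles_deg: tuple[float, ...] = DEFAULT_ANGLES
    # forward dose engine
    mu_eff_per_mm: float = 0.004  # effective 6 MV attenuation in water
    smoothing_sigma_mm: float = 3.0
    depth_step_mm: float = 5.0
    # reference-plan optimization
    opt_iterations: int = 60
    oar_weight: float = 0.08
    shell_weight: float = 0.02
    # anatomy jitter
    center_jitter_mm: float = 3.0
    radius_jitter_frac: float = 0.10
    hu_noise_sd: float = 12.0

    @property
    def grid(self) -> GridSpec:
        s = self.spacing_mm
        return GridSpec(shape=self.grid_shape, spacing=(s, s, s))

    @property
    def beams(self) -> BeamGeometry:
        return BeamGeometry(
            gantry_angles_deg=self.gantry_angles_deg,
            sad_mm=self.sad_mm,
            fluence_shape=self.fluence_shape,
            fluence_pitch_mm=self.fluence_pitch_mm,
        )


@dataclass
class PatientCase:
    """One case: anatomy, prescriptions, reference fluence and dose."""

    grid: GridSpec
    beams: BeamGeometry
    ct: np.ndarray  # HU
    ptv_masks: dict[str, np.ndarray]
    oar_masks: dict[str, np.ndarray]
    prescriptions: dict[str, float]  # cGy per PTV
    ptv_dose_mask: np.ndarray  # cGy; max prescription among covering PTVs
    dose: np.ndarray | None = None  # cGy
    fluence: np.ndarray | None = None  # MU, (n_beams, rows, cols)
    seed: int | None = None

    @property
    def n_slices(self) -> int:
        return self.grid.shape[0]

    def validate(self) -> None:
        grid_shape = self.grid.shape
        for name, arr in [("ct", self.ct), ("ptv_dose_mask", self.ptv_dose_mask)]:
            if arr.shape != grid_shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {grid_shape}")
        if set(self.oar_masks) != set(OAR_NAMES):
            missing = set(OAR_NAMES) - set(self.oar_masks)
            extra = set(self.oar_masks) - set(OAR_NAMES)
            raise ValueError(f"OAR masks mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        if set(self.ptv_masks) != set(PTV_NAMES):
            raise ValueError("PTV masks must be exactly " + ", ".join(PTV_NAMES))
        body = self.oar_masks["body"].astype(bool)
        for name, m in {**self.ptv_masks, **self.oar_masks}.items():
            if m.shape != grid_shape:
                raise ValueError(f"mask {name} has wrong shape")
            if name != "body" and np.any(m.astype(bool) & ~body):
                raise ValueError(f"mask {name} extends outside the body")
        gtv, p1, p2 = (self.ptv_masks[n].astype(bool) for n in ("ptv_gtv", "ptv_1", "ptv_2"))
        if np.any(gtv & ~p1) or np.any(p1 & ~p2):
            raise ValueError("PTV nesting violated: GTV must be inside PTV-1 inside PTV-2")
        levels = set(np.unique(self.ptv_dose_mask)) - {0.0}
        allowed = set(self.prescriptions.values())
        if not levels <= allowed:
            raise ValueError(f"ptv_dose_mask levels {levels} not in prescriptions {allowed}")
        if self.fluence is not None:
            want = (self.beams.n_beams,) + self.beams.fluence_shape
            if self.fluence.shape != want:
                raise ValueError(f"fluence shape {self.fluence.shape} != {want}")

    def input_channel_names(self) -> list[str]:
        """Fixed network-input channel order: PTV prescription mask, the 17
        OARs alphabetically, CT last (19 channels)."""
        return ["ptv_dose_mask"] + sorted(OAR_NAMES) + ["ct"]


def sample_prescriptions(rng: np.random.Generator) -> dict[str, float]:
    """Draw one prescription assignment from the allowed clinical sets."""
    gtv, p1, p2 = PRESCRIPTION_COMBOS[rng.integers(len(PRESCRIPTION_COMBOS))]
    return {
        "ptv_gtv": gtv,
        "ptv_1": p1,
        "ptv_2": p2,
        "ptv_ln_l": float(rng.choice(NODAL_LEVELS)),
        "ptv_ln_r": float(rng.choice(NODAL_LEVELS)),
    }


def _coords(grid: GridSpec):
    nz, ny, nx = grid.shape
    dz, dy, dx = grid.spacing
    ox, oy, oz = grid.origin
    z = (oz + np.arange(nz) * dz)[:, None, None]
    y = (oy + np.arange(ny) * dy)[None, :, None]
    x = (ox + np.arange(nx) * dx)[None, None, :]
    return z, y, x


def _ellipsoid(grid, center, radii):
    """Boolean mask of an axis-aligned ellipsoid; center/radii in mm (x,y,z)."""
    z, y, x = _coords(grid)
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _cylinder(grid, center_xy, radii_xy, z_range):
    z, y, x = _coords(grid)
    cx, cy = center_xy
    rx, ry = radii_xy
    z0, z1 = z_range
    return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0) & (z >= z0) & (z <= z1)


def generate_anatomy(seed: int, config: PhantomConfig | None = None) -> PatientCase:
    """Deterministic synthetic anatomy for one case.

    An elliptical soft-tissue body with bony spine/mandible and an air
    cavity, five PTVs (nested central targets plus mirrored lateral nodal
    cylinders) and seventeen OARs placed at anatomically plausible relative
    positions (parotids lateral and overlapping PTV-2, cord/brainstem
    posterior-central, paired organs mirrored left/right).
    """
    config = config or PhantomConfig()
    grid = config.grid
    rng = np.random.default_rng(seed)
    nz, ny, nx = grid.shape
    dz = grid.spacing[0]
    Z = nz * dz / 2.0  # half-extents (mm)
    Y = ny * grid.spacing[1] / 2.0
    X = nx * grid.spacing[2] / 2.0
    zmin, zmax = -Z + dz, Z - dz

    def jc(v):  # jitter a center coordinate
        return v + rng.uniform(-config.center_jitter_mm, config.center_jitter_mm)

    def jr(v):  # jitter a radius
        return v * (1 + rng.uniform(-config.radius_jitter_frac, config.radius_jitter_frac))

    # radius floor guaranteeing at least one voxel center falls inside an
    # ellipsoid at 2.5 mm sampling (sqrt(3)/2 * spacing)
    def rf(v):
        return max(v, 0.9 * config.spacing_mm)

    # Body sized so its BEV projection stays inside the fluence plane.
    half_plane = config.fluence_shape[1] * config.fluence_pitch_mm / 2.0
    ax = min(jr(0.60 * X), 0.88 * half_plane)
    ay = min(jr(0.70 * Y), 0.92 * half_plane)
    body = _cylinder(grid, (0.0, 0.0), (ax, ay), (-Z, Z))

    masks: dict[str, np.ndarray] = {"body": body}
    s = min(ax, ay)  # anatomy scale

    # --- targets ---------------------------------------------------------
    gtv_c = (jc(0.0), jc(-0.05 * s), jc(0.0))
    gtv_r = (jr(0.22 * s), jr(0.20 * s), jr(0.45 * Z))
    ptvs = {
        "ptv_gtv": _ellipsoid(grid, gtv_c, gtv_r),
        "ptv_1": _ellipsoid(grid, gtv_c, tuple(r * 1.30 for r in gtv_r)),
        "ptv_2": _ellipsoid(grid, gtv_c, tuple(r * 1.65 for r in gtv_r)),
    }
    ln_x = jr(0.58 * s)
    ln_r = (jr(0.14 * s), jr(0.16 * s))
    ln_z = (jc(-0.45 * Z), jc(0.35 * Z))
    ptvs["ptv_ln_l"] = _cylinder(grid, (+ln_x, jc(0.08 * s)), ln_r, ln_z)
    ptvs["ptv_ln_r"] = _cylinder(grid, (-ln_x, jc(0.08 * s)), ln_r, ln_z)
    ptvs = {k: (v & body) for k, v in ptvs.items()}

    # --- OARs ------------------------------------------------------------
    masks["spinal_cord"] = _cylinder(
        grid, (jc(0.0), jc(0.62 * ay)), (0.09 * s, 0.09 * s), (-Z, jc(0.2 * Z))
    )
    masks["brainstem"] = _cylinder(
        grid, (jc(0.0), jc(0.50 * ay)), (0.11 * s, 0.11 * s), (jc(0.2 * Z), Z)
    )
    masks["chiasm"] = _ellipsoid(
        grid,
        (jc(0.0), jc(-0.15 * s), jc(0.62 * Z)),
        (rf(0.12 * s), rf(0.05 * s), rf(0.9 * dz + 0.04 * Z)),
    )
    masks["tongue"] = _ellipsoid(
        grid, (jc(0.0), jc(-0.55 * ay), jc(-0.45 * Z)), (0.22 * s, 0.18 * s, 0.35 * Z)
    )
    eye_y = -0.72 * ay
    for side, sgn in (("l", +1), ("r", -1)):
        masks[f"optic_nerve_{side}"] = _ellipsoid(
            grid,
            (sgn * jr(0.16 * s), jc(-0.45 * ay), jc(0.62 * Z)),
            (rf(0.12 * s), rf(0.05 * s), rf(0.05 * Z + 0.9 * dz)),
        )
        masks[f"lens_{side}"] = _ellipsoid(
            grid,
            (sgn * jr(0.28 * s), jc(eye_y), jc(0.62 * Z)),
            (rf(0.06 * s), rf(0.05 * s), rf(0.04 * Z + 0.9 * dz)),
        )
        masks[f"temporal_lobe_{side}"] = _ellipsoid(
            grid, (sgn * jr(0.55 * s), jc(0.05 * s), jc(0.7 * Z)), (0.22 * s, 0.28 * s, 0.35 * Z)
        )
        masks[f"mandible_{side}"] = _cylinder(
            grid, (sgn * jr(0.40 * s), jc(-0.60 * ay)), (0.10 * s, 0.08 * s), (jc(-0.8 * Z), jc(-0.2 * Z))
        )
        masks[f"tmj_{side}"] = _ellipsoid(
            grid,
            (sgn * jr(0.62 * s), jc(0.12 * s), jc(-0.1 * Z)),
            (rf(0.07 * s), rf(0.07 * s), rf(0.12 * Z)),
        )
        masks[f"parotid_{side}"] = _ellipsoid(
            grid, (sgn * jr(0.66 * s), jc(0.18 * s), jc(-0.15 * Z)), (0.18 * s, 0.22 * s, 0.45 * Z)
        )
    masks = {k: (v & body) if k != "body" else v for k, v in masks.items()}

    # --- CT --------------------------------------------------------------
    ct = np.full(grid.shape, -1000.0)
    ct[body] = 30.0
    spine_bone = _cylinder(grid, (0.0, 0.62 * ay), (0.14 * s, 0.14 * s), (-Z, Z)) & body
    ct[spine_bone & ~masks["spinal_cord"]] = 700.0
    for side in ("l", "r"):
        ct[masks[f"mandible_{side}"]] = 700.0
    air = _ellipsoid(grid, (0.0, -0.30 * ay, 0.1 * Z), (0.14 * s, 0.10 * s, 0.25 * Z)) & body
    air &= ~ptvs["ptv_2"]  # keep targets in soft tissue
    ct[air] = -800.0
    ct[body] += rng.normal(0.0, config.hu_noise_sd, size=int(body.sum()))

    prescriptions = sample_prescriptions(rng)
    pdm = np.zeros(grid.shape)
    for name in PTV_NAMES:
        m = ptvs[name]
        pdm[m] = np.maximum(pdm[m], prescriptions[name])

    case = PatientCase(
        grid=grid,
        beams=config.beams,
        ct=ct,
        ptv_masks=ptvs,
        oar_masks=masks,
        prescriptions=prescriptions,
        ptv_dose_mask=pdm,
        seed=seed,
    )
    case.validate()
    return case


# ---------------------------------------------------------------------------
# forward dose engine


def hu_to_density(ct: np.ndarray) -> np.ndarray:
    """Relative electron density from HU via a two-segment linear ramp.

    -1000 HU -> 0 (air), 0 HU -> 1 (water), +2000 HU -> 2 (dense bone);
    clipped below at 0.
    """
    ct = np.asarray(ct, dtype=np.float64)
    rho = np.where(ct <= 0, 1.0 + ct / 1000.0, 1.0 + ct / 2000.0)
    return np.clip(rho, 0.0, None)


def radiological_depth(
    ct: np.ndarray,
    grid: GridSpec,
    beams: BeamGeometry,
    beam_index: int,
    step_mm: float = 5.0,
    chunk: int = 32768,
) -> np.ndarray:
    """Water-equivalent depth (mm) of every voxel along its divergent ray.

    Midpoint-rule integral of relative density sampled every ``step_mm``
    from outside the grid down to the voxel; samples beyond the grid are
    treated as vacuum.
    """
    density = hu_to_density(ct)
    angle = beams.gantry_angles_deg[beam_index]
    src = gantry_source_position(angle, beams.sad_mm)
    pts = grid.voxel_centers()  # (N, 3) physical
    ext = np.array(grid.shape)[::-1] * np.array(grid.spacing)[::-1]  # (x,y,z) mm
    ray_len = float(np.linalg.norm(ext))  # upper bound on in-grid path
    n_steps = max(2, int(np.ceil(ray_len / step_mm)))
    svals = (np.arange(n_steps) + 0.5) * (ray_len / n_steps)

    dz, dy, dx = grid.spacing
    ox, oy, oz = grid.origin
    depth = np.empty(pts.shape[0])
    for lo in range(0, pts.shape[0], chunk):
        p = pts[lo : lo + chunk]
        u = p - src
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # sample positions p - u*s, converted to fractional voxel indices
        sample = p[:, None, :] - u[:, None, :] * svals[None, :, None]
        iz = (sample[..., 2] - oz) / dz
        iy = (sample[..., 1] - oy) / dy
        ix = (sample[..., 0] - ox) / dx
        vals = ndimage.map_coordinates(
            density,
            np.stack([iz.ravel(), iy.ravel(), ix.ravel()]),
            order=1,
            mode="constant",
            cval=0.0,
        ).reshape(iz.shape)
        depth[lo : lo + chunk] = vals.sum(axis=1) * (ray_len / n_steps)
    return depth.reshape(grid.shape)


class DoseEngine:
    """Linear fluence->dose map for one case's CT and beam geometry.

    dose(i) = sum_b f_b(j(i)) * (SAD/d_i)^2 * exp(-mu_eff * depth_b(i)),
    optionally followed by a 3D Gaussian blur.  The unsmoothed map and its
    exact adjoint drive the reference-plan optimizer; calibration is
    1 cGy per MU for a beamlet at the isocenter in vacuum.
    """

    def __init__(
        self,
        ct: np.ndarray,
        grid: GridSpec,
        beams: BeamGeometry,
        config: PhantomConfig,
        operators: list[ProjectionOperator] | None = None,
    ):
        self.grid = grid
        self.beams = beams
        self.config = config
        self.operators = operators or build_all_operators(grid, beams)
        self.influence: list[sp.csr_matrix] = []
        for b, op in enumerate(self.operators):
            depth = radiological_depth(
                ct, grid, beams, b, step_mm=config.depth_step_mm
            ).ravel()
            atten = np.exp(-config.mu_eff_per_mm * depth)
            A = sp.diags(atten) @ op.matrix  # (n_vox, n_beamlets)
            self.influence.append(A.tocsr())

    def dose(self, fluence: np.ndarray, smooth: bool = True) -> np.ndarray:
        """Dose volume (cGy) from a fluence stack (MU)."""
        want = (self.beams.n_beams,) + self.beams.fluence_shape
        if fluence.shape != want:
            raise ValueError(f"fluence shape {fluence.shape} != {want}")
        d = np.zeros(self.grid.n_voxels)
        for A, f in zip(self.influence, fluence):
            d += A @ f.ravel()
        d = d.reshape(self.grid.shape)
        if smooth and self.config.smoothing_sigma_mm > 0:
            sig = self.config.smoothing_sigma_mm / np.array(self.grid.spacing)
            d = ndimage.gaussian_filter(d, sigma=sig)
        return d

    def adjoint(self, residual: np.ndarray) -> np.ndarray:
        """Adjoint of the unsmoothed dose map: per-beam fluence gradients."""
        r = residual.ravel()
        out = np.empty((self.beams.n_beams,) + self.beams.fluence_shape)
        for b, A in enumerate(self.influence):
            out[b] = (A.T @ r).reshape(self.beams.fluence_shape)
        return out


def forward_dose(
    fluence: np.ndarray,
    ct: np.ndarray,
    grid: GridSpec,
    beams: BeamGeometry,
    config: PhantomConfig | None = None,
    smooth: bool = True,
    engine: DoseEngine | None = None,
) -> np.ndarray:
    """Convenience wrapper building a :class:`DoseEngine` and applying it."""
    engine = engine or DoseEngine(ct, grid, beams, config or PhantomConfig())
    return engine.dose(fluence, smooth=smooth)


def optimize_reference_fluence(
    case: PatientCase,
    engine: DoseEngine,
    config: PhantomConfig | None = None,
    return_history: bool = False,
):
    """Reference-plan fluence by projected gradient descent.

    Minimizes the weighted least-squares objective
    ``0.5 * sum_i w_i (dose_i - target_i)^2`` with target = prescription
    inside PTVs and 0 inside OARs and the remaining body shell, using the
    unsmoothed dose map; the fluence is projected onto the non-negative
    orthant after every step.  Deterministic.
    """
    config = config or engine.config
    grid = engine.grid
    ptv = case.ptv_dose_mask.ravel()
    in_ptv = ptv > 0
    body = case.oar_masks["body"].astype(bool).ravel()
    oar_union = np.zeros_like(body)
    for name in OAR_NAMES:
        if name != "body":
            oar_union |= case.oar_masks[name].astype(bool).ravel()
    w = np.zeros(grid.n_voxels)
    t = np.zeros(grid.n_voxels)
    w[body] = config.shell_weight
    w[oar_union & ~in_ptv] = config.oar_weight
    w[in_ptv] = 1.0
    t[in_ptv] = ptv[in_ptv]

    # warm start: uniform fluence on the BEV PTV(+5mm) footprints,
    # scaled by an exact 1D line search along that direction
    init = np.stack(
        [
            bev_target_mask(case.ptv_dose_mask > 0, op, margin_mm=5.0).astype(float)
            for op in engine.operators
        ]
    )
    Am = engine.dose(init, smooth=False).ravel()
    denom = float(Am @ (w * Am))
    scale = float((Am @ (w * t)) / denom) if denom > 0 else 0.0
    f = np.maximum(init * scale, 0.0)

    # fixed step from a power-iteration estimate of the Lipschitz constant
    v = np.ones_like(f)
    lam = 1.0
    for _ in range(8):
        Av = engine.dose(v, smooth=False).ravel()
        v2 = engine.adjoint(w * Av)
        lam = float(np.sqrt(np.sum(v2 * v2)))
        if lam == 0:
            break
        v = v2 / lam
    step = 1.0 / max(lam, 1e-12)

    history = []
    bad = 0
    for _ in range(config.opt_iterations):
        r = engine.dose(f, smooth=False).ravel() - t
        obj = 0.5 * float(np.sum(w * r * r))
        if history and obj > history[-1] + 1e-9:
            bad += 1
            if bad > 5:
                raise RuntimeError(
                    "reference-plan optimization diverged; reduce the step size"
                )
        else:
            bad = 0
        history.append(obj)
        g = engine.adjoint(w * r)
        f = np.maximum(f - step * g, 0.0)
    return (f, history) if return_history else f


def generate_case(
    seed: int,
    config: PhantomConfig | None = None,
    operators: list[ProjectionOperator] | None = None,
    engine: DoseEngine | None = None,
) -> PatientCase:
    """Full synthetic case: anatomy + optimized fluence + forward dose."""
    config = config or PhantomConfig()
    case = generate_anatomy(seed, config)
    engine = engine or DoseEngine(case.ct, case.grid, case.beams, config, operators)
    case.fluence = optimize_reference_fluence(case, engine, config)
    case.dose = engine.dose(case.fluence, smooth=True)
    case.validate()
    return case
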