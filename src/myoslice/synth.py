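"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the raw data of a failing-myocardium slice study:

* 3D membrane-stained (WGA-like) cardiomyocyte volumes with a closed surface
  sarcolemma and an internal t-tubule system of tunable geometry and density,
  including depth attenuation and detector noise;
* 2D mosaics of elongated myocytes with known per-cell orientations and a
  programmable fraction of disarrayed cells;
* striated alpha-actinin-like patterns with a known sarcomere period;
* paced force traces following the 0.2/0.5/1/2 Hz staircase protocol with a
  programmable twitch shape and frequency response;
* cohort tables tying t-system remodeling (dTT), Ca2+-handling protein levels
  and contractile kinetics together through known generating models.

Every generator takes an explicit ``rng_seed`` and is bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .core import InvalidSpecError, VoxelStack
from .kinetics import DEFAULT_PROTOCOL, ForceTrace, TwitchParams

__all__ = [
    "TubulePhantomSpec",
    "SyntheticGroundTruth",
    "TwitchShape",
    "gen_tsystem_stack",
    "brute_force_dtt",
    "gen_myocyte_mosaic",
    "gen_sarcomere_pattern",
    "gen_force_trace",
    "gen_cohort",
    "LATTICE_DTT_FACTOR",
]

#: Mean distance to the nearest corner of a square cell of unit spacing:
#: (1/6) * (sqrt(2) + asinh(1)) -- the radius->0 limit for a square lattice
#: of tubules running along the cell's long axis.
LATTICE_DTT_FACTOR = (math.sqrt(2.0) + math.log(1.0 + math.sqrt(2.0))) / 6.0

GEOMETRIES = ("full-lattice", "sheets", "surface-only", "custom")


@dataclass(frozen=True)
class TubulePhantomSpec:
    """Specification of a membrane-stained cardiomyocyte phantom.

    ``cell_extent_um`` and ``voxel_size_um`` are (z, y, x). ``geometry``
    selects the internal tubule arrangement: ``full-lattice`` draws tubules
    along z on a square y-x lattice, ``sheets`` draws planes normal to y,
    ``surface-only`` leaves the interior tubule-free, and ``custom`` takes a
    caller-provided boolean ``custom_mask``. Tubule positions are snapped to
    voxel centers, so a single-voxel tubule realises the radius->0 ideal in
    the voxel-center metric.
    """

    cell_extent_um: tuple[float, float, float] = (5.8, 19.0, 19.0)
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1)
    geometry: str = "full-lattice"
    lattice_spacing_um: float = 1.8
    tubule_radius_um: float = 0.05
    surface_thickness_um: float = 0.2
    intensity_background: float = 10.0
    intensity_membrane: float = 100.0
    attenuation_coefficient_per_um: float = 0.0
    noise_sigma: float = 0.0
    poisson_scaling: float | None = None
    blur_sigma_um: float = 0.0
    border_vox: int = 3
    rng_seed: int = 0
    custom_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise InvalidSpecError(f"unknown geometry {self.geometry!r}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise InvalidSpecError("voxel_size_um must be positive")
        if self.geometry in ("full-lattice", "sheets"):
            if self.lattice_spacing_um <= 2 * self.tubule_radius_um:
                raise InvalidSpecError("lattice spacing must exceed the tubule diameter")
            if self.lattice_spacing_um < 2 * max(self.voxel_size_um):
                raise InvalidSpecError("lattice spacing unresolvable at this voxel size")
        if min(self.stack_shape) < 64:
            raise InvalidSpecError("stack must be at least 64 voxels per axis")

    @property
    def stack_shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(e / v)) + 2 * self.border_vox
            for e, v in zip(self.cell_extent_um, self.voxel_size_um)
        )


@dataclass
class SyntheticGroundTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    rng_seed: int
    tubule_mask: np.ndarray | None = None
    cell_mask: np.ndarray | None = None
    surface_mask: np.ndarray | None = None
    true_delta_tt_um: float = np.nan
    label_map: np.ndarray | None = None
    true_orientations_deg: np.ndarray | None = None
    disarray_flags: np.ndarray | None = None
    true_sarcomere_length_um: float | None = None
    true_twitch_params: dict[float, TwitchParams] | None = None
    true_ffr_1_0p5: float | None = None
    true_ffr_2_0p5: float | None = None
    generating_coefficients: dict | None = None


# --------------------------------------------------------------------------
# 3D t-system phantoms
# --------------------------------------------------------------------------

def _periodic_axis(start: int, length: int, step_um: float, voxel_um: float):
    """Trim an axis to whole periods and return (lo, hi, tubule positions).

    The requested spacing is snapped to an integer number of voxels and the
    cell is trimmed (centred) to a whole number of periods; tubules sit at
    half-period offsets so voxel centers sample each period symmetrically.
    This keeps the discrete mean tubule distance at its continuum value.
    """
    step = max(1, int(round(step_um / voxel_um)))
    m = length // step
    if m < 1:
        raise InvalidSpecError("cell extent smaller than one tubule period")
    trimmed = m * step
    lo = start + (length - trimmed) // 2
    pos = lo + step // 2 + step * np.arange(m)
    return lo, lo + trimmed, pos.astype(int), step * voxel_um


def gen_tsystem_stack(spec: TubulePhantomSpec) -> tuple[VoxelStack, SyntheticGroundTruth]:
    """Render a membrane-stained myocyte volume plus exact ground truth.

    The cell is a box inset by ``border_vox`` from the stack edge. Its outer
    shell of ``surface_thickness_um`` is the surface sarcolemma; the interior
    holds the tubule geometry. Intensities are background plus membrane on
    (surface | tubules), optionally blurred, attenuated as exp(-c * depth)
    and degraded by Poisson and/or Gaussian noise.

    The returned ground truth carries exact masks and, for sheet and lattice
    geometries, the analytic mean tubule distance (spacing/4 for sheets and
    ``LATTICE_DTT_FACTOR * spacing`` for the lattice); for other geometries
    ``true_delta_tt_um`` is NaN (use :func:`brute_force_dtt`).
    """
    shape = spec.stack_shape
    dz, dy, dx = spec.voxel_size_um
    b = spec.border_vox
    lens = [n - 2 * b for n in shape]
    bounds = [(b, b + n) for n in lens]  # cell box, possibly trimmed below

    tub = np.zeros(shape, dtype=bool)
    # voxels whose center lies within the tubule radius of the centerline
    r_vox_y = int(math.floor(spec.tubule_radius_um / dy + 1e-9))
    true_dtt = np.nan
    actual_spacing = spec.lattice_spacing_um
    if spec.geometry == "sheets":
        lo_y, hi_y, ys, actual_spacing = _periodic_axis(b, lens[1], spec.lattice_spacing_um, dy)
        bounds[1] = (lo_y, hi_y)
        for y in ys:
            tub[:, max(y - r_vox_y, 0) : y + r_vox_y + 1, :] = True
        # the d/4 closed form holds for infinitesimally thin sheets only
        true_dtt = actual_spacing / 4.0 if r_vox_y == 0 else np.nan
    elif spec.geometry == "full-lattice":
        lo_y, hi_y, ys, actual_spacing = _periodic_axis(b, lens[1], spec.lattice_spacing_um, dy)
        lo_x, hi_x, xs, _ = _periodic_axis(b, lens[2], spec.lattice_spacing_um, dx)
        bounds[1], bounds[2] = (lo_y, hi_y), (lo_x, hi_x)
        r_vox_x = int(math.floor(spec.tubule_radius_um / dx + 1e-9))
        for y in ys:
            for x in xs:
                tub[
                    :,
                    max(y - r_vox_y, 0) : y + r_vox_y + 1,
                    max(x - r_vox_x, 0) : x + r_vox_x + 1,
                ] = True
        # the corner-distance closed form is the radius->0 (single-voxel) limit
        true_dtt = LATTICE_DTT_FACTOR * actual_spacing if r_vox_y == r_vox_x == 0 else np.nan
    elif spec.geometry == "custom":
        if spec.custom_mask is None or spec.custom_mask.shape != shape:
            raise InvalidSpecError("custom geometry requires a custom_mask of stack shape")
        tub = spec.custom_mask.astype(bool)

    cell = np.zeros(shape, dtype=bool)
    cell[tuple(slice(lo, hi) for lo, hi in bounds)] = True
    tub &= cell

    s_vox = max(1, int(round(spec.surface_thickness_um / min(dy, dx))))
    interior = np.zeros(shape, dtype=bool)
    interior[tuple(slice(lo + s_vox, hi - s_vox) for lo, hi in bounds)] = True
    surface = cell & ~interior & ~tub

    membrane = surface | tub
    img = np.full(shape, spec.intensity_background, dtype=float)
    img[membrane] = spec.intensity_membrane
    if spec.blur_sigma_um > 0:
        img = gaussian_filter(img, sigma=[spec.blur_sigma_um / v for v in spec.voxel_size_um])
    if spec.attenuation_coefficient_per_um > 0:
        depth = (np.arange(shape[0]) * dz)[:, None, None]
        img = img * np.exp(-spec.attenuation_coefficient_per_um * depth)

    rng = np.random.default_rng(spec.rng_seed)
    if spec.poisson_scaling is not None:
        if spec.poisson_scaling <= 0:
            raise InvalidSpecError("poisson_scaling must be positive")
        img = rng.poisson(img * spec.poisson_scaling) / spec.poisson_scaling
    if spec.noise_sigma < 0:
        raise InvalidSpecError("noise_sigma must be >= 0")
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(img, 0.0, None)

    stack = VoxelStack(
        intensities=img,
        voxel_size_um=spec.voxel_size_um,
        channel_label="WGA",
        metadata={
            "rng_seed": spec.rng_seed,
            "geometry": spec.geometry,
            "actual_spacing_um": actual_spacing,
        },
    )
    truth = SyntheticGroundTruth(
        rng_seed=spec.rng_seed,
        tubule_mask=tub,
        cell_mask=cell,
        surface_mask=surface,
        true_delta_tt_um=float(true_dtt),
    )
    return stack, truth


def brute_force_dtt(
    tubule_mask: np.ndarray,
    cell_mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
) -> float:
    """Oracle mean tubule distance by exact nearest-neighbour search.

    For every cell voxel the minimum Euclidean distance (voxel centers, in
    micrometres) to any tubule voxel is found with an exact KD-tree query --
    a code path independent of the distance-transform implementation it
    cross-checks. Returns NaN when the tubule mask is empty.
    """
    tubule_mask = np.asarray(tubule_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if tubule_mask.shape != cell_mask.shape:
        raise InvalidSpecError("masks must share a shape")
    if not cell_mask.any():
        raise InvalidSpecError("cell mask is empty")
    if not tubule_mask.any():
        return float("nan")
    scale = np.asarray(voxel_size_um, dtype=float)
    tub_pts = np.argwhere(tubule_mask) * scale
    cell_pts = np.argwhere(cell_mask) * scale
    d, _ = cKDTree(tub_pts).query(cell_pts, k=1)
    return float(np.mean(d))


# --------------------------------------------------------------------------
# 2D mosaics and striation patterns
# --------------------------------------------------------------------------

def gen_myocyte_mosaic(
    n_cells: int,
    mean_angle_deg: float = 0.0,
    angle_sd_deg: float = 12.0,
    disarray_fraction: float = 0.11,
    rng_seed: int = 0,
    pixel_size_um: float = 1.0,
    tile_px: int = 64,
    cell_intensity: float = 40.0,
    membrane_intensity: float = 200.0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render a WGA-like mosaic of elongated myocytes with known orientations.

    Cells are rotated rectangles (dim interiors) on a square grid, separated
    by bright membrane/interstitium. Exactly ``round(disarray_fraction *
    n_cells)`` cells are drawn with an axial offset in (36, 60) degrees from
    ``mean_angle_deg`` (i.e. deviating by more than the 30-degree disarray
    criterion); aligned cells scatter normally with ``angle_sd_deg`` clipped
    to +-25 degrees so they never cross it. Angles are measured from the
    x (column) axis toward +y (rows), axial range [-90, 90).
    """
    if n_cells < 1:
        raise InvalidSpecError("n_cells must be >= 1")
    if not 0.0 <= disarray_fraction <= 1.0:
        raise InvalidSpecError("disarray_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)

    n_dis = int(round(disarray_fraction * n_cells))
    dis_idx = rng.choice(n_cells, size=n_dis, replace=False) if n_dis else np.array([], int)
    flags = np.zeros(n_cells, dtype=bool)
    flags[dis_idx] = True

    offsets = np.clip(rng.normal(0.0, angle_sd_deg, size=n_cells), -25.0, 25.0)
    dis_mag = rng.uniform(36.0, 60.0, size=n_cells)
    dis_sign = rng.choice([-1.0, 1.0], size=n_cells)
    offsets[flags] = (dis_mag * dis_sign)[flags]
    angles = mean_angle_deg + offsets
    angles = ((angles + 90.0) % 180.0) - 90.0  # axial wrap

    grid = int(math.ceil(math.sqrt(n_cells)))
    size = grid * tile_px
    img = np.full((size, size), membrane_intensity, dtype=float)
    labels = np.zeros((size, size), dtype=np.int32)
    yy, xx = np.mgrid[0:size, 0:size]
    a, bwidth = 0.35 * tile_px, 0.12 * tile_px
    for k in range(n_cells):
        r, c = divmod(k, grid)
        cy, cx = (r + 0.5) * tile_px, (c + 0.5) * tile_px
        th = math.radians(angles[k])
        u = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
        v = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
        inside = (np.abs(u) <= a) & (np.abs(v) <= bwidth)
        img[inside] = cell_intensity
        labels[inside] = k + 1
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, size=img.shape), 0.0, None)

    truth = SyntheticGroundTruth(
        rng_seed=rng_seed,
        label_map=labels,
        true_orientations_deg=angles,
        disarray_flags=flags,
        generating_coefficients={
            "mean_angle_deg": mean_angle_deg,
            "angle_sd_deg": angle_sd_deg,
            "disarray_fraction": disarray_fraction,
            "pixel_size_um": pixel_size_um,
        },
    )
    return img, truth


def gen_sarcomere_pattern(
    length_um: float,
    angle_deg: float = 0.0,
    image_size: int = 256,
    pixel_size_um: float = 0.1,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    offset: float = 100.0,
    amplitude: float = 50.0,
) -> np.ndarray:
    """Sinusoidal alpha-actinin-like striation of period ``length_um``.

    Striations run perpendicular to ``angle_deg`` (the direction of the
    spatial-frequency vector, measured from the x axis). The sampling must
    resolve the period with at least four pixels.
    """
    if length_um <= 0:
        raise InvalidSpecError("length_um must be positive")
    if pixel_size_um > length_um / 4.0:
        raise InvalidSpecError("pixel size too coarse for the requested period")
    rng = np.random.default_rng(rng_seed)
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    th = math.radians(angle_deg)
    phase = (xx * math.cos(th) + yy * math.sin(th)) * pixel_size_um / length_um
    img = offset + amplitude * np.cos(2.0 * np.pi * phase)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


# --------------------------------------------------------------------------
# Paced force traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwitchShape:
    """Biexponential twitch F(t) = A * (exp(-t/tau_decay) - exp(-t/tau_rise))."""

    tau_rise_s: float
    tau_decay_s: float

    def __post_init__(self) -> None:
        if self.tau_decay_s <= self.tau_rise_s or self.tau_rise_s <= 0:
            raise InvalidSpecError("twitch shape requires 0 < tau_rise < tau_decay")

    def value(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.exp(-t / self.tau_decay_s) - np.exp(-t / self.tau_rise_s)
        return np.where(t >= 0, out, 0.0)

    def ttp(self) -> float:
        """Closed-form time to peak: tr*td*ln(td/tr)/(td-tr)."""
        tr, td = self.tau_rise_s, self.tau_decay_s
        return tr * td * math.log(td / tr) / (td - tr)

    def peak_factor(self) -> float:
        """Peak of the unit-coefficient twitch: (tr/td)^(tr/(td-tr)) - (tr/td)^(td/(td-tr))."""
        tr, td = self.tau_rise_s, self.tau_decay_s
        r = tr / td
        return r ** (tr / (td - tr)) - r ** (td / (td - tr))

    def ttr(self, recovery: float = 0.9) -> float:
        """Numerically solved time from peak to ``recovery`` relaxation of the peak."""
        ttp = self.ttp()
        level = (1.0 - recovery) * self.peak_factor()
        f = lambda t: float(self.value(np.array(t))) - level
        hi = ttp + 30.0 * self.tau_decay_s
        return brentq(f, ttp, hi) - ttp


#: Default per-frequency twitch shapes: kinetics accelerate with pacing rate
#: so each twitch relaxes fully within its stimulation period.
DEFAULT_TWITCH_SHAPES: dict[float, TwitchShape] = {
    0.2: TwitchShape(0.05, 0.15),
    0.5: TwitchShape(0.05, 0.15),
    1.0: TwitchShape(0.045, 0.13),
    2.0: TwitchShape(0.03, 0.065),
}


def gen_force_trace(
    protocol: tuple[tuple[float, float], ...] = DEFAULT_PROTOCOL,
    twitch_shapes: dict[float, TwitchShape] | TwitchShape | None = None,
    amplitudes: dict[float, float] | float = 2.5,
    baseline_mN: float = 0.5,
    noise_sd: float = 0.0,
    sampling_hz: float = 1000.0,
    rng_seed: int = 0,
    allow_fusion: bool = False,
    fusion_tolerance: float = 0.05,
) -> tuple[ForceTrace, SyntheticGroundTruth]:
    """Simulate a paced staircase force recording with exact twitch truth.

    Each stimulus adds one biexponential twitch of the per-frequency shape
    and amplitude coefficient A (the twitch peak is A * peak_factor, stored
    in the ground truth together with the closed-form TTP and numerically
    solved TTR/CD90). Unless ``allow_fusion``, the residual force at the end
    of each stimulation period must stay below ``fusion_tolerance`` of the
    twitch peak.
    """
    shapes: dict[float, TwitchShape] = {}
    amps: dict[float, float] = {}
    for f_hz, _ in protocol:
        if isinstance(twitch_shapes, TwitchShape):
            shapes[f_hz] = twitch_shapes
        elif twitch_shapes is not None:
            shapes[f_hz] = twitch_shapes[f_hz]
        else:
            shapes[f_hz] = DEFAULT_TWITCH_SHAPES.get(f_hz, TwitchShape(0.05, 0.15))
        amps[f_hz] = amplitudes[f_hz] if isinstance(amplitudes, dict) else float(amplitudes)

    for f_hz, _ in protocol:
        sh = shapes[f_hz]
        residual = float(sh.value(np.array(1.0 / f_hz))) / sh.peak_factor()
        if residual > fusion_tolerance and not allow_fusion:
            raise InvalidSpecError(
                f"twitch at {f_hz} Hz does not relax within the stimulation period"
            )

    total = sum(d for _, d in protocol)
    n = int(round(total * sampling_hz))
    t = np.arange(n) / sampling_hz
    force = np.full(n, baseline_mN, dtype=float)

    stim_times: list[float] = []
    truth_params: dict[float, TwitchParams] = {}
    t0 = 0.0
    for f_hz, dur in protocol:
        sh, amp = shapes[f_hz], amps[f_hz]
        period = 1.0 / f_hz
        n_stim = int(math.floor(dur * f_hz))
        for k in range(n_stim):
            s = t0 + k * period
            stim_times.append(s)
            i0 = int(math.ceil(s * sampling_hz - 1e-9))
            i1 = min(n, i0 + int(math.ceil(40.0 * sh.tau_decay_s * sampling_hz)))
            force[i0:i1] += amp * sh.value(t[i0:i1] - s)
        ttp = sh.ttp()
        ttr = sh.ttr()
        truth_params[f_hz] = TwitchParams(
            f_max_mN=amp * sh.peak_factor(),
            ttp_s=ttp,
            ttr_s=ttr,
            cd90_s=ttp + ttr,
            onset_time_s=0.0,
        )
        t0 += dur

    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        force = force + rng.normal(0.0, noise_sd, size=n)

    def _true_ratio(a: float, b: float) -> float | None:
        if a in truth_params and b in truth_params and truth_params[b].f_max_mN > 0:
            return truth_params[a].f_max_mN / truth_params[b].f_max_mN
        return None

    trace = ForceTrace(
        time_s=t,
        force_mN=force,
        sampling_hz=sampling_hz,
        protocol=tuple(protocol),
        stimulus_times_s=np.asarray(stim_times),
        metadata={"rng_seed": rng_seed, "baseline_mN": baseline_mN},
    )
    truth = SyntheticGroundTruth(
        rng_seed=rng_seed,
        true_twitch_params=truth_params,
        true_ffr_1_0p5=_true_ratio(1.0, 0.5),
        true_ffr_2_0p5=_true_ratio(2.0, 0.5),
        generating_coefficients={
            "amplitudes": amps,
            "shapes": {f: (s.tau_rise_s, s.tau_decay_s) for f, s in shapes.items()},
            "baseline_mN": baseline_mN,
            "noise_sd": noise_sd,
        },
    )
    return trace, truth


# --------------------------------------------------------------------------
# Cohort tables
# --------------------------------------------------------------------------

def gen_cohort(
    n_samples: int = 13,
    ttr_coeff: float = 0.36,
    interaction_ratio: float = 0.069,
    dtt_range_um: tuple[float, float] = (0.8, 1.5),
    ncx1_range: tuple[float, float] = (0.2, 3.0),
    ffr_slope_per_um: float = -0.8,
    ffr_intercept: float = 1.84,
    ffr2_slope_per_um: float = -0.85,
    ffr2_intercept: float = 1.83,
    ttr_noise_sd: float = 0.02,
    ffr_noise_sd: float = 0.075,
    ffr2_noise_sd: float = 0.16,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Simulate a per-patient cohort table with known generating models.

    dTT is uniform over ``dtt_range_um`` (the observed remodeling range,
    about 0.8-1.5 um) and NCX1 uniform over ``ncx1_range``. Relaxation time
    follows the interaction model TTR = b1 * (dTT - r * NCX1 * dTT) + noise
    with defaults b1 = 0.36 s/um and r = 0.069 per NCX1 unit; the FFR ratios
    follow linear dTT models crossing 1.0 near dTT = 1.05 um, so that low
    and high remodeling groups show positive and negative FFR respectively.
    Per-frequency wall tension is the 0.5 Hz tension scaled by the programmed
    force ratios. All generating coefficients are recorded in the truth.
    """
    if n_samples < 3:
        raise InvalidSpecError("n_samples must be >= 3")
    for sd in (ttr_noise_sd, ffr_noise_sd, ffr2_noise_sd):
        if sd < 0:
            raise InvalidSpecError("noise sds must be >= 0")
    rng = np.random.default_rng(rng_seed)

    dtt = rng.uniform(*dtt_range_um, size=n_samples)
    ncx1 = rng.uniform(*ncx1_range, size=n_samples)
    serca2 = rng.uniform(0.5, 2.0, size=n_samples)
    plb = rng.uniform(0.5, 2.0, size=n_samples)
    plb_ps16 = plb * rng.uniform(0.2, 0.8, size=n_samples)
    plb_pt17 = plb * rng.uniform(0.1, 0.6, size=n_samples)

    ttr = ttr_coeff * (dtt - interaction_ratio * ncx1 * dtt)
    ttr = ttr + rng.normal(0.0, ttr_noise_sd, size=n_samples)
    ttp = 0.16 + rng.normal(0.0, 0.02, size=n_samples)
    ffr1 = ffr_intercept + ffr_slope_per_um * dtt + rng.normal(0.0, ffr_noise_sd, n_samples)
    ffr2 = ffr2_intercept + ffr2_slope_per_um * dtt + rng.normal(0.0, ffr2_noise_sd, n_samples)
    tension_0p5 = rng.uniform(0.9, 1.3, size=n_samples)
    ratio_0p2 = rng.normal(0.9, 0.03, size=n_samples)

    df = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:02d}" for i in range(n_samples)],
            "delta_tt_um": dtt,
            "ncx1": ncx1,
            "serca2": serca2,
            "plb": plb,
            "plb_ps16": plb_ps16,
            "plb_pt17": plb_pt17,
            "serca2_plb_ratio": serca2 / plb,
            "plb_pt17_plb_ratio": plb_pt17 / plb,
            "ttp_1hz_s": ttp,
            "ttr_1hz_s": ttr,
            "cd90_1hz_s": ttp + ttr,
            "ffr_1_0p5": ffr1,
            "ffr_2_0p5": ffr2,
            "tension_0p2_mN_mm2": tension_0p5 * ratio_0p2,
            "tension_0p5_mN_mm2": tension_0p5,
            "tension_1_mN_mm2": tension_0p5 * ffr1,
            "tension_2_mN_mm2": tension_0p5 * ffr2,
        }
    )
    truth = SyntheticGroundTruth(
        rng_seed=rng_seed,
        generating_coefficients={
            "ttr_coeff": ttr_coeff,
            "interaction_ratio": interaction_ratio,
            "ffr_slope_per_um": ffr_slope_per_um,
            "ffr_intercept": ffr_intercept,
            "ffr2_slope_per_um": ffr2_slope_per_um,
            "ffr2_intercept": ffr2_intercept,
            "ttr_noise_sd": ttr_noise_sd,
            "ffr_noise_sd": ffr_noise_sd,
            "dtt_range_um": dtt_range_um,
            "ncx1_range": ncx1_range,
        },
    )
    return df, truth
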