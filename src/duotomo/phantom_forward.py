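"""Synthetic breast cross-sections and acoustic forward models.

The phantom generator emulates the imaged quantities of a 2D breast
cross-section: a skin band, a parenchymal region bounded by a chest wall, a
vascular tree (apparent diameters 0.2-3 mm), a tumor with an echogenic halo,
and speckle-producing echo texture.  Benign and malignant archetypes differ in
vessel density inside the tumor and boundary zones, vessel tortuosity, tumor
shape irregularity and elongation, intratumoral echo texture, and the
amplitude/heterogeneity of the vascular photoacoustic signal -- the contrast
directions that distinguish the two classes in dual-modal breast imaging.

Forward models are deliberately simple and linear: band-limited pulses at the
transducer centre frequency, straight-ray time of flight at a single speed of
sound, and 1/r (photoacoustic) or 1/(r1*r2) (pulse-echo) amplitude decay with
distances floored at one pixel pitch.  Echo texture is represented by a
deterministic set of discrete point scatterers drawn from the reflectivity
map, which produces fully developed speckle under coherent summation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from . import _kernels
from .errors import GenerationError, InvalidProfileError, TruncationError
from .geometry import ArrayGeometry, ImagingGrid

__all__ = [
    "ArchetypeParams",
    "benign_archetype",
    "malignant_archetype",
    "VesselPhantom",
    "FluenceProfile",
    "ChannelData",
    "generate_breast_phantom",
    "make_fluence",
    "forward_pa",
    "forward_urct_frame",
    "sample_scatterers",
    "add_noise",
    "pulse_sigma_us",
]


# --------------------------------------------------------------------------
# archetypes


@dataclass(frozen=True)
class ArchetypeParams:
    """Generation parameters controlling the benign/malignant contrast."""

    n_background_vessels: int = 12
    tumor_vessel_base: float = 2.5
    tumor_vessel_factor: float = 1.0      # multiplies intratumoral vessel count
    boundary_vessel_factor: float = 1.0   # multiplies peritumoral vessel count
    tortuosity: float = 0.2               # heading noise per 1.2-mm step, rad
    shape_irregularity: float = 0.1       # radial boundary perturbation amplitude
    axis_ratio_range: tuple[float, float] = (1.0, 1.6)
    tumor_semiaxis_range_mm: tuple[float, float] = (4.5, 9.0)
    echo_texture_sd: float = 0.05         # intratumoral reflectivity patchiness
    amp_sigma: float = 0.15               # lognormal SD of per-vessel PA amplitude
    tumor_amp_factor: float = 1.0         # mean PA amplitude of tumor-zone vessels
    vessel_diameter_range_mm: tuple[float, float] = (0.2, 3.0)
    hypoechoic_factor: float = 0.35       # tumor-core reflectivity vs parenchyma
    halo_factor: float = 1.4              # echogenic-halo reflectivity


def benign_archetype() -> ArchetypeParams:
    return ArchetypeParams(
        tumor_vessel_factor=0.4,
        boundary_vessel_factor=0.4,
        tortuosity=0.18,
        shape_irregularity=0.07,
        axis_ratio_range=(1.0, 1.6),
        echo_texture_sd=0.05,
        amp_sigma=0.15,
        tumor_amp_factor=1.0,
    )


def malignant_archetype() -> ArchetypeParams:
    return ArchetypeParams(
        tumor_vessel_factor=3.0,
        boundary_vessel_factor=2.6,
        tortuosity=0.40,
        shape_irregularity=0.28,
        axis_ratio_range=(1.5, 2.8),
        echo_texture_sd=0.15,
        amp_sigma=0.45,
        tumor_amp_factor=1.6,
    )


# --------------------------------------------------------------------------
# domain types


@dataclass
class VesselPhantom:
    grid: ImagingGrid
    absorption_map: np.ndarray            # (n_y, n_x) optical-absorption proxy
    scatterer_map: np.ndarray             # (n_y, n_x) acoustic reflectivity
    vessel_paths: list                    # [(polyline (N,2) mm, diameter_mm), ...]
    tumor_mask: np.ndarray                # (n_y, n_x) bool
    skin_line: np.ndarray                 # per-column skin depth below image top, mm
    label: str                            # 'benign' | 'malignant'
    archetype_params: ArchetypeParams
    seed: int
    breast_mask: np.ndarray = None
    chest_line: np.ndarray = None


@dataclass(frozen=True)
class FluenceProfile:
    """Exponential depth decay exp(-mu_eff * z), normalised to 1 at the skin."""

    mode: str                             # 'dark_field' | 'bright_field'
    depth_ratio: float
    depth_mm: float
    mu_eff_per_mm: float
    surface_value: float = 1.0

    def __call__(self, depth_below_skin_mm):
        z = np.maximum(np.asarray(depth_below_skin_mm, dtype=float), 0.0)
        return self.surface_value * np.exp(-self.mu_eff_per_mm * z)


@dataclass
class ChannelData:
    """Time-sampled per-element signals (n_t, n_elements)."""

    samples: np.ndarray
    fs_MHz: float = 40.0
    c_mm_per_us: float = 1.52
    t0_us: float = 0.0
    modality: str = "PA"                  # 'PA' | 'US'
    emitter_index: int | None = None
    geometry_id: str = ""

    def __post_init__(self):
        if self.t0_us < 0:
            raise ValueError("t0 must be nonnegative")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("channel samples must be finite")


def make_fluence(
    mode: str = "dark_field", depth_ratio: float = 62.0, depth_mm: float = 50.0
) -> FluenceProfile:
    """Depth-decay profile with a prescribed surface-to-bottom fluence ratio.

    Dark-field illumination spreads light outside the imaging plane and decays
    62-fold over 50 mm; bright-field decays 220-fold.
    """
    if depth_ratio < 1:
        raise InvalidProfileError(f"depth ratio must be >= 1, got {depth_ratio}")
    mu = math.log(depth_ratio) / depth_mm if depth_ratio > 1 else 0.0
    return FluenceProfile(
        mode=mode, depth_ratio=float(depth_ratio), depth_mm=float(depth_mm),
        mu_eff_per_mm=mu,
    )


# --------------------------------------------------------------------------
# phantom generation


def _smooth_line(rng, n_x, base, amp, n_modes=3):
    x = np.linspace(0, 2 * np.pi, n_x)
    line = np.full(n_x, base, dtype=float)
    for k in range(1, n_modes + 1):
        line += amp / k * math.sin(rng.uniform(0, 2 * np.pi)) * np.cos(
            k * x + rng.uniform(0, 2 * np.pi)
        )
    return line


def _grow_vessel(rng, start_xy, heading, length_mm, tortuosity, step_mm=1.2):
    n = max(int(length_mm / step_mm), 2)
    pts = np.empty((n, 2))
    pts[0] = start_xy
    h = heading
    for i in range(1, n):
        h += rng.normal(0.0, tortuosity)
        pts[i] = pts[i - 1] + step_mm * np.array([math.cos(h), math.sin(h)])
    return pts


def _rasterize_vessels(grid, vessels, amps):
    """Draw polylines with per-vessel diameter and amplitude onto the grid."""
    canvas = np.zeros((grid.n_y, grid.n_x))
    by_radius = {}
    for (path, diam), amp in zip(vessels, amps):
        r_px = max(int(round(diam / 2.0 / grid.pitch_mm)), 0)
        by_radius.setdefault(r_px, []).append((path, amp))
    x0 = grid.center_xy[0] - grid.width_mm / 2.0
    ytop = grid.center_xy[1] + grid.depth_mm / 2.0
    for r_px, items in by_radius.items():
        layer = np.zeros_like(canvas)
        for path, amp in items:
            seg = np.diff(path, axis=0)
            seglen = np.hypot(seg[:, 0], seg[:, 1])
            n_pts = max(int(seglen.sum() / (0.4 * grid.pitch_mm)), 2)
            t = np.linspace(0, 1, n_pts)
            cum = np.concatenate([[0.0], np.cumsum(seglen)])
            if cum[-1] <= 0:
                continue
            xs = np.interp(t * cum[-1], cum, path[:, 0])
            ys = np.interp(t * cum[-1], cum, path[:, 1])
            cols = np.floor((xs - x0) / grid.pitch_mm).astype(int)
            rows = np.floor((ytop - ys) / grid.pitch_mm).astype(int)
            ok = (rows >= 0) & (rows < grid.n_y) & (cols >= 0) & (cols < grid.n_x)
            layer[rows[ok], cols[ok]] = np.maximum(layer[rows[ok], cols[ok]], amp)
        if r_px > 0:
            yy, xx = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
            layer = ndimage.grey_dilation(
                layer, footprint=(yy * yy + xx * xx) <= r_px * r_px
            )
        canvas = np.maximum(canvas, layer)
    return canvas


def _tumor_mask(grid, rng, params, depth_range=(13.0, 24.0)):
    a = rng.uniform(*params.tumor_semiaxis_range_mm)
    ar = rng.uniform(*params.axis_ratio_range)
    b = a / ar
    cx = rng.uniform(-0.25 * grid.width_mm, 0.25 * grid.width_mm)
    cdepth = rng.uniform(*depth_range)
    theta = rng.uniform(0, np.pi)
    # radial boundary perturbation by low-order Fourier modes
    n_modes = 4
    coeff = rng.normal(0.0, 0.5, size=(n_modes, 2))
    ytop = grid.center_xy[1] + grid.depth_mm / 2.0
    cy = ytop - cdepth
    X, Y = np.meshgrid(grid.x_mm - cx, grid.y_mm - cy)
    ct, st = math.cos(theta), math.sin(theta)
    U = X * ct + Y * st
    V = -X * st + Y * ct
    ang = np.arctan2(V / b, U / a)
    pert = np.zeros_like(ang)
    for k in range(n_modes):
        pert += (coeff[k, 0] * np.cos((k + 2) * ang) +
                 coeff[k, 1] * np.sin((k + 2) * ang)) / (k + 2)
    r_norm = np.sqrt((U / a) ** 2 + (V / b) ** 2)
    mask = r_norm <= 1.0 + params.shape_irregularity * pert
    return mask, (cx, cy), (a, b)


def generate_breast_phantom(
    grid: ImagingGrid,
    label: str = "benign",
    archetype_params: ArchetypeParams | None = None,
    seed: int = 0,
) -> VesselPhantom:
    """Generate a labelled 2D breast cross-section phantom, reproducibly.

    The same ``(seed, params, grid)`` always yields a bit-identical phantom.
    """
    if archetype_params is None:
        archetype_params = (
            malignant_archetype() if label == "malignant" else benign_archetype()
        )
    p = archetype_params
    rng = np.random.default_rng(seed)

    skin_line = _smooth_line(rng, grid.n_x, base=rng.uniform(3.8, 5.2), amp=0.8)
    chest_line = _smooth_line(
        rng, grid.n_x, base=grid.depth_mm - rng.uniform(6.0, 9.0), amp=1.5
    )
    depth_rows = grid.depth_of_row_mm[:, None]
    breast_mask = (depth_rows > skin_line[None, :]) & (depth_rows < chest_line[None, :])
    skin_band = (depth_rows > skin_line[None, :] - 0.8) & (
        depth_rows <= skin_line[None, :] + 0.4
    )

    tumor_mask, (cx, cy), _ = _tumor_mask(grid, rng, p)
    tumor_mask &= np.ones_like(breast_mask)
    if tumor_mask.sum() == 0:
        raise GenerationError("tumor mask is empty")
    if np.any(tumor_mask & ~breast_mask):
        raise GenerationError("tumor extends outside the breast region")

    ytop = grid.center_xy[1] + grid.depth_mm / 2.0
    dmin, dmax = p.vessel_diameter_range_mm

    def random_point_in_breast():
        for _ in range(100):
            col = rng.integers(0, grid.n_x)
            row = rng.integers(0, grid.n_y)
            if breast_mask[row, col]:
                return np.array([grid.x_mm[col], grid.y_mm[row]])
        raise GenerationError("could not place a vessel inside the breast")

    vessels = []
    amps = []
    # background vascular tree
    for _ in range(p.n_background_vessels):
        start = random_point_in_breast()
        path = _grow_vessel(
            rng, start, rng.uniform(0, 2 * np.pi), rng.uniform(15, 45), p.tortuosity
        )
        diam = float(np.clip(np.exp(rng.uniform(np.log(0.25), np.log(1.5))), dmin, dmax))
        vessels.append((path, diam))
        amps.append(float(np.exp(rng.normal(0.0, 0.15))))

    # tumor-zone and boundary-zone angiogenesis: short, tortuous, thin vessels
    halo_px = max(int(round(3.0 / grid.pitch_mm)), 1)
    boundary_ring = ndimage.binary_dilation(tumor_mask, iterations=halo_px) & ~tumor_mask

    # angiogenesis length scales with tumor size so the vessels stay in-zone
    r_eq_mm = math.sqrt(tumor_mask.sum() * grid.pitch_mm**2 / math.pi)

    def seed_zone_vessels(zone_mask, count, amp_mean):
        rows, cols = np.nonzero(zone_mask)
        if rows.size == 0:
            return
        for _ in range(count):
            k = rng.integers(0, rows.size)
            start = np.array([grid.x_mm[cols[k]], grid.y_mm[rows[k]]])
            path = _grow_vessel(
                rng, start, rng.uniform(0, 2 * np.pi),
                rng.uniform(0.5, 1.0) * r_eq_mm,
                1.3 * p.tortuosity, step_mm=0.8,
            )
            diam = float(np.clip(rng.uniform(0.2, 0.5), dmin, dmax))
            vessels.append((path, diam))
            amps.append(float(amp_mean * np.exp(rng.normal(0.0, p.amp_sigma))))

    n_tumor = rng.poisson(p.tumor_vessel_base * p.tumor_vessel_factor)
    n_bound = rng.poisson(p.tumor_vessel_base * p.boundary_vessel_factor)
    seed_zone_vessels(tumor_mask, int(n_tumor), p.tumor_amp_factor)
    seed_zone_vessels(boundary_ring, int(n_bound), p.tumor_amp_factor)

    absorption = _rasterize_vessels(grid, vessels, amps)
    absorption[~breast_mask] = 0.0
    absorption[skin_band] = np.maximum(absorption[skin_band], 1.2)

    # reflectivity: parenchymal speckle texture, hypoechoic core, echogenic halo
    texture = ndimage.gaussian_filter(
        rng.standard_normal((grid.n_y, grid.n_x)), sigma=2.0 / grid.pitch_mm
    )
    sd = texture.std()
    texture /= sd if sd > 0 else 1.0
    scatterer = np.zeros((grid.n_y, grid.n_x))
    scatterer[breast_mask] = 1.0 + 0.15 * texture[breast_mask]
    scatterer[boundary_ring] = p.halo_factor * (1.0 + 0.15 * texture[boundary_ring])
    scatterer[tumor_mask] = p.hypoechoic_factor * (
        1.0 + p.echo_texture_sd / max(p.hypoechoic_factor, 1e-9) * texture[tumor_mask]
    )
    scatterer = np.clip(scatterer, 0.0, None)
    # heterogeneous internal echoes: discrete echogenic foci inside the mass,
    # rate tied to the archetype's echo-texture parameter
    t_rows, t_cols = np.nonzero(tumor_mask)
    n_foci = rng.poisson(max(30.0 * p.echo_texture_sd - 1.0, 0.0))
    focus_r_px = max(int(round(0.8 / grid.pitch_mm)), 1)
    for _ in range(int(n_foci)):
        k = rng.integers(0, t_rows.size)
        rr, cc = np.ogrid[: grid.n_y, : grid.n_x]
        disk = (rr - t_rows[k]) ** 2 + (cc - t_cols[k]) ** 2 <= focus_r_px**2
        scatterer[disk & tumor_mask] = 4.0
    scatterer[skin_band] = 2.5
    chest_band = (depth_rows >= chest_line[None, :]) & (
        depth_rows < chest_line[None, :] + 1.5
    )
    scatterer[chest_band] = 2.0

    return VesselPhantom(
        grid=grid,
        absorption_map=absorption,
        scatterer_map=scatterer,
        vessel_paths=vessels,
        tumor_mask=tumor_mask,
        skin_line=skin_line,
        label=label,
        archetype_params=p,
        seed=int(seed),
        breast_mask=breast_mask,
        chest_line=chest_line,
    )


# --------------------------------------------------------------------------
# forward models


def pulse_sigma_us(f_center_MHz: float, bandwidth_frac: float) -> float:
    """Gaussian envelope SD giving the requested -6 dB fractional bandwidth."""
    return math.sqrt(2.0 * math.log(2.0)) / (math.pi * bandwidth_frac * f_center_MHz)


def _required_n_t(max_dist_mm, c, fs, sigma):
    return int(math.ceil((max_dist_mm / c + 3.0 * sigma) * fs)) + 2


def _depth_below_skin(grid, skin_line):
    return grid.depth_of_row_mm[:, None] - skin_line[None, :]


def forward_pa(
    phantom: VesselPhantom,
    fluence: FluenceProfile,
    geom: ArrayGeometry,
    fs_MHz: float = 40.0,
    c_mm_per_us: float = 1.52,
    n_t: int | None = None,
) -> ChannelData:
    """Photoacoustic channel data: band-limited N-shaped pulses at t = d/c.

    Each absorbing pixel emits with amplitude ``absorption * fluence(depth)``
    decaying as 1/max(d, pitch); contributions superpose linearly.  Only the
    receive elements of ``geom`` record signal.
    """
    grid = phantom.grid
    amp_map = phantom.absorption_map * fluence(_depth_below_skin(grid, phantom.skin_line))
    rows, cols = np.nonzero(amp_map > 0)
    src_xy = np.column_stack([grid.x_mm[cols], grid.y_mm[rows]])
    src_amp = amp_map[rows, cols]

    rx = geom.receiver_idx
    det_xy = geom.element_xy[rx]
    sigma = pulse_sigma_us(geom.f_center_MHz, geom.bandwidth_frac)
    if src_xy.shape[0] == 0:
        max_dist = geom.radius_mm + grid.width_mm
    else:
        # bound the farthest source-detector pair by grid corners
        corners = np.array(
            [[grid.x_mm[0], grid.y_mm[0]], [grid.x_mm[-1], grid.y_mm[0]],
             [grid.x_mm[0], grid.y_mm[-1]], [grid.x_mm[-1], grid.y_mm[-1]]]
        )
        diff = corners[:, None, :] - det_xy[None, :, :]
        max_dist = float(np.hypot(diff[..., 0], diff[..., 1]).max())
    need = _required_n_t(max_dist, c_mm_per_us, fs_MHz, sigma)
    if n_t is None:
        n_t = need
    elif n_t < need:
        raise TruncationError(
            f"sampling window {n_t} shorter than required {need} samples"
        )
    table, t_half, dt_tab = _kernels.make_pulse_table(
        "pa", geom.f_center_MHz, sigma, fs_MHz
    )
    sub = _kernels.pa_forward_kernel(
        np.ascontiguousarray(src_xy),
        np.ascontiguousarray(src_amp),
        np.ascontiguousarray(det_xy),
        fs_MHz, c_mm_per_us, grid.pitch_mm, n_t, table, t_half, dt_tab,
    )
    samples = np.zeros((n_t, geom.n_elements))
    samples[:, rx] = sub
    return ChannelData(
        samples=samples, fs_MHz=fs_MHz, c_mm_per_us=c_mm_per_us,
        modality="PA", geometry_id=f"ring{geom.n_elements}",
    )


def sample_scatterers(
    phantom: VesselPhantom, n_scatterers: int = 1600, seed: int | None = None
):
    """Deterministic discrete point-scatterer representation of the phantom.

    Positions are drawn uniformly over the support of the reflectivity map
    (sub-pixel jittered); reflectivity is the local map value.  The same
    phantom always yields the same scatterer set so that every per-emitter
    frame of a synthetic-aperture acquisition sees identical tissue.
    """
    if seed is None:
        seed = phantom.seed + 77_000
    rng = np.random.default_rng(seed)
    grid = phantom.grid
    rows, cols = np.nonzero(phantom.scatterer_map > 0)
    if rows.size == 0:
        return np.zeros((0, 2)), np.zeros(0)
    k = rng.integers(0, rows.size, size=min(n_scatterers, rows.size))
    # densify the diagnostically decisive tumor + halo region so that its
    # echo texture is actually sampled; per-scatterer amplitude is scaled by
    # sqrt(density ratio) so the expected envelope power is unchanged
    base_density = k.size / max(rows.size * grid.pitch_mm**2, 1e-9)
    dense_density = max(4.0, base_density)
    halo_px = max(int(round(3.0 / grid.pitch_mm)), 1)
    region = ndimage.binary_dilation(phantom.tumor_mask, iterations=halo_px)
    in_region = region[rows[k], cols[k]]
    rows_b, cols_b = rows[k][~in_region], cols[k][~in_region]
    t_rows, t_cols = np.nonzero(region & (phantom.scatterer_map > 0))
    if t_rows.size:
        n_dense = max(int(round(dense_density * t_rows.size * grid.pitch_mm**2)), 1)
        ke = rng.integers(0, t_rows.size, size=n_dense)
        rows_all = np.concatenate([rows_b, t_rows[ke]])
        cols_all = np.concatenate([cols_b, t_cols[ke]])
        scale = np.concatenate([
            np.ones(rows_b.size),
            np.full(n_dense, math.sqrt(base_density / dense_density)),
        ])
    else:
        rows_all, cols_all = rows_b, cols_b
        scale = np.ones(rows_all.size)
    jitter = rng.uniform(-0.5, 0.5, size=(rows_all.size, 2)) * grid.pitch_mm
    xy = np.column_stack([grid.x_mm[cols_all], grid.y_mm[rows_all]]) + jitter
    refl = phantom.scatterer_map[rows_all, cols_all] * scale
    return xy, refl


def forward_urct_frame(
    phantom: VesselPhantom,
    geom: ArrayGeometry,
    emitter_index: int,
    fs_MHz: float = 40.0,
    c_mm_per_us: float = 1.52,
    scatterers: tuple[np.ndarray, np.ndarray] | None = None,
    n_scatterers: int = 1600,
    n_t: int | None = None,
    receivers: np.ndarray | None = None,
) -> ChannelData:
    """Single-emitter pulse-echo frame received on the non-emitting elements.

    Scatterers outside the emitter's transmit diffraction cone (half-angle =
    upper end of ``geom.tx_half_angle_deg``) contribute nothing.
    ``receivers`` restricts reception to a subset of the receive elements
    (e.g. a decimated aperture); by default all receive elements listen.
    """
    if emitter_index not in set(geom.emitter_idx.tolist()):
        raise ValueError(f"element {emitter_index} is not an emitter")
    grid = phantom.grid
    if scatterers is None:
        scat_xy, refl = sample_scatterers(phantom, n_scatterers)
    else:
        scat_xy, refl = scatterers
        scat_xy = np.asarray(scat_xy, dtype=float).reshape(-1, 2)
        refl = np.asarray(refl, dtype=float)

    rx = geom.receiver_idx if receivers is None else np.asarray(receivers, int)
    det_xy = geom.element_xy[rx]
    sigma = pulse_sigma_us(geom.f_center_MHz, geom.bandwidth_frac)
    if scat_xy.shape[0] == 0:
        max_dist = 2.0 * geom.radius_mm
    else:
        e = geom.element_xy[emitter_index]
        d1 = np.hypot(scat_xy[:, 0] - e[0], scat_xy[:, 1] - e[1])
        # second leg bounded by |s| + R (receivers lie on the ring)
        max_dist = float(
            (d1 + np.hypot(scat_xy[:, 0], scat_xy[:, 1]) + geom.radius_mm).max()
        )
    need = _required_n_t(max_dist, c_mm_per_us, fs_MHz, sigma)
    if n_t is None:
        n_t = need
    elif n_t < need:
        raise TruncationError(
            f"sampling window {n_t} shorter than required {need} samples"
        )
    cos_gate = math.cos(math.radians(geom.tx_half_angle_deg[1]))
    table, t_half, dt_tab = _kernels.make_pulse_table(
        "us", geom.f_center_MHz, sigma, fs_MHz
    )
    sub = _kernels.urct_forward_kernel(
        np.ascontiguousarray(scat_xy),
        np.ascontiguousarray(refl),
        np.ascontiguousarray(geom.element_xy[emitter_index]),
        np.ascontiguousarray(geom.element_normal[emitter_index]),
        np.ascontiguousarray(det_xy),
        cos_gate, fs_MHz, c_mm_per_us, grid.pitch_mm, n_t,
        table, t_half, dt_tab,
    )
    samples = np.zeros((n_t, geom.n_elements))
    samples[:, rx] = sub
    return ChannelData(
        samples=samples, fs_MHz=fs_MHz, c_mm_per_us=c_mm_per_us,
        modality="US", emitter_index=int(emitter_index),
        geometry_id=f"ring{geom.n_elements}",
    )


def add_noise(
    cd: ChannelData, snr_db: float, seed: int = 0,
    columns: np.ndarray | None = None,
) -> ChannelData:
    """Additive white Gaussian noise at a prescribed peak-signal-to-RMS SNR.

    ``columns`` restricts the noisy channels (e.g. to the receive elements);
    by default every channel receives noise.
    """
    if np.isinf(snr_db):
        return replace(cd, samples=cd.samples.copy())
    peak = np.abs(cd.samples).max()
    if peak == 0:
        return replace(cd, samples=cd.samples.copy())
    rng = np.random.default_rng(seed)
    noise_rms = peak / 10.0 ** (snr_db / 20.0)
    noisy = cd.samples.copy()
    if columns is None:
        noisy += rng.normal(0.0, noise_rms, size=noisy.shape)
    else:
        cols = np.asarray(columns, dtype=int)
        noisy[:, cols] += rng.normal(0.0, noise_rms, size=(noisy.shape[0], cols.size))
    return replace(cd, samples=noisy)
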