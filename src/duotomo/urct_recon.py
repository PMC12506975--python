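"""Synthetic-aperture reflection ultrasound reconstruction and display.

Each per-emitter frame is beamformed by complex (analytic-signal) two-leg
delay-and-sum over the gated receivers -- only elements whose inward axis is
less than 90 degrees from the emitting element's axis, which rejects the
directly transmitted wave.  Per-frame envelopes are averaged (incoherent
compounding) and the compound envelope is log-compressed and contrast
equalised for display.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert
from skimage import exposure

from . import _kernels
from .errors import IncompleteCompoundError
from .geometry import ArrayGeometry, ImagingGrid
from .pact_recon import ReconImage
from .phantom_forward import ChannelData

__all__ = ["sa_compound_recon", "log_compress", "condition_us"]


def sa_compound_recon(
    frames: list[ChannelData],
    geom: ArrayGeometry,
    grid: ImagingGrid,
    c: float | None = None,
    tx_cone_gate: bool = True,
    rx_apodization: bool = True,
    rx_stride: int = 1,
) -> ReconImage:
    """Incoherently compound per-emitter synthetic-aperture reconstructions.

    Per frame, only receivers whose inward axis is less than 90 degrees from
    the emitter's axis are summed; with ``tx_cone_gate`` each frame
    reconstructs only the region inside the emitter's transmit diffraction
    cone (the only region it insonifies), and ``rx_apodization`` applies
    cosine receive-directivity weighting.  The compound image is the mean of
    the per-frame envelopes, normalised per pixel by the number of frames
    whose cone covers it.  ``rx_stride`` decimates the receive aperture (the
    same subset must have been used to record the frames).
    """
    have = {f.emitter_index for f in frames}
    missing = set(geom.emitter_idx.tolist()) - have
    if missing:
        raise IncompleteCompoundError(missing)
    rx = geom.receiver_idx[::max(int(rx_stride), 1)]
    det_xy = geom.element_xy[rx]
    det_nrm = geom.element_normal[rx]
    px = np.ascontiguousarray(grid.x_mm)
    py = np.ascontiguousarray(grid.y_mm)
    cos_tx = (
        np.cos(np.radians(geom.tx_half_angle_deg[1])) if tx_cone_gate else -1.0
    )
    env_sum = np.zeros((grid.n_y, grid.n_x))
    coverage = np.zeros((grid.n_y, grid.n_x))
    n = 0
    for cd in sorted(frames, key=lambda f: f.emitter_index):
        if cd.modality != "US":
            raise ValueError("sa_compound_recon expects ultrasound frames")
        c_use = cd.c_mm_per_us if c is None else c
        e_nrm = geom.element_normal[cd.emitter_index]
        gate = (det_nrm @ e_nrm) > 0.0  # axis angle < 90 deg
        sub = cd.samples[:, rx][:, gate]
        if sub.shape[1] == 0:
            continue
        analytic = hilbert(sub, axis=0)
        frame_img, cone, _ = _kernels.sa_das_kernel(
            np.ascontiguousarray(analytic),
            np.ascontiguousarray(geom.element_xy[cd.emitter_index]),
            np.ascontiguousarray(e_nrm),
            np.ascontiguousarray(det_xy[gate]),
            np.ascontiguousarray(det_nrm[gate]),
            px, py, c_use, cd.fs_MHz, cos_tx, 1 if rx_apodization else 0,
        )
        env_sum += np.abs(frame_img)
        coverage += cone
        n += 1
    env = env_sum / np.maximum(coverage, 1.0)
    return ReconImage(
        pixels=env, grid=grid, variant="envelope",
        provenance={"op": "sa_compound_recon", "n_frames": n,
                    "tx_cone_gate": tx_cone_gate,
                    "rx_apodization": rx_apodization},
    )


def log_compress(img: ReconImage, dynamic_range_db: float = 50.0) -> ReconImage:
    """Log compression and dynamic-range clipping of an envelope; [0, 1] output.

    This is the quantitative display scale: 20*log10(env/max) clipped to
    [-dynamic_range_db, 0] and mapped linearly onto [0, 1].
    """
    if img.variant != "envelope":
        raise ValueError("log_compress expects an envelope image")
    env = img.pixels
    peak = env.max()
    if peak <= 0:
        out = np.zeros_like(env)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(np.where(env > 0, env / peak, np.nan))
        db = np.where(np.isnan(db), -dynamic_range_db, db)
        db = np.clip(db, -dynamic_range_db, 0.0)
        out = (db + dynamic_range_db) / dynamic_range_db
    return ReconImage(
        pixels=out, grid=img.grid, variant="log",
        provenance={**img.provenance, "dynamic_range_db": dynamic_range_db},
    )


def condition_us(
    img: ReconImage,
    dynamic_range_db: float = 50.0,
    clahe_clip: float = 0.01,
    clahe_tiles: int = 8,
) -> ReconImage:
    """Log compression, dynamic-range clipping and CLAHE; output in [0, 1].

    CLAHE equalises contrast adaptively for display; quantitative amplitude
    statistics should be taken on the :func:`log_compress` output, whose
    scale is comparable across cases.
    """
    logimg = log_compress(img, dynamic_range_db)
    norm = logimg.pixels
    if np.ptp(norm) > 0:
        ky = max(norm.shape[0] // clahe_tiles, 2)
        kx = max(norm.shape[1] // clahe_tiles, 2)
        out = exposure.equalize_adapthist(
            norm, kernel_size=(ky, kx), clip_limit=clahe_clip
        )
    else:
        out = norm
    return ReconImage(
        pixels=out, grid=img.grid, variant="display",
        provenance={
            **logimg.provenance, "clahe_clip": clahe_clip,
            "clahe_tiles": clahe_tiles,
        },
    )
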