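"""Velocity fields and infinitesimal strain from displacement fields.

Strain uses the small-deformation (engineering) tensor: observed tissue
strains are below ~10%, so the linear components suffice.  The shear
component is tensorial, exy = (du/dy + dv/dx) / 2, and the sign convention
is tensile positive / compressive negative.  Gradients are central
differences on the vector grid, one-sided at borders; px units cancel in
the strain components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .piv import DisplacementField

__all__ = [
    "VelocityField",
    "StrainTensorField",
    "velocity_field",
    "velocity_series",
    "strain_fields",
    "principal_strains",
]


@dataclass
class VelocityField:
    """Grid velocities in um/s for frame ``frame_index`` (defined t >= 1)."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    frame_index: int = -1

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


@dataclass
class StrainTensorField:
    """Infinitesimal strain components per grid point (dimensionless)."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    exx: np.ndarray
    eyy: np.ndarray
    exy: np.ndarray
    valid: np.ndarray
    frame_index: int = -1

    def principal(self):
        return principal_strains(self)


def _check_same_grid(a, b) -> None:
    if not (np.array_equal(a.grid_x, b.grid_x) and np.array_equal(a.grid_y, b.grid_y)):
        raise ValueError("fields are defined on different grids")


def velocity_field(
    field_t: DisplacementField,
    field_prev: DisplacementField,
    dt_s: float,
    pixel_size_um: float,
    prev_ref_correction: DisplacementField | None = None,
) -> VelocityField:
    """Backward-difference velocity between consecutive displacement fields.

    ``v = (d_t - d_{t-1}) * pixel_size_um / dt_s``.  When the reference
    switched between the two frames, ``field_prev`` must first be
    re-expressed against the new reference; pass the recorded field of the
    new reference versus the old one as ``prev_ref_correction`` (the
    switch frame is near rest, so the correction is ~ -d_{t-1} when the
    new reference is the previous frame itself).
    """
    if not dt_s > 0:
        raise ValueError("dt_s must be > 0")
    _check_same_grid(field_t, field_prev)
    du_prev = field_prev.u
    dv_prev = field_prev.v
    valid = field_t.valid & field_prev.valid
    if field_t.reference_index != field_prev.reference_index:
        if prev_ref_correction is None:
            if field_t.reference_index == field_prev.frame_index:
                # new reference is the previous frame: d_prev vs itself is 0
                du_prev = field_prev.u * 0.0
                dv_prev = field_prev.v * 0.0
            else:
                raise ValueError(
                    "reference switched between frames; pass the new "
                    "reference's field versus the old reference"
                )
        else:
            _check_same_grid(field_t, prev_ref_correction)
            du_prev = field_prev.u - prev_ref_correction.u
            dv_prev = field_prev.v - prev_ref_correction.v
            valid &= prev_ref_correction.valid
    scale = pixel_size_um / dt_s
    return VelocityField(
        grid_x=field_t.grid_x,
        grid_y=field_t.grid_y,
        vx=(field_t.u - du_prev) * scale,
        vy=(field_t.v - dv_prev) * scale,
        valid=valid,
        frame_index=field_t.frame_index,
    )


def velocity_series(fields, fps: float, pixel_size_um: float):
    """Velocities for every consecutive pair in an AR-DIC field sequence.

    Reference switches are resolved automatically from the recorded
    ``reference_index`` of each field.
    """
    by_frame = {f.frame_index: f for f in fields}
    out = []
    for prev, cur in zip(fields, fields[1:]):
        corr = None
        if cur.reference_index != prev.reference_index:
            corr = by_frame.get(cur.reference_index)
            if corr is not None and corr.frame_index == prev.frame_index:
                corr = prev
        out.append(
            velocity_field(cur, prev, 1.0 / fps, pixel_size_um,
                           prev_ref_correction=corr)
        )
    return out


def strain_fields(
    field: DisplacementField,
    smooth_sigma_cells: float = 0.0,
) -> StrainTensorField:
    """Infinitesimal strain components from a displacement field.

    Optional Gaussian pre-smoothing of (u, v) (sigma in grid cells, off by
    default) tames the noise amplification of differentiation.
    """
    if field.u.shape[0] < 3 or field.u.shape[1] < 3:
        raise ValueError("need at least a 3x3 vector grid for strain")
    u = field.u.astype(float)
    v = field.v.astype(float)
    if smooth_sigma_cells > 0:
        u = gaussian_filter(u, smooth_sigma_cells, mode="nearest")
        v = gaussian_filter(v, smooth_sigma_cells, mode="nearest")
    gx = field.grid_x.astype(float)
    gy = field.grid_y.astype(float)
    dudy, dudx = np.gradient(u, gy, gx)
    dvdy, dvdx = np.gradient(v, gy, gx)
    interior = field.valid.copy()
    return StrainTensorField(
        grid_x=field.grid_x,
        grid_y=field.grid_y,
        exx=dudx,
        eyy=dvdy,
        exy=0.5 * (dudy + dvdx),
        valid=interior,
        frame_index=field.frame_index,
    )


def principal_strains(tensor: StrainTensorField):
    """Principal strains and angle from the 2D strain tensor.

    e1,2 = (exx+eyy)/2 +- sqrt(((exx-eyy)/2)^2 + exy^2), e1 >= e2, and
    theta_p = atan2(2 exy, exx - eyy) / 2.  The trace is conserved:
    e1 + e2 = exx + eyy.
    """
    mean = 0.5 * (tensor.exx + tensor.eyy)
    radius = np.sqrt((0.5 * (tensor.exx - tensor.eyy)) ** 2 + tensor.exy**2)
    e1 = mean + radius
    e2 = mean - radius
    theta = 0.5 * np.arctan2(2 * tensor.exy, tensor.exx - tensor.eyy)
    return e1, e2, theta
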