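"""Affine alignment of the template-space brain-stem atlas to a subject.

The brain-stem/peduncle atlas mask is drawn once in template space and
only used as a cut-out region whose boundary is afterwards smoothed by a
morphological opening, so a 9-parameter affine (3 translations, 3
rotations, 3 anisotropic scales) captures the mechanism; a nonlinear
backend can be slotted in behind the same ``align_atlas`` contract.

Optimization is deterministic and derivative-free: a center-of-mass /
second-moment initialization followed by coarse-to-fine (4/2/1 mm)
cyclic coordinate descent on the mean squared intensity difference, with
per-parameter step halving whenever a full sweep fails to improve the
cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ContractError, RegistrationError
from .volume_io import BinaryMask, Volume, read_mask, read_volume, resample_to_grid


@dataclass(frozen=True)
class AffineTransform:
    """World-to-world homogeneous transform in mm."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ContractError(f"transform must be 4x4, got {m.shape}")
        if not np.allclose(m[3], (0, 0, 0, 1)):
            raise ContractError(f"last row must be (0,0,0,1), got {m[3]}")
        det = np.linalg.det(m[:3, :3])
        if not (0.3 <= abs(det) <= 3.0):
            raise ContractError(
                f"3x3 block determinant {det:.4f} outside the sane range [0.3, 3]")
        object.__setattr__(self, "matrix", m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return AffineTransform(self.matrix @ other.matrix)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def save(self, path) -> None:
        np.savetxt(str(path), self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(str(path)))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))


@dataclass
class BrainStemAtlas:
    """Template intensity volume plus the brain-stem/peduncle mask on it."""

    template: Volume
    stem_mask: BinaryMask

    def __post_init__(self):
        from .volume_io import require_same_geometry
        require_same_geometry(self.template, self.stem_mask,
                              "atlas template and stem mask")
        if not self.stem_mask.data.any():
            raise ContractError("atlas stem mask is empty")

    @classmethod
    def load(cls, atlas_dir) -> "BrainStemAtlas":
        atlas_dir = Path(atlas_dir)
        return cls(template=read_volume(atlas_dir / "template.nii.gz"),
                   stem_mask=read_mask(atlas_dir / "stem_mask.nii.gz"))

    def save(self, atlas_dir) -> None:
        from .volume_io import write_volume
        atlas_dir = Path(atlas_dir)
        atlas_dir.mkdir(parents=True, exist_ok=True)
        write_volume(self.template, atlas_dir / "template.nii.gz")
        write_volume(self.stem_mask, atlas_dir / "stem_mask.nii.gz")


@dataclass(frozen=True)
class RegistrationConfig:
    levels_mm: tuple = (4.0, 2.0, 1.0)
    max_iter_per_level: int = 200
    cost_tol: float = 1e-6
    init_steps: tuple = (2.0, 2.0, 0.02)   # mm, degrees, scale per level start
    min_step_scale: float = 1.0 / 64       # stop once steps shrink below this
                                           # fraction of their level-start size


# ---------------------------------------------------------------------------

def _params_to_matrix(params: np.ndarray, center: np.ndarray) -> np.ndarray:
    """(tx,ty,tz, rx,ry,rz deg, sx,sy,sz) -> 4x4 about a fixed world center."""
    t = params[:3]
    rx, ry, rz = np.deg2rad(params[3:6])
    s = params[6:9]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    A = (Rz @ Ry @ Rx) * s[np.newaxis, :]
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = t + center - A @ center
    return M


def _moments(vol: Volume):
    """Intensity center of mass (world mm) and per-world-axis std (mm)."""
    w = np.clip(vol.data, 0, None)
    total = w.sum()
    if total <= 0:
        raise ContractError("volume has no positive mass")
    idx = np.indices(vol.shape, dtype=float)
    com_idx = np.array([(w * idx[i]).sum() / total for i in range(3)])
    com = vol.affine[:3, :3] @ com_idx + vol.affine[:3, 3]
    world = np.einsum("ab,b...->a...", vol.affine[:3, :3], idx) \
        + vol.affine[:3, 3][:, None, None, None]
    var = np.array([(w * (world[i] - com[i]) ** 2).sum() / total
                    for i in range(3)])
    return com, np.sqrt(var)


def register_affine(moving: Volume, fixed: Volume,
                    config: RegistrationConfig = RegistrationConfig()
                    ) -> AffineTransform:
    """Estimate the world transform mapping moving toward fixed.

    Initialization: translate the moving center of mass onto the fixed one
    and match per-axis second moments.  Refinement: coarse-to-fine cyclic
    coordinate descent on mean squared intensity difference over
    translation, rotation and per-axis scale, halving each step size when
    a full parameter sweep brings no improvement.  Fully deterministic.
    """
    for name, v in (("moving", moving), ("fixed", fixed)):
        if v.data.max() == v.data.min():
            raise ContractError(f"{name} volume is constant")

    com_m, sd_m = _moments(moving)
    com_f, sd_f = _moments(fixed)
    center = com_m
    scale0 = np.clip(sd_f / np.maximum(sd_m, 1e-9), 0.5, 2.0)
    params = np.concatenate([com_f - com_m, np.zeros(3), scale0])

    for level in config.levels_mm:
        mov_l = resample_to_grid(moving, level, "trilinear") \
            if not np.allclose(moving.spacing, level) else moving
        fix_l = resample_to_grid(fixed, level, "trilinear") \
            if not np.allclose(fixed.spacing, level) else fixed
        mov_data = mov_l.data.astype(np.float32)
        inv_mov = np.linalg.inv(mov_l.affine)
        # evaluate the cost on at most ~250k fixed voxels (strided subsample)
        stride = max(1, int(np.ceil((np.prod(fix_l.shape) / 250_000) ** (1 / 3))))
        sl = (slice(None, None, stride),) * 3
        fix_vals = fix_l.data[sl].astype(np.float32).ravel()
        idx = np.indices(fix_l.shape)[:, sl[0], sl[1], sl[2]].reshape(3, -1)
        fix_world = (fix_l.affine[:3, :3] @ idx
                     + fix_l.affine[:3, 3][:, None]).astype(np.float64)

        def cost(p):
            inv_world = np.linalg.inv(_params_to_matrix(p, center))
            pts = inv_mov @ np.vstack([inv_world[:3, :3] @ fix_world
                                       + inv_world[:3, 3][:, None],
                                       np.ones((1, fix_world.shape[1]))])
            sampled = ndimage.map_coordinates(mov_data, pts[:3], order=1,
                                              mode="constant", cval=0.0)
            c = float(np.mean((sampled - fix_vals) ** 2))
            if not np.isfinite(c):
                raise RegistrationError(
                    f"non-finite cost at level {level} mm with params {p}")
            return c

        level_scale = level / config.levels_mm[-1]
        init = np.concatenate([
            np.full(3, config.init_steps[0] * level_scale),
            np.full(3, config.init_steps[1] * level_scale),
            np.full(3, config.init_steps[2] * level_scale)])
        steps = init.copy()
        current = cost(params)
        for _ in range(config.max_iter_per_level):
            improved = False
            sweep_start = current
            for i in range(9):
                for sign in (+1.0, -1.0):
                    trial = params.copy()
                    trial[i] += sign * steps[i]
                    c = cost(trial)
                    if c < current:
                        params, current = trial, c
                        improved = True
                        # greedy: keep stepping while the cost keeps falling
                        while True:
                            trial = params.copy()
                            trial[i] += sign * steps[i]
                            c = cost(trial)
                            if c < current:
                                params, current = trial, c
                            else:
                                break
                        break
            if not improved:
                steps *= 0.5
                if np.all(steps < init * config.min_step_scale):
                    break
            elif sweep_start > 0 and \
                    (sweep_start - current) / sweep_start < config.cost_tol:
                break
    return AffineTransform(_params_to_matrix(params, center))


def apply_transform(mask: BinaryMask, xf: AffineTransform, target,
                    interp: str = "nearest") -> BinaryMask:
    """Resample a mask through a world transform onto a target geometry.

    Only nearest-neighbour interpolation is offered so the output stays
    strictly binary.
    """
    if interp != "nearest":
        raise ContractError("masks are resampled with interp='nearest' only")
    if abs(np.linalg.det(xf.matrix[:3, :3])) < 1e-12:
        raise ContractError("singular transform")
    M = np.linalg.inv(mask.affine) @ np.linalg.inv(xf.matrix) @ target.affine
    out = ndimage.affine_transform(
        mask.data.astype(np.float32), M[:3, :3], offset=M[:3, 3],
        output_shape=target.shape, order=0, mode="constant", cval=0.0)
    return BinaryMask(out > 0.5, np.asarray(target.affine).copy())


def align_atlas(atlas: BrainStemAtlas, subject_t1: Volume,
                config: RegistrationConfig = RegistrationConfig()) -> BinaryMask:
    """Warp the atlas brain-stem mask into subject space.

    Registers template -> subject with :func:`register_affine`, then
    resamples the stem mask with nearest-neighbour interpolation.
    """
    xf = register_affine(atlas.template, subject_t1, config)
    warped = apply_transform(atlas.stem_mask, xf, subject_t1)
    if not warped.data.any():
        raise RegistrationError("warped atlas stem mask is empty")
    return warped
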