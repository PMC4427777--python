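"""Synthetic skull-stripped head phantoms with exact ground truth.

The generator emulates the anatomy that makes cerebellar segmentation
hard on real T1 images: a cerebrum occupying the upper head, a
cerebellum below and behind it, a brain stem joined to the cerebellum
through a cerebellar-peduncle bridge, and a venous-sinus slab hugging
the posterior-inferior cerebellar surface, separated from it only by a
thin sheet of CSF.  Sinus intensity is deliberately placed within 10%
of cerebellar gray matter, reproducing the classic false-positive
confound.

Anatomy is built from analytic primitives (ellipsoids, cylinders, a
distance-transform shell) on a 3x-supersampled lattice; per-voxel tissue
fractions and partial-volume-mixed intensities come from block
averaging, and the native label grid is the per-block majority vote.
Ground truth — labels, tissue-fraction maps, the bias field, and the
generating configuration — is therefore exact by construction.

Phantoms are deterministic per (config, seed).  The seed drives only
the bias-field coefficients and the additive Gaussian noise; anatomy
depends only on the geometric/intensity configuration and is cached
across seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from functools import lru_cache
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .errors import ConfigurationError, ContractError
from .preprocess import PVEMaps
from .volume_io import BinaryMask, Volume, read_volume, write_volume

SUPERSAMPLE = 3  # per-axis label supersampling factor for partial-volume mixing


class Label(IntEnum):
    BACKGROUND = 0
    CEREBRUM = 1
    CEREBELLUM_GM = 2
    CEREBELLUM_WM = 3
    BRAINSTEM = 4
    PEDUNCLE = 5
    SINUS = 6
    CSF = 7


#: labels making up the ground-truth cerebellum
CEREBELLUM_LABELS = (Label.CEREBELLUM_GM, Label.CEREBELLUM_WM)
#: labels the brain-stem atlas mask is meant to remove
BRAINSTEM_LABELS = (Label.BRAINSTEM, Label.PEDUNCLE)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and noise settings for one phantom.

    Intensities follow the T1 convention CSF < GM < WM (defaults 40/100/150
    arbitrary units) with the sinus mean at 95, within 10% of gray matter.
    The default is noiseless and bias-free; noise_sigma and bias_amplitude
    switch the confounds on.
    """

    grid_shape: tuple = (128, 128, 128)
    csf_mean: float = 40.0
    gm_mean: float = 100.0
    wm_mean: float = 150.0
    sinus_mean: float = 95.0
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    csf_sheet_thickness: int = 1
    peduncle_radius: float = 5.0
    sinus_thickness: float = 4.0
    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(s) for s in np.atleast_1d(self.grid_shape).repeat(
            3 if np.ndim(self.grid_shape) == 0 else 1)[:3])
        if len(shape) != 3:
            raise ConfigurationError(f"grid_shape must be a triple, got {self.grid_shape}")
        object.__setattr__(self, "grid_shape", shape)
        if min(shape) < 48:
            raise ConfigurationError(
                f"grid too small to place all structures: {shape}, minimum 48 per axis")
        if not (self.csf_mean < self.gm_mean < self.wm_mean):
            raise ConfigurationError(
                "tissue means must satisfy CSF < GM < WM (T1 convention)")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not (0.0 <= self.bias_amplitude <= 0.5):
            raise ConfigurationError("bias_amplitude must lie in [0, 0.5]")
        if self.csf_sheet_thickness < 1:
            raise ConfigurationError("csf_sheet_thickness must be >= 1 voxel")

    def anatomy_key(self) -> tuple:
        """Hashable key of the fields the noise-free anatomy depends on."""
        return (self.grid_shape, self.csf_mean, self.gm_mean, self.wm_mean,
                self.sinus_mean, self.csf_sheet_thickness,
                float(self.peduncle_radius), float(self.sinus_thickness))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


@dataclass
class PhantomCase:
    """A generated phantom: T1 volume plus exact ground truth."""

    t1: Volume
    labels: np.ndarray            # int8 grid of Label values
    pve_truth: PVEMaps
    bias_truth: Volume
    config: PhantomConfig
    applied_pose: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def affine(self) -> np.ndarray:
        return self.t1.affine

    def label_mask(self, *labels: Label) -> BinaryMask:
        return BinaryMask(np.isin(self.labels, labels), self.affine.copy())

    def brain_mask(self) -> BinaryMask:
        """All non-background voxels (the skull-stripped head)."""
        return BinaryMask(self.labels > 0, self.affine.copy())

    def cerebellum_mask(self) -> BinaryMask:
        return self.label_mask(*CEREBELLUM_LABELS)

    def brainstem_mask(self) -> BinaryMask:
        return self.label_mask(*BRAINSTEM_LABELS)

    def sinus_mask(self) -> BinaryMask:
        return self.label_mask(Label.SINUS)

    def cerebral_mask(self, dilate_voxels: int = 1) -> BinaryMask:
        """Cerebrum ground truth, dilated to emulate a cortical-surface mask."""
        from .morphology import dilate, make_ball_se
        mask = self.label_mask(Label.CEREBRUM)
        if dilate_voxels > 0:
            mask = dilate(mask, make_ball_se(dilate_voxels))
        return mask


# ---------------------------------------------------------------------------
# anatomy construction (seed-independent, cached across seeds)
# ---------------------------------------------------------------------------

# structure geometry in fractions of the grid (x = left-right, y =
# posterior->anterior, z = inferior->superior)
_CEREBRUM_CENTER = (0.50, 0.55, 0.62)
_CEREBRUM_SEMI = (0.34, 0.32, 0.26)
_CEREBELLUM_CENTER = (0.50, 0.36, 0.25)
_CEREBELLUM_SEMI = (0.205, 0.150, 0.120)
_CEREBELLUM_WM_SCALE = 0.55          # WM core as scaled copy of the ellipsoid
_BRAINSTEM_XY = (0.50, 0.58)
_BRAINSTEM_RADIUS = 0.0625
_BRAINSTEM_Z = (0.10, 0.52)
_PEDUNCLE_Z = 0.28
_PEDUNCLE_Y = (0.30, 0.60)
_CSF_RIM = 2.0                       # CSF rim thickness around structures, voxels
_SHEET_MARGIN = 1.0                  # extra CSF guard between sheet and sinus, voxels
_SINUS_SECTOR_Y = -0.2               # normalized posterior threshold
_SINUS_SECTOR_Z = 0.35               # normalized superior cut-off


def _ellipsoid_norm2(xx, yy, zz, center, semi):
    return (((xx - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((zz - center[2]) / semi[2]) ** 2)


@lru_cache(maxsize=4)
def _build_anatomy(anatomy_key: tuple):
    """Labels, tissue fractions and ideal (noise-free, bias-free) intensity.

    Everything is computed on a SUPERSAMPLE^3-finer lattice and reduced to
    the native grid: fractions by block averaging, labels by majority vote.
    """
    (shape, csf_mean, gm_mean, wm_mean, sinus_mean,
     sheet_t, ped_radius, sinus_thick) = anatomy_key
    shape = tuple(shape)
    f = SUPERSAMPLE
    hi_shape = tuple(s * f for s in shape)
    n = np.asarray(shape, dtype=float)

    # supersample-voxel centers in native voxel units
    coords = [((np.arange(hs) + 0.5) / f - 0.5).astype(np.float32)
              for hs in hi_shape]
    xx = coords[0][:, None, None]
    yy = coords[1][None, :, None]
    zz = coords[2][None, None, :]

    def scaled(center_frac, semi_frac=None):
        c = np.asarray(center_frac) * (n - 1)
        if semi_frac is None:
            return c
        return c, np.asarray(semi_frac) * n

    hi = np.zeros(hi_shape, dtype=np.int8)

    cb_c, cb_s = scaled(_CEREBELLUM_CENTER, _CEREBELLUM_SEMI)
    cr_c, cr_s = scaled(_CEREBRUM_CENTER, _CEREBRUM_SEMI)

    cerebrum = _ellipsoid_norm2(xx, yy, zz, cr_c, cr_s) <= 1.0
    hi[cerebrum] = Label.CEREBRUM

    cb_norm2 = _ellipsoid_norm2(xx, yy, zz, cb_c, cb_s)
    cerebellum = cb_norm2 <= 1.0
    hi[cerebellum & (hi == 0)] = Label.CEREBELLUM_GM
    core = cb_norm2 <= _CEREBELLUM_WM_SCALE ** 2
    hi[core & (hi == Label.CEREBELLUM_GM)] = Label.CEREBELLUM_WM

    bs_c = (_BRAINSTEM_XY[0] * (n[0] - 1), _BRAINSTEM_XY[1] * (n[1] - 1))
    bs_r = _BRAINSTEM_RADIUS * n[0]
    stem = (((xx - bs_c[0]) ** 2 + (yy - bs_c[1]) ** 2 <= bs_r ** 2)
            & (zz >= _BRAINSTEM_Z[0] * n[2]) & (zz <= _BRAINSTEM_Z[1] * n[2]))
    hi[stem & (hi == 0)] = Label.BRAINSTEM

    ped_c = (0.5 * (n[0] - 1), _PEDUNCLE_Z * (n[2] - 1))
    ped = (((xx - ped_c[0]) ** 2 + (zz - ped_c[1]) ** 2 <= ped_radius ** 2)
           & (yy >= _PEDUNCLE_Y[0] * n[1]) & (yy <= _PEDUNCLE_Y[1] * n[1]))
    hi[ped & (hi == 0)] = Label.PEDUNCLE

    # CSF sheet and venous sinus: shells of the Euclidean distance (in
    # native-voxel units) outside the cerebellum
    d_cb = ndimage.distance_transform_edt(hi != Label.CEREBELLUM_GM,
                                          sampling=1.0).astype(np.float32) / f
    # guard margin keeps majority-voted sinus voxels >= sheet_t voxels away
    sinus_start = sheet_t + _SHEET_MARGIN
    ux = (xx - cb_c[0]) / cb_s[0]
    uy = (yy - cb_c[1]) / cb_s[1]
    uz = (zz - cb_c[2]) / cb_s[2]
    sector = (uy < _SINUS_SECTOR_Y) & (uz < _SINUS_SECTOR_Z)
    sinus = ((d_cb > sinus_start) & (d_cb <= sinus_start + sinus_thick)
             & sector & (hi == 0))
    hi[sinus] = Label.SINUS
    del ux, uy, uz, sector, sinus

    # CSF: the inter-structure sheet plus a rim around every structure
    d_all = ndimage.distance_transform_edt(hi == 0, sampling=1.0
                                           ).astype(np.float32) / f
    csf = (hi == 0) & ((d_all <= _CSF_RIM) | (d_cb <= sinus_start))
    hi[csf] = Label.CSF
    del d_cb, d_all, csf

    # block reduction: per-label subvoxel counts
    n_labels = len(Label)
    counts = np.zeros(shape + (n_labels,), dtype=np.int16)
    view = hi.reshape(shape[0], f, shape[1], f, shape[2], f)
    for lab in range(n_labels):
        counts[..., lab] = (view == lab).sum(axis=(1, 3, 5))
    labels = counts.argmax(axis=-1).astype(np.int8)
    frac = counts.astype(np.float64) / f ** 3

    tissue_mean = np.zeros(n_labels)
    tissue_mean[Label.CEREBRUM] = gm_mean
    tissue_mean[Label.CEREBELLUM_GM] = gm_mean
    tissue_mean[Label.CEREBELLUM_WM] = wm_mean
    tissue_mean[Label.BRAINSTEM] = wm_mean
    tissue_mean[Label.PEDUNCLE] = wm_mean
    tissue_mean[Label.SINUS] = sinus_mean
    tissue_mean[Label.CSF] = csf_mean
    ideal = frac @ tissue_mean

    # tissue-class fractions (sinus blood pools with GM intensity-wise)
    csf_f = frac[..., Label.CSF]
    gm_f = (frac[..., Label.CEREBRUM] + frac[..., Label.CEREBELLUM_GM]
            + frac[..., Label.SINUS])
    wm_f = (frac[..., Label.CEREBELLUM_WM] + frac[..., Label.BRAINSTEM]
            + frac[..., Label.PEDUNCLE])
    brain = labels > 0
    total = csf_f + gm_f + wm_f
    # renormalize to a partition of unity on brain voxels, zero outside
    with np.errstate(invalid="ignore", divide="ignore"):
        for m in (csf_f, gm_f, wm_f):
            np.divide(m, total, out=m, where=total > 0)
    for m in (csf_f, gm_f, wm_f):
        m[~brain] = 0.0
    return labels, csf_f, gm_f, wm_f, ideal


def _default_affine(shape) -> np.ndarray:
    """1 mm isotropic RAS+ grid centered on the world origin."""
    aff = np.eye(4)
    aff[:3, 3] = -(np.asarray(shape, dtype=float) - 1) / 2
    return aff


# ---------------------------------------------------------------------------
# noise and bias
# ---------------------------------------------------------------------------

def _poly_field(shape, coeffs) -> np.ndarray:
    """Order-2 polynomial over coordinates normalized to [-1, 1]."""
    ax = [np.linspace(-1.0, 1.0, s) for s in shape]
    x = ax[0][:, None, None]
    y = ax[1][None, :, None]
    z = ax[2][None, None, :]
    terms = [np.ones(shape), x, y, z, x * y, x * z, y * z,
             x ** 2, y ** 2, z ** 2]
    out = np.zeros(shape)
    for c, t in zip(coeffs, terms):
        out += c * t
    return out


def apply_bias_field(vol: Volume, amplitude: float, seed: int):
    """Multiply by a smooth random polynomial bias field.

    The field has mean exactly 1 over the grid and peak deviation
    |bias - 1| equal to ``amplitude``.  Returns (biased volume, bias field).
    """
    if amplitude < 0 or amplitude > 0.5:
        raise ContractError(f"bias amplitude must lie in [0, 0.5], got {amplitude}")
    ones = np.ones(vol.shape)
    if amplitude == 0:
        return vol.with_data(vol.data.copy()), Volume(ones, vol.affine.copy(), "bias")
    rng = np.random.default_rng(seed)
    coeffs = rng.uniform(-1.0, 1.0, size=10)
    g = _poly_field(vol.shape, coeffs)
    g -= g.mean()
    peak = np.abs(g).max()
    if peak > 0:
        g *= amplitude / peak
    bias = 1.0 + g
    return (vol.with_data(vol.data * bias),
            Volume(bias, vol.affine.copy(), "bias"))


def add_noise(vol: Volume, sigma: float, seed: int) -> Volume:
    """Additive i.i.d. Gaussian noise, deterministic per seed."""
    if sigma < 0:
        raise ContractError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return vol.with_data(vol.data.copy())
    rng = np.random.default_rng(seed)
    return vol.with_data(vol.data + rng.normal(0.0, sigma, size=vol.shape))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate a phantom case; bit-identical for identical configs."""
    labels, csf_f, gm_f, wm_f, ideal = _build_anatomy(config.anatomy_key())
    affine = _default_affine(config.grid_shape)
    t1 = Volume(ideal.copy(), affine.copy(), "intensity")

    child = np.random.SeedSequence(config.seed).generate_state(2) % (2 ** 31)
    t1, bias = apply_bias_field(t1, config.bias_amplitude, int(child[0]))
    t1 = add_noise(t1, config.noise_sigma, int(child[1]))

    pve = PVEMaps(
        csf=Volume(csf_f.copy(), affine.copy(), "fraction"),
        gm=Volume(gm_f.copy(), affine.copy(), "fraction"),
        wm=Volume(wm_f.copy(), affine.copy(), "fraction"))
    return PhantomCase(t1=t1, labels=labels.copy(), pve_truth=pve,
                       bias_truth=bias, config=config)


def perturb_pose(case: PhantomCase, translation=(0, 0, 0), rotation=(0, 0, 0),
                 scale: float = 1.0) -> PhantomCase:
    """Apply a rigid+scale world transform and resample every volume.

    ``rotation`` is per-axis degrees (applied as Rz @ Ry @ Rx about the
    world origin, which sits at the grid center), ``translation`` in mm.
    Labels and fraction maps use nearest-neighbour resampling, intensities
    and the bias field trilinear.  The applied world transform is recorded
    in the returned case.
    """
    translation = np.asarray(translation, dtype=float)
    rotation = np.asarray(rotation, dtype=float)
    if np.any(np.abs(rotation) > 30):
        raise ContractError("rotation limited to 30 degrees per axis")
    if not (0.8 <= scale <= 1.25):
        raise ContractError("scale limited to [0.8, 1.25]")

    rx, ry, rz = np.deg2rad(rotation)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = scale * (Rz @ Ry @ Rx)
    T[:3, 3] = translation

    affine = case.affine
    # output voxel -> world -> inverse pose -> input voxel
    M = np.linalg.inv(affine) @ np.linalg.inv(T) @ affine

    def warp(data, order):
        return ndimage.affine_transform(
            np.asarray(data, dtype=np.float64), M[:3, :3], offset=M[:3, 3],
            output_shape=case.labels.shape, order=order, mode="constant", cval=0.0)

    labels = warp(case.labels, 0).astype(np.int8)
    t1 = case.t1.with_data(warp(case.t1.data, 1))
    bias = case.bias_truth.with_data(np.clip(warp(case.bias_truth.data, 1), 1e-6, None))
    pve = PVEMaps(
        csf=case.pve_truth.csf.with_data(warp(case.pve_truth.csf.data, 0)),
        gm=case.pve_truth.gm.with_data(warp(case.pve_truth.gm.data, 0)),
        wm=case.pve_truth.wm.with_data(warp(case.pve_truth.wm.data, 0)))
    return PhantomCase(t1=t1, labels=labels, pve_truth=pve, bias_truth=bias,
                       config=case.config, applied_pose=T @ case.applied_pose)


def make_atlas(case: PhantomCase, dilate_voxels: int = 2):
    """Build a phantom-derived brain-stem atlas.

    Uses the case's T1 as the template and its brain-stem + peduncle
    ground truth, dilated for cut-out margin, as the stem mask.  Stands in
    for a population-template atlas when working with synthetic data.
    """
    from .morphology import dilate, make_ball_se
    from .registration import BrainStemAtlas
    stem = case.brainstem_mask()
    if dilate_voxels > 0:
        stem = dilate(stem, make_ball_se(dilate_voxels))
    return BrainStemAtlas(template=case.t1.with_data(case.t1.data.copy()),
                          stem_mask=stem)


# ---------------------------------------------------------------------------
# case I/O
# ---------------------------------------------------------------------------

_CASE_FILES = ("t1", "labels", "pve_csf", "pve_gm", "pve_wm", "bias")


def write_case(case: PhantomCase, outdir) -> None:
    """Write a phantom case as NIfTI files plus a YAML config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(case.t1, outdir / "t1.nii.gz")
    labels_img = Volume(case.labels.astype(np.float64), case.affine.copy())
    write_volume(labels_img, outdir / "labels.nii.gz")
    write_volume(case.pve_truth.csf, outdir / "pve_csf.nii.gz")
    write_volume(case.pve_truth.gm, outdir / "pve_gm.nii.gz")
    write_volume(case.pve_truth.wm, outdir / "pve_wm.nii.gz")
    write_volume(case.bias_truth, outdir / "bias.nii.gz")
    sidecar = {"config": case.config.to_dict(),
               "applied_pose": np.asarray(case.applied_pose).tolist()}
    (outdir / "phantom.yaml").write_text(yaml.safe_dump(sidecar))


def load_case(indir) -> PhantomCase:
    indir = Path(indir)
    sidecar = yaml.safe_load((indir / "phantom.yaml").read_text())
    cfg_d = dict(sidecar["config"])
    cfg_d["grid_shape"] = tuple(cfg_d["grid_shape"])
    config = PhantomConfig(**cfg_d)
    t1 = read_volume(indir / "t1.nii.gz")
    labels = read_volume(indir / "labels.nii.gz").data.astype(np.int8)
    pve = PVEMaps(
        csf=read_volume(indir / "pve_csf.nii.gz", "fraction"),
        gm=read_volume(indir / "pve_gm.nii.gz", "fraction"),
        wm=read_volume(indir / "pve_wm.nii.gz", "fraction"))
    bias = read_volume(indir / "bias.nii.gz", "bias")
    return PhantomCase(t1=t1, labels=labels, pve_truth=pve, bias_truth=bias,
                       config=config,
                       applied_pose=np.asarray(sidecar["applied_pose"]))
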