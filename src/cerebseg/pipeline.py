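"""The cerebellum-segmentation algorithm.

Stages, in fixed order:

1. bias-field correction and tissue classification with partial-volume
   estimation on the skull-stripped T1;
2. **candidate A** — subtract the cerebral mask from the brain mask;
3. **CSF-PVE trim** — drop voxels whose CSF fraction exceeds the
   threshold, then erode, severing the thin bridges that attach the
   venous sinuses to the cerebellum;
4. **candidate B** — keep the largest connected component and dilate it
   back to original size with the same kernel;
5. **brain-stem removal** — subtract the affinely aligned atlas mask of
   brain stem + cerebellar peduncle, open to remove masking noise, and
   keep the largest component as the final cerebellum.

Each stage appends its voxel count to a stage log for auditability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError, ContractError, PipelineError
from .morphology import dilate, erode, largest_component, make_ball_se, open_mask
from .preprocess import classify_tissue, correct_inhomogeneity, estimate_pve
from .registration import BrainStemAtlas, RegistrationConfig, align_atlas
from .volume_io import BinaryMask, Volume, require_same_geometry


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters the algorithm's description leaves open."""

    csf_threshold: float = 0.5       # CSF fraction above which a voxel is cut
    trim_se_radius: int = 2          # ball radius for the trim erode/dilate pair
    opening_se_radius: int = 1       # ball radius for the final opening
    connectivity: int = 26           # component adjacency (6/18/26)
    remove_brainstem: bool = True
    poly_order: int = 3              # bias-correction polynomial order
    seed: int = 0                    # tissue-classifier seed

    def __post_init__(self):
        if not (0.0 < self.csf_threshold < 1.0):
            raise ConfigurationError(
                f"csf_threshold must lie strictly inside (0,1), got {self.csf_threshold}")
        if self.trim_se_radius < 1 or self.opening_se_radius < 1:
            raise ConfigurationError("structuring-element radii must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ConfigurationError(
                f"connectivity must be 6, 18 or 26, got {self.connectivity}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SegmentationResult:
    candidate_a: BinaryMask
    candidate_b: BinaryMask
    brainstem_subject: BinaryMask      # empty mask when removal is off
    final: BinaryMask
    config: PipelineConfig
    stage_log: list = field(default_factory=list)


def _log(stage_log, stage: str, mask: BinaryMask, note: str = ""):
    entry = {"stage": stage, "voxels": mask.count()}
    if note:
        entry["note"] = note
    stage_log.append(entry)


def candidate_a(brain_mask: BinaryMask, cerebral_mask: BinaryMask,
                stage_log: list | None = None) -> BinaryMask:
    """Approximate cerebellar region: brain mask minus cerebral mask."""
    require_same_geometry(brain_mask, cerebral_mask, "brain and cerebral masks")
    out = brain_mask & ~cerebral_mask
    if stage_log is not None:
        _log(stage_log, "candidate_a", out,
             "" if out.data.any() else "empty candidate A")
    return out


def trim_with_csf_pve(cand_a: BinaryMask, csf_pve: Volume,
                      config: PipelineConfig = PipelineConfig()) -> BinaryMask:
    """Threshold the CSF fraction map, then erode.

    Removes CSF-dominated voxels (the sheet between sinuses and
    cerebellum) and erodes so the sinus slab detaches from the
    cerebellar body.
    """
    require_same_geometry(cand_a, csf_pve, "candidate A and CSF PVE map")
    if csf_pve.dtype_role != "fraction":
        raise ContractError("csf_pve must be a fraction volume")
    keep = cand_a.with_data(cand_a.data & (csf_pve.data < config.csf_threshold))
    return erode(keep, make_ball_se(config.trim_se_radius))


def candidate_b(trimmed: BinaryMask,
                config: PipelineConfig = PipelineConfig()) -> BinaryMask:
    """Largest component of the trimmed mask, dilated back to size."""
    if not trimmed.data.any():
        raise PipelineError("candidate_b", "trimmed mask is empty")
    keep = largest_component(trimmed, config.connectivity)
    return dilate(keep, make_ball_se(config.trim_se_radius))


def remove_brainstem(cand_b: BinaryMask, stem_subject: BinaryMask,
                     config: PipelineConfig = PipelineConfig()) -> BinaryMask:
    """Mask out the brain stem + peduncle, open, keep the largest component."""
    require_same_geometry(cand_b, stem_subject, "candidate B and stem mask")
    masked = cand_b & ~stem_subject
    if not masked.data.any():
        raise PipelineError("remove_brainstem",
                            "stem mask covers all of candidate B")
    opened = open_mask(masked, make_ball_se(config.opening_se_radius))
    if not opened.data.any():
        raise PipelineError("remove_brainstem", "opening removed every voxel")
    return largest_component(opened, config.connectivity)


def segment_cerebellum(t1: Volume, brain_mask: BinaryMask,
                       cerebral_mask: BinaryMask,
                       atlas: BrainStemAtlas | None,
                       config: PipelineConfig = PipelineConfig(),
                       reg_config: RegistrationConfig = RegistrationConfig()
                       ) -> SegmentationResult:
    """Run the full segmentation on a skull-stripped T1 volume.

    ``atlas`` may be None only when ``config.remove_brainstem`` is off.
    Deterministic for fixed inputs and config.
    """
    require_same_geometry(t1, brain_mask, "T1 and brain mask")
    if config.remove_brainstem and atlas is None:
        raise ContractError("brain-stem removal requested but no atlas given")
    stage_log: list = []

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    corrected, _ = run("correct_inhomogeneity", correct_inhomogeneity,
                       t1, brain_mask, config.poly_order)
    labels = run("classify_tissue", classify_tissue,
                 corrected, brain_mask, config.seed)
    pve = run("estimate_pve", estimate_pve, corrected, labels)
    cand_a = candidate_a(brain_mask, cerebral_mask, stage_log)
    trimmed = run("trim_with_csf_pve", trim_with_csf_pve, cand_a, pve.csf, config)
    _log(stage_log, "trim_with_csf_pve", trimmed)
    cand_b = run("candidate_b", candidate_b, trimmed, config)
    _log(stage_log, "candidate_b", cand_b)

    empty = BinaryMask(np.zeros(t1.shape, dtype=bool), t1.affine.copy())
    if config.remove_brainstem:
        stem_subject = run("align_atlas", align_atlas, atlas, corrected,
                           reg_config)
        _log(stage_log, "align_atlas", stem_subject)
        final = run("remove_brainstem", remove_brainstem,
                    cand_b, stem_subject, config)
        _log(stage_log, "remove_brainstem", final,
             "largest-component pass after opening (extension)")
    else:
        stem_subject = empty
        opened = open_mask(cand_b, make_ball_se(config.opening_se_radius))
        if not opened.data.any():
            raise PipelineError("final_opening", "opening removed every voxel")
        final = largest_component(opened, config.connectivity)
        _log(stage_log, "final_opening", final)

    return SegmentationResult(candidate_a=cand_a, candidate_b=cand_b,
                              brainstem_subject=stem_subject, final=final,
                              config=config, stage_log=stage_log)
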