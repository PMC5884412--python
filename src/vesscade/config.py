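"""Configuration dataclasses and YAML round-trip.

Every tunable of the pipeline lives here with its default, so runs are fully
described by (config, seed). Defaults follow the package's standard study
conditions: 6-scale feature bank from 0.6 mm, 72 rays, cascade targets
d = 0.99, e = 0.3, n_th = 15, E_target = 6e−6, and a three-tree synthetic
experiment at noise variances {20, 40, 60, 80}.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .cascade import CascadeTargets
from .synth import TreeSpec
from .vesselness import FeatureParams


@dataclass(frozen=True)
class SamplingConfig:
    """Cross-section ray sampling parameters.

    The ray step defaults to half the smallest voxel size and the ray length
    to four times the largest feature scale, covering the largest vessels
    with margin; both are overridable. ``gap_tolerance`` is the number of
    consecutive nonvessel-classified samples that terminates the accepted
    run when tracing the boundary along a ray.
    """

    n_rays: int = 72
    step: float | None = None  # mm; None → min(spacing)/2 (training)
    segment_step: float | None = None  # mm; None → min(spacing)/2
    max_len: float | None = None  # mm; None → 4 × largest scale
    gap_tolerance: int = 2
    train_axis_stride: int = 3
    max_pos_samples: int = 15000
    max_neg_samples: int = 30000
    frame_source: str = "hessian"  # "hessian" | "tangent"
    closing: bool = True  # morphological closing of the rasterized mask
    boundary_rule: str = "depth"  # "depth" (crossing of cascade depth) | "run"
    azimuthal_median_window: int = 11  # rays; ≤1 disables
    axial_median_window: int = 7  # sections; ≤1 disables
    calibration_stride: int = 3  # axis stride when fitting radius calibration
    calibration_max_volumes: int = 8

    def resolved_step(self, spacing) -> float:
        return self.step if self.step is not None else min(spacing) / 2.0

    def resolved_segment_step(self, spacing) -> float:
        return (self.segment_step if self.segment_step is not None
                else min(spacing) / 2.0)

    def resolved_max_len(self, sigmas) -> float:
        return self.max_len if self.max_len is not None else 4.0 * max(sigmas)


@dataclass(frozen=True)
class ExperimentConfig:
    """The synthetic noise-robustness experiment.

    ``n_trees`` phantoms are generated; for each noise variance a training
    and a testing noisy realization are drawn; one cascade is trained on the
    pooled training samples and evaluated on every test volume.
    """

    n_trees: int = 3
    tree: TreeSpec = field(default_factory=TreeSpec)
    noise_variances: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0)
    scale_base: float = 0.6
    scale_count: int = 6
    features: FeatureParams = field(default_factory=FeatureParams)
    targets: CascadeTargets = field(default_factory=CascadeTargets)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    svm_enabled: bool = True

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kwargs = dict(raw)
        if "tree" in kwargs and isinstance(kwargs["tree"], dict):
            tree = dict(kwargs["tree"])
            for key in ("shape", "spacing", "bifurcation_angle_deg", "segment_length"):
                if key in tree and isinstance(tree[key], list):
                    tree[key] = tuple(tree[key])
            kwargs["tree"] = TreeSpec(**tree)
        if "features" in kwargs and isinstance(kwargs["features"], dict):
            kwargs["features"] = FeatureParams(**kwargs["features"])
        if "targets" in kwargs and isinstance(kwargs["targets"], dict):
            kwargs["targets"] = CascadeTargets(**kwargs["targets"])
        if "sampling" in kwargs and isinstance(kwargs["sampling"], dict):
            kwargs["sampling"] = SamplingConfig(**kwargs["sampling"])
        if "noise_variances" in kwargs and isinstance(kwargs["noise_variances"], list):
            kwargs["noise_variances"] = tuple(kwargs["noise_variances"])
        return cls(**kwargs)
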