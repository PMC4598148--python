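"""Cohort configuration: probe arms, aortic geometry, and sampling parameters.

A cohort is a set of probe *arms* (one fluorescent probe per arm, several
rabbits per arm).  Each rabbit's abdominal aorta is divided into contiguous
4 mm axial segments measured from the left renal bifurcation; each segment is
either disrupted (mural thrombus present — the gold standard for a high-risk
plaque) or non-disrupted.  The per-arm distribution parameters below drive the
synthetic generator: fluorescence enhancement ratios (FER) for closed-view
imaging, open-view plaque enhancement at disrupted sites, outward remodeling
ratios (RR) and gadolinium enhancement ratios (GdR) for the MRI tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "Probe",
    "TARGETED_PROBES",
    "ArmConfig",
    "CohortConfig",
    "load_config",
    "save_config",
    "config_hash",
]


class Probe(str, Enum):
    """Fluorescent probe injected in an arm.

    MMP_ACPP and THROMBIN_ACPP are protease-activatable probes; PEG_ACPP is
    the non-cleavable control with no expected disrupted/non-disrupted
    contrast.
    """

    MMP_ACPP = "MMP_ACPP"
    THROMBIN_ACPP = "THROMBIN_ACPP"
    PEG_ACPP = "PEG_ACPP"


#: Arms whose segments participate in the disrupted-segment draw in replica
#: mode (the control probe arm is imaged but not part of the pooled counts).
TARGETED_PROBES = frozenset({Probe.MMP_ACPP, Probe.THROMBIN_ACPP})

MeanSd = tuple[float, float]


def _check_mean_sd(name: str, value: MeanSd) -> MeanSd:
    mean, sd = float(value[0]), float(value[1])
    if mean <= 0:
        raise ValueError(f"{name}: mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"{name}: SD must be >= 0, got {sd}")
    return (mean, sd)


@dataclass
class ArmConfig:
    """One probe arm: rabbit count, segment layout and signal distributions.

    FER/RR/GdR values are sampled from normal distributions truncated to be
    positive, with the (mean, sd) pairs given here.
    """

    probe: Probe
    n_rabbits: int
    segments_per_rabbit: int = 17
    fer_disrupted: MeanSd = (4.5, 1.0)
    fer_nondisrupted: MeanSd = (2.2, 1.0)
    fer_openview_plaque: MeanSd = (4.0, 1.1)
    thrombus_to_plaque_signal_ratio: float = 0.5
    rr_disrupted: MeanSd = (1.08, 0.12)
    rr_nondisrupted: MeanSd = (1.00, 0.08)
    gdr_disrupted: MeanSd = (1.3, 0.25)
    gdr_nondisrupted: MeanSd = (1.3, 0.25)

    def __post_init__(self) -> None:
        self.probe = Probe(self.probe)
        if self.n_rabbits < 1:
            raise ValueError("n_rabbits must be >= 1")
        if self.segments_per_rabbit < 1:
            raise ValueError("segments_per_rabbit must be >= 1")
        if not 0.0 < self.thrombus_to_plaque_signal_ratio < 1.0:
            raise ValueError(
                "thrombus_to_plaque_signal_ratio must lie in (0, 1), got "
                f"{self.thrombus_to_plaque_signal_ratio}"
            )
        for name in (
            "fer_disrupted",
            "fer_nondisrupted",
            "fer_openview_plaque",
            "rr_disrupted",
            "rr_nondisrupted",
            "gdr_disrupted",
            "gdr_nondisrupted",
        ):
            setattr(self, name, _check_mean_sd(name, getattr(self, name)))


@dataclass
class CohortConfig:
    """Whole-cohort configuration.

    Two disruption-assignment modes exist:

    * replica mode (``replica_mode=True``): exactly ``n_disrupted`` segments
      are drawn uniformly at random among all targeted-arm segments, and
      ``total_segments`` (if set) trims the last rabbit so the cohort totals
      match a prescribed design;
    * probability mode: every segment is independently disrupted with
      probability ``disruption_probability``.
    """

    arms: list[ArmConfig]
    axial_segment_length_mm: float = 4.0
    mri_slice_pitch_mm: float = 4.0  # 3 mm slice + 1 mm gap
    seed: int = 0
    replica_mode: bool = False
    n_disrupted: Optional[int] = None
    total_segments: Optional[int] = None
    disruption_probability: Optional[float] = None

    def __post_init__(self) -> None:
        self.arms = [
            arm if isinstance(arm, ArmConfig) else ArmConfig(**arm) for arm in self.arms
        ]
        if not self.arms:
            raise ValueError("at least one arm is required")
        if self.axial_segment_length_mm <= 0:
            raise ValueError("axial_segment_length_mm must be > 0")
        if self.mri_slice_pitch_mm <= 0:
            raise ValueError("mri_slice_pitch_mm must be > 0")
        if self.replica_mode:
            if self.n_disrupted is None:
                raise ValueError("replica mode requires n_disrupted")
            if self.n_disrupted < 0:
                raise ValueError("n_disrupted must be >= 0")
            capacity = self.targeted_segment_capacity()
            if self.n_disrupted > capacity:
                raise ValueError(
                    f"replica mode infeasible: n_disrupted={self.n_disrupted} exceeds "
                    f"the {capacity} targeted-arm segments"
                )
        else:
            p = self.disruption_probability
            if p is None:
                raise ValueError("probability mode requires disruption_probability")
            if not 0.0 <= p <= 1.0:
                raise ValueError("disruption_probability must lie in [0, 1]")
        if self.total_segments is not None:
            if not self.replica_mode:
                raise ValueError("total_segments is only meaningful in replica mode")
            nominal = sum(a.n_rabbits * a.segments_per_rabbit for a in self.arms)
            if not 0 < self.total_segments <= nominal:
                raise ValueError(
                    f"total_segments={self.total_segments} must lie in (0, {nominal}]"
                )
            n_rabbits = sum(a.n_rabbits for a in self.arms)
            if nominal - self.total_segments >= self.arms[-1].segments_per_rabbit:
                raise ValueError(
                    "total_segments requires trimming more than the last rabbit; "
                    f"need >= {nominal - self.arms[-1].segments_per_rabbit + 1}, "
                    f"got {self.total_segments} (rabbits: {n_rabbits})"
                )

    def targeted_segment_capacity(self) -> int:
        """Number of segments in targeted (non-control) arms after trimming."""
        nominal = sum(
            a.n_rabbits * a.segments_per_rabbit
            for a in self.arms
            if a.probe in TARGETED_PROBES
        )
        if self.total_segments is not None and self.arms[-1].probe in TARGETED_PROBES:
            total_nominal = sum(a.n_rabbits * a.segments_per_rabbit for a in self.arms)
            nominal -= total_nominal - self.total_segments
        return nominal

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        for arm in d["arms"]:
            arm["probe"] = str(Probe(arm["probe"]).value)
            for key, val in list(arm.items()):
                if isinstance(val, tuple):
                    arm[key] = list(val)
        return d


def load_config(path: str | Path) -> CohortConfig:
    """Read a cohort configuration from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "arms" not in raw:
        raise ValueError(f"{path}: not a cohort configuration (missing 'arms')")
    return CohortConfig(**raw)


def save_config(config: CohortConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: CohortConfig) -> str:
    """Stable hash of the configuration, for report provenance."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
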