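"""NMJ innervation / degeneration scoring rules.

Each NMJ receives two independent labels:

* **pre-synaptic** state — ``completely_denervated`` if more than 90% of
  the post-synaptic apparatus is devoid of nerve-terminal signal;
  otherwise ``partially_innervated`` if any AChR-enriched branch carries
  a contiguous uncovered stretch longer than 5 μm; otherwise
  ``innervated`` (the "vast majority covered" case is the complement of
  the two degeneration rules, which makes the three labels exhaustive
  and mutually exclusive).
* **post-synaptic** state — ``degenerated`` if the endplate is a patch
  without elaborate branches (fewer than ``min_elaborate_branches``
  branches longer than 5 μm), else ``intact``.

Post-synaptic **myonuclei** are nuclei whose volume overlaps the
(dilated) post-synaptic apparatus by strictly more than 25%.

All comparisons are strict (``>``), matching the rule statements; the
evaluation order for the pre-synaptic label is fixed with complete
denervation tested first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

from .morphometry import (
    CoverageProfile,
    MorphometryConfig,
    NMJGeometry,
    compute_coverage,
    nucleus_overlap_fractions,
    quantify_geometry,
    segment_channels,
)
from .stack import ConfocalStack

__all__ = [
    "PRE_CLASSES",
    "POST_CLASSES",
    "MYONUCLEAR_BINS",
    "ClassificationThresholds",
    "NMJRecord",
    "classify_presynaptic",
    "classify_postsynaptic",
    "count_myonuclei",
    "bin_myonuclear_counts",
    "score_stack",
]

PRE_CLASSES = ("innervated", "partially_innervated", "completely_denervated")
POST_CLASSES = ("intact", "degenerated")
MYONUCLEAR_BINS = ("0-2", "3-4", ">4")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Decision thresholds, all applied as strict inequalities."""

    branch_gap_um: float = 5.0
    denervated_devoid_fraction: float = 0.90
    postsyn_branch_min_um: float = 5.0
    nucleus_overlap_fraction: float = 0.25
    min_elaborate_branches: int = 2

    def __post_init__(self) -> None:
        if self.branch_gap_um <= 0 or self.postsyn_branch_min_um <= 0:
            raise ValueError("length thresholds must be positive")
        if not 0 < self.denervated_devoid_fraction < 1:
            raise ValueError("denervated_devoid_fraction must be in (0, 1)")
        if not 0 < self.nucleus_overlap_fraction < 1:
            raise ValueError("nucleus_overlap_fraction must be in (0, 1)")
        if self.min_elaborate_branches < 1:
            raise ValueError("min_elaborate_branches must be >= 1")

    @classmethod
    def from_config(cls, cfg: Mapping | None) -> "ClassificationThresholds":
        """Build from a (possibly partial) ``thresholds`` config mapping."""
        cfg = cfg or {}
        known = {f.name for f in fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**{k: cfg[k] for k in cfg})


@dataclass
class NMJRecord:
    """One scored NMJ: measurements, labels, and group metadata."""

    id: str
    pre_class: str
    post_class: str
    myonuclear_count: int
    volume_um3: float
    cumulative_intensity: float
    devoid_fraction: float
    max_uncovered_um: float
    n_branches_ge_5um: int
    nmj_found: bool = True
    mouse: str = ""
    genotype: str = ""
    age: str = ""
    muscle: str = ""


def classify_presynaptic(
    cov: CoverageProfile, th: ClassificationThresholds | None = None
) -> str:
    """Innervation label from the coverage profile (denervation tested first)."""
    th = th or ClassificationThresholds()
    if cov.devoid_fraction > th.denervated_devoid_fraction:
        return "completely_denervated"
    if any(run > th.branch_gap_um for _, run in cov.per_branch_uncovered):
        return "partially_innervated"
    return "innervated"


def classify_postsynaptic(
    geom: NMJGeometry, th: ClassificationThresholds | None = None
) -> str:
    """Post-synaptic label: a patch without elaborate branches is degenerated."""
    th = th or ClassificationThresholds()
    if geom.n_branches_ge_5um < th.min_elaborate_branches:
        return "degenerated"
    return "intact"


def count_myonuclei(
    overlaps: Iterable[float] | Iterable[tuple[int, float]],
    th: ClassificationThresholds | None = None,
) -> int:
    """Count nuclei whose overlap fraction strictly exceeds the threshold.

    Accepts plain fractions or ``(nucleus id, fraction)`` pairs.
    """
    th = th or ClassificationThresholds()
    count = 0
    for item in overlaps:
        frac = item[1] if isinstance(item, tuple) else float(item)
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"overlap fraction {frac} outside [0, 1]")
        if frac > th.nucleus_overlap_fraction:
            count += 1
    return count


def bin_myonuclear_counts(counts: Sequence[int]) -> dict:
    """Bin per-NMJ myonuclear counts into the cluster-size classes 0–2 / 3–4 / >4.

    Returns ``{"0-2": p, "3-4": p, ">4": p, "n": n, "defined": bool}``;
    an empty input yields all-zero proportions with ``defined=False``.
    """
    counts = list(counts)
    if any(c < 0 for c in counts):
        raise ValueError("myonuclear counts must be non-negative")
    n = len(counts)
    if n == 0:
        return {"0-2": 0.0, "3-4": 0.0, ">4": 0.0, "n": 0, "defined": False}
    b02 = sum(1 for c in counts if c <= 2)
    b34 = sum(1 for c in counts if 3 <= c <= 4)
    b4p = sum(1 for c in counts if c > 4)
    return {"0-2": b02 / n, "3-4": b34 / n, ">4": b4p / n, "n": n, "defined": True}


def score_stack(
    stack: ConfocalStack,
    thresholds: ClassificationThresholds | None = None,
    cfg: MorphometryConfig | None = None,
    record_id: str = "nmj",
    **metadata: str,
) -> NMJRecord:
    """Full pipeline: segment, measure, classify one stack into an NMJRecord."""
    th = thresholds or ClassificationThresholds()
    cfg = cfg or MorphometryConfig()
    seg = segment_channels(stack, cfg)
    if not seg.nmj_found:
        return NMJRecord(
            id=record_id, pre_class="completely_denervated", post_class="degenerated",
            myonuclear_count=0, volume_um3=0.0, cumulative_intensity=0.0,
            devoid_fraction=1.0, max_uncovered_um=0.0, n_branches_ge_5um=0,
            nmj_found=False, **metadata,
        )
    cov = compute_coverage(seg, reach_radius=cfg.reach_radius_um)
    geom = quantify_geometry(seg, stack, cfg, elaborate_branch_min_um=th.postsyn_branch_min_um)
    overlaps = nucleus_overlap_fractions(seg, cfg)
    return NMJRecord(
        id=record_id,
        pre_class=classify_presynaptic(cov, th),
        post_class=classify_postsynaptic(geom, th),
        myonuclear_count=count_myonuclei(overlaps, th),
        volume_um3=geom.volume_um3,
        cumulative_intensity=geom.cumulative_intensity,
        devoid_fraction=cov.devoid_fraction,
        max_uncovered_um=cov.max_uncovered_um,
        n_branches_ge_5um=geom.n_branches_ge_5um,
        nmj_found=True,
        **metadata,
    )
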