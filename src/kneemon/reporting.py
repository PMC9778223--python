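"""Subject summaries, group aggregation and rehabilitation-progress reports.

A subject's summary is the mean of their session averages (ROM in degrees,
MAV/RMS per channel in volts); groups aggregate subjects by arithmetic
mean.  Progress between two weeks is reported as field-wise deltas with a
three-way direction call (improved / unchanged / declined), where
"unchanged" uses a small dead band — +/-0.1 deg for angles, +/-0.001 V for
EMG features — so that sub-resolution wiggles are not reported as change.

The package bundles a reference cohort of per-subject averages from a
knee-extension monitoring study (six healthy adults tested once with a
1 kg ankle load; six rehabilitation patients — three with bone/joint
problems, three with neurodegenerative/brain problems — tested in the
first and last week of a month of therapy).  ``load_reference_cohort``
returns it; the group aggregates computed from it reproduce the study's
published group tables.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as _dc_fields

import numpy as np

from .errors import ConfigurationError
from .session import SessionResult

__all__ = [
    "SubjectSummary",
    "GroupSummary",
    "ProgressReport",
    "FieldDelta",
    "summarize_subject",
    "aggregate_group",
    "progress_report",
    "GROUP_LABELS",
    "WEEK_LABELS",
]

GROUP_LABELS = ("healthy", "bone_joint", "neuro")
WEEK_LABELS = ("first", "middle", "last", "single")

_FEATURE_FIELDS = ("avg_rom_deg", "mav_vl_v", "mav_vm_v", "rms_vl_v", "rms_vm_v")
# dead band half-widths for the progress direction call
_UNCHANGED_BAND = {"avg_rom_deg": 0.1, "mean_rom_deg": 0.1}
_DEFAULT_BAND_V = 0.001


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject average ROM and EMG features across their sessions."""

    subject_id: str
    group_label: str
    week_label: str
    avg_rom_deg: float
    mav_vl_v: float
    mav_vm_v: float
    rms_vl_v: float
    rms_vm_v: float

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ConfigurationError(
                f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}"
            )
        if self.week_label not in WEEK_LABELS:
            raise ConfigurationError(
                f"week_label must be one of {WEEK_LABELS}, got {self.week_label!r}"
            )
        for name in _FEATURE_FIELDS:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GroupSummary:
    """Arithmetic group means of the member subject summaries."""

    group_label: str
    week_label: str
    n_subjects: int
    mean_rom_deg: float
    mean_mav_vl_v: float
    mean_mav_vm_v: float
    mean_rms_vl_v: float
    mean_rms_vm_v: float


@dataclass(frozen=True)
class FieldDelta:
    field: str
    first: float
    last: float
    delta: float
    direction: str  # improved | unchanged | declined


@dataclass(frozen=True)
class ProgressReport:
    entity: str  # subject_id or group_label
    first_week: str
    last_week: str
    deltas: tuple[FieldDelta, ...]

    def as_dict(self) -> dict[str, FieldDelta]:
        return {d.field: d for d in self.deltas}


def summarize_subject(
    results: list[SessionResult],
    subject_id: str,
    group_label: str = "healthy",
    week_label: str = "single",
) -> SubjectSummary:
    """Mean of the supplied sessions' averages; needs >=1 completed session."""
    done = [r for r in results if r.completed]
    if not done:
        raise ConfigurationError(
            f"subject {subject_id!r}: no completed session to summarize"
        )
    return SubjectSummary(
        subject_id=subject_id,
        group_label=group_label,
        week_label=week_label,
        avg_rom_deg=float(np.mean([r.averages.avg_rom_deg for r in done])),
        mav_vl_v=float(np.mean([r.averages.avg_mav_vl_v for r in done])),
        mav_vm_v=float(np.mean([r.averages.avg_mav_vm_v for r in done])),
        rms_vl_v=float(np.mean([r.averages.avg_rms_vl_v for r in done])),
        rms_vm_v=float(np.mean([r.averages.avg_rms_vm_v for r in done])),
    )


def aggregate_group(summaries: list[SubjectSummary]) -> GroupSummary:
    """Field-wise arithmetic means over a homogeneous group/week."""
    if not summaries:
        raise ConfigurationError("cannot aggregate an empty group")
    groups = {s.group_label for s in summaries}
    weeks = {s.week_label for s in summaries}
    if len(groups) > 1 or len(weeks) > 1:
        raise ConfigurationError(
            f"mixed labels in group aggregation: groups={sorted(groups)}, weeks={sorted(weeks)}"
        )
    # fixed summation order makes the means permutation-invariant bit-for-bit
    summaries = sorted(summaries, key=lambda s: s.subject_id)
    return GroupSummary(
        group_label=summaries[0].group_label,
        week_label=summaries[0].week_label,
        n_subjects=len(summaries),
        mean_rom_deg=float(np.mean([s.avg_rom_deg for s in summaries])),
        mean_mav_vl_v=float(np.mean([s.mav_vl_v for s in summaries])),
        mean_mav_vm_v=float(np.mean([s.mav_vm_v for s in summaries])),
        mean_rms_vl_v=float(np.mean([s.rms_vl_v for s in summaries])),
        mean_rms_vm_v=float(np.mean([s.rms_vm_v for s in summaries])),
    )


def _numeric_fields(obj) -> list[str]:
    skip = {"n_subjects"}
    return [
        f.name
        for f in _dc_fields(obj)
        if f.name not in skip and isinstance(getattr(obj, f.name), float)
    ]


def progress_report(first, last) -> ProgressReport:
    """Field-wise change between two weeks of the same subject or group."""
    if type(first) is not type(last):
        raise ConfigurationError(
            f"cannot compare a {type(first).__name__} with a {type(last).__name__}"
        )
    if isinstance(first, SubjectSummary):
        if first.subject_id != last.subject_id:
            raise ConfigurationError(
                f"mismatched subjects: {first.subject_id!r} vs {last.subject_id!r}"
            )
        entity = first.subject_id
    elif isinstance(first, GroupSummary):
        if first.group_label != last.group_label:
            raise ConfigurationError(
                f"mismatched groups: {first.group_label!r} vs {last.group_label!r}"
            )
        entity = first.group_label
    else:
        raise ConfigurationError(
            f"progress_report expects SubjectSummary or GroupSummary, got {type(first).__name__}"
        )
    if first.week_label == last.week_label:
        raise ConfigurationError("progress requires two different weeks")

    deltas = []
    for name in _numeric_fields(first):
        a, b = getattr(first, name), getattr(last, name)
        d = b - a
        band = _UNCHANGED_BAND.get(name, _DEFAULT_BAND_V)
        if abs(d) <= band + 1e-12:
            direction = "unchanged"
        elif d > 0:
            direction = "improved"
        else:
            direction = "declined"
        deltas.append(FieldDelta(field=name, first=a, last=b, delta=d, direction=direction))
    return ProgressReport(
        entity=entity,
        first_week=first.week_label,
        last_week=last.week_label,
        deltas=tuple(deltas),
    )
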