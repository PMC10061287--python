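"""Somatic copy-number alteration (SCNA) event classification and burden
scoring.

Per-allele states: copy 0 = deletion, copy 1 = normal, copy >= 2 =
amplification. Each segment receives an integer score S:

* +2 when one allele is amplified and the other deleted,
* +1 when both alleles are altered in the same direction,
* +1 when exactly one allele is altered,
*  0 when both alleles are normal.

Events are classified per sample: an *arm* event requires the cumulative
length of same-sign alterations to exceed 50% of the arm; a *chromosome*
event requires every modeled arm of the chromosome to pass the arm rule
with the same sign (on chromosomes modeled with a single arm the arm rule
alone suffices); remaining altered segments are *focal*. Every altered
segment belongs to exactly one scope. ChromL / ArmL / FocalL are sums of S
within each scope, z-normalised across the cohort; the total normalised
SCNA level divides the summed S of all segments by the total segment
length.

Input segmentation must be split at arm boundaries: a segment that is not
fully contained in one modeled arm is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import ArmModel, SegmentRecord

AMP = "amplification"
DEL = "deletion"


@dataclass
class ScnaEvent:
    sample_id: str
    scope: str  # chromosome | arm | focal
    chrom: str
    arm: Optional[str]  # None for chromosome scope
    sign: str  # amplification | deletion
    segment_indices: List[int] = field(default_factory=list)
    ccf: Optional[float] = None
    clonality: str = "unknown"

    @property
    def feature(self) -> str:
        loc = self.chrom if self.arm is None else f"{self.chrom}{self.arm}"
        return f"{'amp' if self.sign == AMP else 'del'}({loc})"


def segment_score(major: int, minor: int) -> int:
    """Integer burden score S of one segment's allelic copy state."""
    if minor < 0 or major < minor:
        raise ValueError(f"require major >= minor >= 0, got ({major},{minor})")

    def state(copies: int) -> int:
        return 0 if copies == 1 else (1 if copies >= 2 else -1)

    s_major, s_minor = state(major), state(minor)
    if s_major == 0 and s_minor == 0:
        return 0
    if s_major * s_minor == -1:  # one amplified, one deleted
        return 2
    return 1


def _segment_signs(seg: SegmentRecord) -> List[str]:
    signs = []
    if seg.major >= 2:
        signs.append(AMP)
    if seg.minor == 0:
        signs.append(DEL)
    return signs


def _locate_arm(seg: SegmentRecord, arms: ArmModel) -> Tuple[str, str]:
    if seg.chrom not in arms.arms:
        raise ValueError(f"segment chromosome {seg.chrom} absent from arm model")
    for arm, (s, e) in arms.arms[seg.chrom].items():
        if s <= seg.start and seg.end <= e:
            return seg.chrom, arm
    raise ValueError(
        f"segment {seg.chrom}:{seg.start}-{seg.end} extends beyond the arm model"
    )


def classify_segments(
    segments: Sequence[SegmentRecord],
    arms: ArmModel,
    segment_ccfs: Optional[Sequence[float]] = None,
    clonal_ccf: float = 0.95,
) -> Tuple[List[ScnaEvent], List[Optional[str]]]:
    """Classify one sample's segments into chromosome/arm/focal events.

    Returns ``(events, scopes)`` where ``scopes[i]`` is the scope of segment
    i ("chromosome" / "arm" / "focal") or None if the segment is unaltered.
    When per-segment CCFs are given, each event carries the length-weighted
    mean CCF of its member segments and a clonal/subclonal call at the
    ``clonal_ccf`` threshold.
    """
    if not segments:
        return [], []
    sample_id = segments[0].sample_id
    if any(s.sample_id != sample_id for s in segments):
        raise ValueError("classify_segments expects segments of a single sample")

    located = [_locate_arm(seg, arms) for seg in segments]
    altered_len: Dict[Tuple[str, str, str], int] = {}
    members: Dict[Tuple[str, str, str], List[int]] = {}
    for i, seg in enumerate(segments):
        chrom, arm = located[i]
        for sign in _segment_signs(seg):
            key = (chrom, arm, sign)
            altered_len[key] = altered_len.get(key, 0) + seg.length
            members.setdefault(key, []).append(i)

    arm_pass = {
        key
        for key, ln in altered_len.items()
        if ln > 0.5 * arms.arm_length(key[0], key[1])
    }
    chrom_events: Dict[Tuple[str, str], List[str]] = {}
    for chrom in arms.arms:
        for sign in (AMP, DEL):
            names = arms.arm_names(chrom)
            if names and all((chrom, arm, sign) in arm_pass for arm in names):
                chrom_events[(chrom, sign)] = names

    def event_ccf(idx: List[int]) -> Tuple[Optional[float], str]:
        if segment_ccfs is None:
            return None, "unknown"
        lens = np.array([segments[i].length for i in idx], dtype=float)
        ccfs = np.array([segment_ccfs[i] for i in idx], dtype=float)
        ccf = float((lens * ccfs).sum() / lens.sum())
        return ccf, ("clonal" if ccf >= clonal_ccf else "subclonal")

    events: List[ScnaEvent] = []
    for (chrom, sign), arm_names in sorted(chrom_events.items()):
        idx = sorted({i for arm in arm_names for i in members[(chrom, arm, sign)]})
        ccf, clon = event_ccf(idx)
        events.append(
            ScnaEvent(sample_id, "chromosome", chrom, None, sign, idx, ccf, clon)
        )
    for (chrom, arm, sign) in sorted(arm_pass):
        if (chrom, sign) in chrom_events:
            continue  # subsumed into the chromosome event
        idx = sorted(members[(chrom, arm, sign)])
        ccf, clon = event_ccf(idx)
        events.append(ScnaEvent(sample_id, "arm", chrom, arm, sign, idx, ccf, clon))

    # scope partition: chromosome > arm > focal, matching sign required
    scopes: List[Optional[str]] = [None] * len(segments)
    for i, seg in enumerate(segments):
        signs = _segment_signs(seg)
        if not signs:
            continue
        chrom, arm = located[i]
        if any((chrom, sign) in chrom_events for sign in signs):
            scopes[i] = "chromosome"
        elif any(
            (chrom, arm, sign) in arm_pass and (chrom, sign) not in chrom_events
            for sign in signs
        ):
            scopes[i] = "arm"
        else:
            scopes[i] = "focal"
    for i, scope in enumerate(scopes):
        if scope == "focal":
            seg = segments[i]
            chrom, arm = located[i]
            for sign in _segment_signs(seg):
                ccf, clon = event_ccf([i])
                events.append(
                    ScnaEvent(sample_id, "focal", chrom, arm, sign, [i], ccf, clon)
                )
    return events, scopes


def coalesce_segments(
    segments: Sequence[SegmentRecord], arms: ArmModel
) -> List[SegmentRecord]:
    """Merge contiguous segments with identical (major, minor) within one
    arm. Scoring operates on these maximal runs, so splitting a segment into
    identical-copy pieces never changes any burden score."""
    by_arm: Dict[Tuple[str, str, str], List[SegmentRecord]] = {}
    for seg in segments:
        chrom, arm = _locate_arm(seg, arms)
        by_arm.setdefault((seg.sample_id, chrom, arm), []).append(seg)
    out: List[SegmentRecord] = []
    for key in sorted(by_arm):
        run: Optional[SegmentRecord] = None
        for seg in sorted(by_arm[key], key=lambda s: s.start):
            if (
                run is not None
                and seg.start == run.end + 1
                and (seg.major, seg.minor) == (run.major, run.minor)
            ):
                run = SegmentRecord(
                    run.sample_id, run.chrom, run.start, seg.end, run.major, run.minor
                )
            else:
                if run is not None:
                    out.append(run)
                run = seg
        if run is not None:
            out.append(run)
    return out


def score_levels(
    segments_by_sample: Mapping[str, Sequence[SegmentRecord]],
    arms: ArmModel,
) -> pd.DataFrame:
    """Per-sample SCNA burden scores with cohort z-normalisation.

    Returns a DataFrame indexed by sample with columns ChromL, ArmL, FocalL,
    z_ChromL, z_ArmL, z_FocalL, total_normalized.
    """
    if len(segments_by_sample) < 2:
        raise ValueError("cohort z-normalisation needs at least two samples")
    rows = {}
    for sample, segs in segments_by_sample.items():
        segs = coalesce_segments(list(segs), arms)
        _, scopes = classify_segments(segs, arms)
        sums = {"chromosome": 0, "arm": 0, "focal": 0}
        total_s = 0
        total_len = 0
        for seg, scope in zip(segs, scopes):
            s = segment_score(seg.major, seg.minor)
            total_s += s
            total_len += seg.length
            if scope is not None:
                sums[scope] += s
        rows[sample] = (
            sums["chromosome"],
            sums["arm"],
            sums["focal"],
            total_s / total_len if total_len else 0.0,
        )
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["ChromL", "ArmL", "FocalL", "total_normalized"]
    ).sort_index()
    for col in ("ChromL", "ArmL", "FocalL"):
        sd = df[col].std(ddof=0)
        df[f"z_{col}"] = (df[col] - df[col].mean()) / sd if sd > 0 else 0.0
    return df


def frequent_arm_events(
    events_by_sample: Mapping[str, Sequence[ScnaEvent]],
    min_freq: float = 0.30,
    arms: Optional[ArmModel] = None,
) -> pd.DataFrame:
    """Arm-level (chrom, arm, sign) features altered in at least ``min_freq``
    of samples. Chromosome-scope events count as carriers of each modeled
    arm of the chromosome."""
    n = len(events_by_sample)
    carriers: Dict[Tuple[str, str, str], set] = {}
    for sample, events in events_by_sample.items():
        for ev in events:
            if ev.scope == "arm":
                carriers.setdefault((ev.chrom, ev.arm, ev.sign), set()).add(sample)
            elif ev.scope == "chromosome":
                arm_names = arms.arm_names(ev.chrom) if arms else ("p", "q")
                for arm in arm_names:
                    carriers.setdefault((ev.chrom, arm, ev.sign), set()).add(sample)
    rows = [
        (chrom, arm, sign, len(samps), len(samps) / n)
        for (chrom, arm, sign), samps in sorted(carriers.items())
        if len(samps) / n >= min_freq
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "arm", "sign", "n_carriers", "frequency"]
    )
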