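"""Core record types for somatic mutation / copy-number / clinical data.

Coordinates are 1-based inclusive throughout (both mutation positions and
segment intervals). Copy-number segments carry integer allelic copies with
``major >= minor``. All invariants are enforced at construction time so that
downstream code can assume well-formed records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

VARIANT_CLASSES = ("silent", "nonsilent_snv", "indel")
RACES = ("Asian", "Black", "White", "unknown")
INVASIVENESS = ("NMIBC", "MIBC")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class RecordError(ValueError):
    """A record violates one of its invariants."""


class FormatError(ValueError):
    """A table is missing a declared column or is otherwise malformed."""


def revcomp(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:  # pragma: no cover - defensive
        raise RecordError(f"non-ACGT base in sequence {seq!r}") from exc


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV or indel with read support and trinucleotide context.

    ``context3`` is the 3-mer reference context centred on the position and is
    required for SNVs (its middle base must equal ``ref``); it is ignored for
    indels.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: str
    alt_count: int
    depth: int
    context3: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise RecordError(
                f"variant_class {self.variant_class!r} not one of {VARIANT_CLASSES}"
            )
        if self.pos < 1:
            raise RecordError(f"pos must be >= 1, got {self.pos}")
        if self.alt_count < 0 or self.depth < 0:
            raise RecordError("read counts must be non-negative")
        if self.alt_count > self.depth:
            raise RecordError(
                f"alt_count {self.alt_count} exceeds depth {self.depth}"
            )
        is_snv_alleles = len(self.ref) == 1 == len(self.alt) and self.ref != self.alt
        if self.variant_class in ("silent", "nonsilent_snv"):
            if not is_snv_alleles:
                raise RecordError(
                    f"SNV requires single differing bases, got {self.ref}>{self.alt}"
                )
            if self.context3 is not None:
                if len(self.context3) != 3:
                    raise RecordError(f"context3 must be a 3-mer, got {self.context3!r}")
                if self.context3[1] != self.ref:
                    raise RecordError(
                        f"context3 middle base {self.context3[1]!r} != ref {self.ref!r}"
                    )
        elif is_snv_alleles:
            raise RecordError("indel record has SNV-style alleles")

    @property
    def is_snv(self) -> bool:
        return self.variant_class in ("silent", "nonsilent_snv")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class SegmentRecord:
    """One allelic copy-number segment (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    major: int
    minor: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise RecordError(f"segment end {self.end} < start {self.start}")
        if self.minor < 0 or self.major < self.minor:
            raise RecordError(
                f"require major >= minor >= 0, got ({self.major},{self.minor})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    race: str
    stage: str
    invasiveness: str
    purity: float
    followup_months: float
    metastasis_time_months: Optional[float] = None

    def __post_init__(self) -> None:
        if self.race not in RACES:
            raise RecordError(f"race {self.race!r} not one of {RACES}")
        if self.invasiveness not in INVASIVENESS:
            raise RecordError(
                f"invasiveness {self.invasiveness!r} not one of {INVASIVENESS}"
            )
        if not (0.0 < self.purity <= 1.0):
            raise RecordError(f"purity must be in (0,1], got {self.purity}")
        if self.followup_months < 0:
            raise RecordError("followup_months must be non-negative")
        if self.metastasis_time_months is not None and self.metastasis_time_months < 0:
            raise RecordError("metastasis_time_months must be non-negative")


@dataclass
class ArmModel:
    """Chromosome-arm intervals: per chromosome, named arms with 1-based spans.

    ``arms[chrom]`` maps arm name ("p"/"q") to a ``(start, end)`` interval.
    Acrocentric chromosomes may carry only a q arm.
    """

    arms: Dict[str, Dict[str, Tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arm_map in self.arms.items():
            spans = sorted(arm_map.values())
            for (s, e) in spans:
                if e < s:
                    raise RecordError(f"arm on {chrom} has end < start")
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise RecordError(f"arms of {chrom} overlap")

    def chromosomes(self) -> List[str]:
        return list(self.arms)

    def arm_names(self, chrom: str) -> List[str]:
        return list(self.arms[chrom])

    def arm_length(self, chrom: str, arm: str) -> int:
        s, e = self.arms[chrom][arm]
        return e - s + 1

    def arm_span(self, chrom: str, arm: str) -> Tuple[int, int]:
        return self.arms[chrom][arm]

    def features(self) -> List[Tuple[str, str]]:
        """All (chrom, arm) pairs in model order."""
        return [(c, a) for c in self.arms for a in self.arms[c]]

    def overlap(self, chrom: str, arm: str, start: int, end: int) -> int:
        """Length of intersection between [start,end] and the named arm."""
        s, e = self.arms[chrom][arm]
        return max(0, min(end, e) - max(start, s) + 1)


def check_referential_integrity(
    samples: Iterable[str], known_samples: Iterable[str], what: str
) -> None:
    known = set(known_samples)
    unknown = sorted({s for s in samples if s not in known})
    if unknown:
        raise RecordError(
            f"{what} reference samples absent from the clinical table: {unknown[:5]}"
        )
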