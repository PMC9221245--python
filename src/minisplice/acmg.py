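"""ACMG/AMP point-based evidence assignment and classification.

Per-transcript evidence calls are aggregated into a single assay-derived
splicing code (``PVS1_O`` for pathogenic, ``BP7_O`` for benign) using the
share rules: a side must contribute at least 90% of the overall expression
for its code to apply, and the applied strength is the weakest strength among
that side's transcripts individually contributing more than 10%.  Points are
summed with the rarity code and any pass-through codes into the five-tier
category.  Predictive splicing codes are dropped whenever an assay-derived
code is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .errors import EvidenceError, InputError

__all__ = [
    "Strength",
    "TranscriptCall",
    "EvidenceStrength",
    "TranscriptEvidence",
    "Verdict",
    "RuleConfig",
    "transcript_evidence",
    "aggregate_readout",
    "pm2_evidence",
    "classify",
    "format_evidence",
]


class Strength(Enum):
    SUPPORTING = 1
    MODERATE = 2
    STRONG = 4
    VERY_STRONG = 8
    NOT_APPLICABLE = 0

    @property
    def abbrev(self) -> str:
        return {
            Strength.SUPPORTING: "P",
            Strength.MODERATE: "M",
            Strength.STRONG: "S",
            Strength.VERY_STRONG: "VS",
            Strength.NOT_APPLICABLE: "N/A",
        }[self]


class TranscriptCall(Enum):
    """Per-transcript evidence call; pathogenic calls carry positive weight,
    benign calls negative, N/A none."""

    P_VS = ("pathogenic", Strength.VERY_STRONG)
    P_S = ("pathogenic", Strength.STRONG)
    P_M = ("pathogenic", Strength.MODERATE)
    P_P = ("pathogenic", Strength.SUPPORTING)
    B_S = ("benign", Strength.STRONG)
    B_P = ("benign", Strength.SUPPORTING)
    NA = ("none", Strength.NOT_APPLICABLE)

    @property
    def direction(self) -> str:
        return self.value[0]

    @property
    def strength(self) -> Strength:
        return self.value[1]

    @property
    def abbrev(self) -> str:
        if self is TranscriptCall.NA:
            return "N/A"
        side = "P" if self.direction == "pathogenic" else "B"
        return f"{side}_{self.strength.abbrev}"


@dataclass(frozen=True)
class EvidenceStrength:
    code: str
    direction: str  # pathogenic | benign | none
    strength: Strength
    points: int
    note: str = ""

    def __post_init__(self) -> None:
        magnitude = self.strength.value
        expected = {
            "pathogenic": magnitude,
            "benign": -magnitude,
            "none": 0,
        }[self.direction]
        if self.points != expected:
            raise InputError(
                f"{self.code}: points {self.points} inconsistent with "
                f"{self.direction}/{self.strength.name}"
            )


@dataclass(frozen=True)
class TranscriptEvidence:
    label: str
    fraction_percent: float
    call: TranscriptCall

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_percent <= 100.0):
            raise InputError(
                f"{self.label}: fraction {self.fraction_percent} outside [0, 100]"
            )


@dataclass(frozen=True)
class Verdict:
    variant_id: str
    evidence_items: tuple[EvidenceStrength, ...]
    total_points: int
    category: str  # P | LP | VUS | LB | B


@dataclass
class RuleConfig:
    """Evidence mapping and thresholds; serializable so other genes can ship
    their own rule files."""

    dominant_share_percent: float = 90.0
    strength_floor_share_percent: float = 10.0
    af_max_pm2: float = 1e-4
    provean_deleterious_max: float = -2.5
    revel_supportive_min: float = 0.7
    ptc_escape_critical_upgrade: bool = True
    category_bands: dict = field(
        default_factory=lambda: {
            "P": [10, None],
            "LP": [6, 9],
            "VUS": [0, 5],
            "LB": [-6, -1],
            "B": [None, -7],
        }
    )
    predictive_codes: tuple = ("PVS1", "PP3", "BP4", "PP3/BP4")

    def to_dict(self) -> dict:
        return {
            "dominant_share_percent": self.dominant_share_percent,
            "strength_floor_share_percent": self.strength_floor_share_percent,
            "af_max_pm2": self.af_max_pm2,
            "provean_deleterious_max": self.provean_deleterious_max,
            "revel_supportive_min": self.revel_supportive_min,
            "ptc_escape_critical_upgrade": self.ptc_escape_critical_upgrade,
            "category_bands": self.category_bands,
            "predictive_codes": list(self.predictive_codes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleConfig":
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise InputError(f"unknown rule key {key!r}")
            if key == "predictive_codes":
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


@dataclass(frozen=True)
class InSilicoAnnotation:
    provean_score: Optional[float] = None
    revel_score: Optional[float] = None
    deleterious_flag: Optional[bool] = None


def _insilico_deleterious(ann: InSilicoAnnotation, rules: RuleConfig) -> bool:
    if ann.deleterious_flag is not None:
        return ann.deleterious_flag
    if ann.provean_score is not None and ann.provean_score <= rules.provean_deleterious_max:
        return True
    if ann.revel_score is not None and ann.revel_score >= rules.revel_supportive_min:
        return True
    return False


def transcript_evidence(
    category: str,
    fraction_percent: float,
    label: str = "",
    critical_domain_lost: bool = False,
    variant_on_transcript: bool = False,
    insilico: Optional[InSilicoAnnotation] = None,
    rules: Optional[RuleConfig] = None,
) -> TranscriptEvidence:
    """Map one transcript's consequence category to an evidence call.

    ``category`` is one of ``FL``, ``PTC_NMD``, ``PTC_escape``, ``in_frame``,
    ``uncharacterized``.  ``variant_on_transcript`` marks a full-length
    transcript that carries the variant (a missense product rather than the
    wild type).
    """
    rules = rules or RuleConfig()
    insilico = insilico or InSilicoAnnotation()
    if category == "PTC_NMD":
        call = TranscriptCall.P_VS
    elif category == "PTC_escape":
        call = TranscriptCall.P_S
        if rules.ptc_escape_critical_upgrade and critical_domain_lost:
            call = TranscriptCall.P_VS
    elif category == "in_frame":
        if critical_domain_lost:
            call = TranscriptCall.P_VS
        elif _insilico_deleterious(insilico, rules):
            call = TranscriptCall.P_P
        else:
            call = TranscriptCall.NA
    elif category == "FL":
        if not variant_on_transcript:
            call = TranscriptCall.B_S
        elif _insilico_deleterious(insilico, rules):
            call = TranscriptCall.P_P
        else:
            call = TranscriptCall.NA
    elif category == "uncharacterized":
        call = TranscriptCall.NA
    else:
        raise EvidenceError(f"undetermined consequence category {category!r}")
    return TranscriptEvidence(label or category, fraction_percent, call)


def aggregate_readout(
    items: Sequence[TranscriptEvidence],
    rules: Optional[RuleConfig] = None,
    sum_tolerance: float = 0.5,
) -> EvidenceStrength:
    """Collapse per-transcript evidence into one assay-derived code.

    Shares are taken over the overall expression (uncharacterized and N/A
    transcripts stay in the denominator).  The >10% strength floor is strict;
    if a side dominates but no single transcript of that side exceeds 10%,
    the weakest strength on that side is used (flagged in the note).
    """
    rules = rules or RuleConfig()
    total = sum(it.fraction_percent for it in items)
    if total > 100.0 + sum_tolerance:
        raise InputError(f"transcript fractions sum to {total:.2f} > 100")

    path = [it for it in items if it.call.direction == "pathogenic"]
    benign = [it for it in items if it.call.direction == "benign"]
    p_share = sum(it.fraction_percent for it in path)
    b_share = sum(it.fraction_percent for it in benign)

    for side, share, members, code in (
        ("pathogenic", p_share, path, "PVS1_O"),
        ("benign", b_share, benign, "BP7_O"),
    ):
        if share >= rules.dominant_share_percent:
            floor = rules.strength_floor_share_percent
            contributing = [
                it for it in members if it.fraction_percent > floor
            ]
            note = ""
            if not contributing:
                contributing = list(members)
                note = "no single transcript above the strength floor; weakest strength used"
            strength = min(
                (it.call.strength for it in contributing),
                key=lambda s: s.value,
            )
            points = strength.value if side == "pathogenic" else -strength.value
            return EvidenceStrength(code, side, strength, points, note)

    return EvidenceStrength(
        "PVS1_O/BP7_O",
        "none",
        Strength.NOT_APPLICABLE,
        0,
        "neither side reaches the dominant share",
    )


def pm2_evidence(
    allele_count: int,
    allele_number: int,
    rules: Optional[RuleConfig] = None,
) -> EvidenceStrength:
    """Rarity evidence at supporting strength when the population allele
    frequency is at most 0.01%."""
    rules = rules or RuleConfig()
    if allele_count < 0 or allele_number <= 0:
        raise InputError("allele_count must be >= 0 and allele_number > 0")
    if allele_count / allele_number <= rules.af_max_pm2:
        return EvidenceStrength("PM2_P", "pathogenic", Strength.SUPPORTING, 1)
    return EvidenceStrength("PM2", "none", Strength.NOT_APPLICABLE, 0)


def classify(
    evidence_items: Sequence[EvidenceStrength],
    rules: Optional[RuleConfig] = None,
    variant_id: str = "",
) -> Verdict:
    """Sum evidence points into the five-tier category.

    Predictive splicing codes are excluded whenever an assay-derived
    (``*_O``) code is present.
    """
    rules = rules or RuleConfig()
    has_assay = any("_O" in it.code for it in evidence_items)
    kept = tuple(
        it
        for it in evidence_items
        if not (has_assay and it.code in rules.predictive_codes)
    )
    total = sum(it.points for it in kept)
    category = None
    for name, (lo, hi) in rules.category_bands.items():
        if (lo is None or total >= lo) and (hi is None or total <= hi):
            category = name
            break
    if category is None:  # pragma: no cover - bands tile the integers
        raise EvidenceError(f"no category band for total {total}")
    return Verdict(variant_id, kept, total, category)


def format_evidence(ev: EvidenceStrength) -> str:
    """Render like ``PVS1_O_VS (+8)`` / ``PM2_P (+1)`` / ``PVS1_O_N/A``."""
    if ev.strength is Strength.NOT_APPLICABLE:
        base = ev.code if ev.code.endswith("N/A") else f"{ev.code}_N/A"
        return base
    if ev.code.endswith(f"_{ev.strength.abbrev}"):
        name = ev.code
    else:
        name = f"{ev.code}_{ev.strength.abbrev}" if "_O" in ev.code else ev.code
    return f"{name} ({ev.points:+d})"
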