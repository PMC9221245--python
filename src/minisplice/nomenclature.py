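"""Parser and serializer for the compact splice-transcript label grammar.

Labels describe one mature transcript relative to the full-length product:

* ``FL`` — full length, no events.
* ``Δ(E5)`` — skip of exon 5; ``Δ(E4_5)`` — skip of exons 4-5.
* ``Δ(E2p3)`` — alternative acceptor 3 nt into exon 2 (first 3 exonic nt lost).
* ``Δ(E2q175)`` — alternative donor 175 nt into exon 2 (last 175 exonic nt lost).
* ``▼(E8p3)`` — alternative acceptor 3 nt into the upstream intron (3 intronic
  nt retained ahead of exon 8).
* ``▼(E6q4)`` — alternative donor 4 nt into the downstream intron.
* an optional ``-a``/``-b`` suffix tags same-event transcripts that differ in
  their underlying variant base.

ASCII aliases ``D``/``d`` (for Δ) and ``v``/``V`` (for ▼) are accepted on
input; canonical output always uses the glyphs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import LabelParseError

__all__ = ["EventKind", "SpliceEvent", "IsoformLabel", "parse_label", "format_label"]

FL_LABEL = "FL"
DELETION_GLYPH = "Δ"  # Δ
INCLUSION_GLYPH = "▼"  # ▼

_DELETION_ALIASES = {DELETION_GLYPH, "∆", "D", "d"}  # ∆ (U+2206) also seen
_INCLUSION_ALIASES = {INCLUSION_GLYPH, "v", "V"}


class EventKind(str, Enum):
    EXON_SKIP = "exon_skip"
    EXONIC_DELETION_ACCEPTOR = "exonic_deletion_acceptor"  # Δ(E n p k)
    EXONIC_DELETION_DONOR = "exonic_deletion_donor"  # Δ(E n q k)
    INTRONIC_INCLUSION_ACCEPTOR = "intronic_inclusion_acceptor"  # ▼(E n p k)
    INTRONIC_INCLUSION_DONOR = "intronic_inclusion_donor"  # ▼(E n q k)

    @property
    def is_deletion(self) -> bool:
        return self in (
            EventKind.EXON_SKIP,
            EventKind.EXONIC_DELETION_ACCEPTOR,
            EventKind.EXONIC_DELETION_DONOR,
        )

    @property
    def is_inclusion(self) -> bool:
        return not self.is_deletion

    @property
    def side(self) -> Optional[str]:
        """'acceptor' for p events, 'donor' for q events, None for skips."""
        if self in (
            EventKind.EXONIC_DELETION_ACCEPTOR,
            EventKind.INTRONIC_INCLUSION_ACCEPTOR,
        ):
            return "acceptor"
        if self in (
            EventKind.EXONIC_DELETION_DONOR,
            EventKind.INTRONIC_INCLUSION_DONOR,
        ):
            return "donor"
        return None


@dataclass(frozen=True)
class SpliceEvent:
    kind: EventKind
    exon_from: int
    exon_to: int
    shift_nt: int = 0
    allele_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.exon_from < 1:
            raise ValueError("exon numbers are 1-based")
        if self.exon_to < self.exon_from:
            raise ValueError("exon_to < exon_from")
        if (self.shift_nt == 0) != (self.kind is EventKind.EXON_SKIP):
            raise ValueError("shift_nt == 0 iff the event is a whole-exon skip")
        if self.exon_to > self.exon_from and self.kind is not EventKind.EXON_SKIP:
            raise ValueError("multi-exon span only valid for exon skips")
        if self.shift_nt < 0:
            raise ValueError("shift_nt must be >= 0")

    @property
    def exon(self) -> int:
        return self.exon_from

    def net_length_change(self, exon_lengths) -> int:
        """Signed mature-length change; ``exon_lengths`` maps index -> nt."""
        if self.kind is EventKind.EXON_SKIP:
            return -sum(
                exon_lengths[i] for i in range(self.exon_from, self.exon_to + 1)
            )
        if self.kind.is_deletion:
            return -self.shift_nt
        return self.shift_nt


@dataclass(frozen=True)
class IsoformLabel:
    events: tuple[SpliceEvent, ...] = field(default_factory=tuple)
    raw_label: Optional[str] = None

    @property
    def is_full_length(self) -> bool:
        return not self.events

    def __str__(self) -> str:
        return format_label(self)


_EVENT_RE = re.compile(
    r"(?P<glyph>[Δ∆▼DdvV])"
    r"\(E(?P<from>\d+)(?:_(?P<to>\d+))?(?:(?P<side>[pq])(?P<shift>\d+))?\)"
    r"(?:-(?P<tag>[A-Za-z0-9]+))?"
)


def parse_label(label: str) -> IsoformLabel:
    """Parse a transcript label into structured events.

    Raises :class:`LabelParseError` naming the first offending token.
    """
    text = label.strip()
    if text in (FL_LABEL, "mgFL", "mgFL-transcript"):
        return IsoformLabel(events=(), raw_label=label)
    if not text:
        raise LabelParseError(label, "", "empty label")
    events: list[SpliceEvent] = []
    pos = 0
    while pos < len(text):
        m = _EVENT_RE.match(text, pos)
        if m is None:
            raise LabelParseError(label, text[pos : pos + 12], "expected event")
        glyph = m.group("glyph")
        exon_from = int(m.group("from"))
        exon_to = int(m.group("to")) if m.group("to") else exon_from
        side = m.group("side")
        shift = int(m.group("shift")) if m.group("shift") else 0
        tag = m.group("tag")
        if glyph in _DELETION_ALIASES:
            if side is None:
                kind = EventKind.EXON_SKIP
            elif side == "p":
                kind = EventKind.EXONIC_DELETION_ACCEPTOR
            else:
                kind = EventKind.EXONIC_DELETION_DONOR
        elif glyph in _INCLUSION_ALIASES:
            if side is None:
                raise LabelParseError(
                    label, m.group(0), "intronic inclusion requires p/q and a size"
                )
            kind = (
                EventKind.INTRONIC_INCLUSION_ACCEPTOR
                if side == "p"
                else EventKind.INTRONIC_INCLUSION_DONOR
            )
        else:  # pragma: no cover - regex restricts glyphs
            raise LabelParseError(label, glyph, "unknown event glyph")
        if side is not None and shift == 0:
            raise LabelParseError(label, m.group(0), "shift size must be >= 1")
        if exon_to != exon_from and side is not None:
            raise LabelParseError(
                label, m.group(0), "multi-exon span only valid for whole skips"
            )
        try:
            events.append(SpliceEvent(kind, exon_from, exon_to, shift, tag))
        except ValueError as exc:
            raise LabelParseError(label, m.group(0), str(exc)) from exc
        pos = m.end()
    return IsoformLabel(events=tuple(events), raw_label=label)


def _format_event(ev: SpliceEvent) -> str:
    if ev.kind is EventKind.EXON_SKIP:
        span = (
            f"E{ev.exon_from}"
            if ev.exon_to == ev.exon_from
            else f"E{ev.exon_from}_{ev.exon_to}"
        )
        core = f"{DELETION_GLYPH}({span})"
    else:
        glyph = DELETION_GLYPH if ev.kind.is_deletion else INCLUSION_GLYPH
        side = "p" if ev.kind.side == "acceptor" else "q"
        core = f"{glyph}(E{ev.exon_from}{side}{ev.shift_nt})"
    return core + (f"-{ev.allele_tag}" if ev.allele_tag else "")


def format_label(isoform: IsoformLabel) -> str:
    """Canonical serialization; ``parse_label(format_label(x)).events == x.events``."""
    if isoform.is_full_length:
        return FL_LABEL
    return "".join(_format_event(ev) for ev in isoform.events)
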