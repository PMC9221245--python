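"""Apply a DNA variant plus splice events to the gene model and derive the
transcript-level consequence: frame status, premature termination, NMD
susceptibility, a best-effort protein annotation, and lost domains.

The variant is applied to the pre-mRNA *before* the splice events, so a
retained intronic segment carries the variant base when the variant lies
inside it, and a full-length transcript over an exonic substitution is a
missense transcript rather than the wild type.

Consequences are evaluated in native full-gene context (all model exons);
reporter-amplicon sizes are a concern of :mod:`minisplice.fragment_quant`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import CoordinateError, HgvsParseError, SequenceRequiredError
from .gene_model import DomainTable, TranscriptModel
from .nomenclature import EventKind, IsoformLabel, SpliceEvent

__all__ = [
    "CPos",
    "VariantSpec",
    "parse_hgvs_c",
    "MatureTranscript",
    "Consequence",
    "apply_isoform",
    "analyze_consequence",
    "variant_in_isoform",
]

_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "*",
}


def _aa3(aa: str) -> str:
    return "".join(_AA3[a] for a in aa)


# -- HGVS c. subset -----------------------------------------------------------


@dataclass(frozen=True)
class CPos:
    """A c. position with a signed intronic offset (0 = exonic)."""

    pos: int
    offset: int = 0

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.pos)
        return f"{self.pos}{self.offset:+d}"


@dataclass(frozen=True)
class VariantSpec:
    hgvs_c: str
    kind: str  # sub | del | ins | delins | dup
    start: CPos
    end: CPos
    ref: Optional[str] = None
    alt: Optional[str] = None


_POS_RE = r"(\d+)([+-]\d+)?"
_HGVS_RE = re.compile(
    rf"^c\.{_POS_RE}(?:_{_POS_RE})?"
    r"(?:(?P<sub>[ACGT]>[ACGT])|(?P<delins>delins(?P<delins_seq>[ACGT]+))"
    r"|(?P<del>del(?P<del_seq>[ACGT]*))|(?P<ins>ins(?P<ins_seq>[ACGT]+))"
    r"|(?P<dup>dup(?P<dup_seq>[ACGT]*)))$"
)


def parse_hgvs_c(hgvs: str) -> VariantSpec:
    """Parse the substitution/deletion/insertion/delins/dup subset of
    HGVS c. descriptions (intronic offsets supported)."""
    text = hgvs.strip()
    m = _HGVS_RE.match(text)
    if m is None:
        raise HgvsParseError(f"unsupported or malformed HGVS description: {hgvs!r}")
    start = CPos(int(m.group(1)), int(m.group(2) or 0))
    if m.group(3):
        end = CPos(int(m.group(3)), int(m.group(4) or 0))
    else:
        end = start
    if (end.pos, end.offset) < (start.pos, start.offset):
        raise HgvsParseError(f"range end precedes start: {hgvs!r}")
    if m.group("sub"):
        if end != start:
            raise HgvsParseError(f"substitution must be a single position: {hgvs!r}")
        ref, alt = m.group("sub").split(">")
        return VariantSpec(text, "sub", start, end, ref, alt)
    if m.group("delins"):
        return VariantSpec(text, "delins", start, end, None, m.group("delins_seq"))
    if m.group("del"):
        return VariantSpec(text, "del", start, end, m.group("del_seq") or None, None)
    if m.group("ins"):
        if end == start:
            raise HgvsParseError(f"insertion needs a two-position anchor: {hgvs!r}")
        return VariantSpec(text, "ins", start, end, None, m.group("ins_seq"))
    return VariantSpec(text, "dup", start, end, m.group("dup_seq") or None, None)


# -- pre-mRNA position walk ---------------------------------------------------


def _succ(model: TranscriptModel, p: CPos) -> CPos:
    """Next pre-mRNA position in transcript orientation."""
    if p.offset > 0:
        return CPos(p.pos, p.offset + 1)
    if p.offset < 0:
        return CPos(p.pos, p.offset + 1)
    exon = next(e for e in model.exons if e.c_start <= p.pos <= e.c_end)
    if p.pos < exon.c_end:
        return CPos(p.pos + 1, 0)
    if exon.index == model.exons[-1].index:
        raise CoordinateError("walked past the transcript end")
    return CPos(p.pos, 1)


def _enumerate_range(model: TranscriptModel, start: CPos, end: CPos) -> list[CPos]:
    """All pre-mRNA positions from start to end inclusive.

    Only meaningful for short ranges; ranges through an intron interior are
    rejected because intron lengths are unknown to the model.
    """
    out = [start]
    cur = start
    for _ in range(100_000):
        if cur == end:
            return out
        nxt = _succ(model, cur)
        if nxt.offset > 0 and cur.offset > 0 and nxt.pos != end.pos and nxt.offset > 5000:
            break
        cur = nxt
        out.append(cur)
    raise CoordinateError(
        f"range {start}..{end} does not terminate within the transcript"
    )


# -- splice plan --------------------------------------------------------------


@dataclass
class _SplicePlan:
    # exon index -> (lo, hi) retained c-range, or None when skipped
    exon_ranges: dict[int, Optional[tuple[int, int]]]
    # (intron index, side) -> retained nt count
    inclusions: dict[tuple[int, str], int]


def _build_plan(model: TranscriptModel, isoform: IsoformLabel) -> _SplicePlan:
    ranges: dict[int, Optional[tuple[int, int]]] = {
        e.index: (e.c_start, e.c_end) for e in model.exons
    }
    inclusions: dict[tuple[int, str], int] = {}
    last = model.exons[-1].index
    first = model.exons[0].index
    for ev in isoform.events:
        if ev.exon_from < first or ev.exon_to > last:
            raise CoordinateError(f"event references exon outside model: {ev}")
        if ev.kind is EventKind.EXON_SKIP:
            for i in range(ev.exon_from, ev.exon_to + 1):
                ranges[i] = None
            continue
        exon = model.exon(ev.exon_from)
        if ev.kind.is_deletion and ev.shift_nt >= exon.length:
            raise CoordinateError(
                f"{ev.kind.value} of {ev.shift_nt} nt exceeds exon "
                f"{exon.index} length {exon.length}"
            )
        cur = ranges[ev.exon_from]
        if ev.kind is EventKind.EXONIC_DELETION_ACCEPTOR:
            ranges[ev.exon_from] = (cur[0] + ev.shift_nt, cur[1])
        elif ev.kind is EventKind.EXONIC_DELETION_DONOR:
            ranges[ev.exon_from] = (cur[0], cur[1] - ev.shift_nt)
        elif ev.kind is EventKind.INTRONIC_INCLUSION_ACCEPTOR:
            if ev.exon_from == first:
                raise CoordinateError("no intron upstream of the first exon")
            inclusions[(ev.exon_from - 1, "acceptor")] = ev.shift_nt
        else:  # intronic inclusion, donor side
            if ev.exon_from == last:
                raise CoordinateError("no intron downstream of the last exon")
            inclusions[(ev.exon_from, "donor")] = ev.shift_nt
    return _SplicePlan(ranges, inclusions)


def _position_retained(plan: _SplicePlan, model: TranscriptModel, p: CPos) -> bool:
    if p.offset == 0:
        exon = next(e for e in model.exons if e.c_start <= p.pos <= e.c_end)
        rng = plan.exon_ranges[exon.index]
        return rng is not None and rng[0] <= p.pos <= rng[1]
    if p.offset > 0:
        exon = next((e for e in model.exons if e.c_end == p.pos), None)
        if exon is None:
            return False
        kept = plan.inclusions.get((exon.index, "donor"), 0)
        return p.offset <= kept
    exon = next((e for e in model.exons if e.c_start == p.pos), None)
    if exon is None:
        return False
    kept = plan.inclusions.get((exon.index - 1, "acceptor"), 0)
    return -p.offset <= kept


def variant_in_isoform(
    model: TranscriptModel, variant: Optional[VariantSpec], isoform: IsoformLabel
) -> bool:
    """True when the variant leaves a trace in the mature transcript (any
    affected or anchor position is retained after splicing)."""
    if variant is None:
        return False
    plan = _build_plan(model, isoform)
    positions = _enumerate_range(model, variant.start, variant.end)
    return any(_position_retained(plan, model, p) for p in positions)


# -- pre-mRNA items (sequence mode) ------------------------------------------

# item: (segment kind 'E'|'I'|'GAP'|'INS', segment index, tag, base)
# exon tag = c position; intron tag = signed flank offset; INS tag = None.


def _premrna_items(model: TranscriptModel) -> list[tuple]:
    model.require_sequences()
    items: list[tuple] = []
    flanks = model.intron_flanks or {}
    for e in model.exons:
        seq = model.exon_sequences[e.index]
        for j, base in enumerate(seq):
            items.append(("E", e.index, e.c_start + j, base))
        if e.index != model.exons[-1].index:
            donor, acceptor = flanks.get(e.index, ("", ""))
            for j, base in enumerate(donor):
                items.append(("I", e.index, j + 1, base))
            items.append(("GAP", e.index, None, None))
            for j, base in enumerate(acceptor):
                items.append(("I", e.index, -(len(acceptor) - j), base))
    return items


def _find_item(items: list[tuple], model: TranscriptModel, p: CPos) -> int:
    if p.offset == 0:
        want = ("E", None, p.pos)
    elif p.offset > 0:
        exon = next((e for e in model.exons if e.c_end == p.pos), None)
        if exon is None:
            raise CoordinateError(f"c.{p}: c.{p.pos} is not an exon end")
        want = ("I", exon.index, p.offset)
    else:
        exon = next((e for e in model.exons if e.c_start == p.pos), None)
        if exon is None:
            raise CoordinateError(f"c.{p}: c.{p.pos} is not an exon start")
        want = ("I", exon.index - 1, p.offset)
    for i, (kind, idx, tag, _base) in enumerate(items):
        if kind != want[0] or tag != want[2]:
            continue
        if want[1] is not None and idx != want[1]:
            continue
        return i
    raise SequenceRequiredError(
        f"position c.{p} is not covered by the stored sequences/flanks"
    )


def _apply_variant_items(
    items: list[tuple], model: TranscriptModel, variant: VariantSpec
) -> list[tuple]:
    i0 = _find_item(items, model, variant.start)
    i1 = _find_item(items, model, variant.end)
    if i1 < i0:
        raise HgvsParseError(f"{variant.hgvs_c}: end precedes start")
    if any(it[0] == "GAP" for it in items[i0 : i1 + 1]):
        raise SequenceRequiredError(
            f"{variant.hgvs_c}: range crosses an intron interior not stored in the model"
        )
    out = list(items)
    span = out[i0 : i1 + 1]
    if variant.kind == "sub":
        kind, idx, tag, base = out[i0]
        if variant.ref and base != variant.ref:
            raise HgvsParseError(
                f"{variant.hgvs_c}: reference base is {base}, not {variant.ref}"
            )
        out[i0] = (kind, idx, tag, variant.alt)
    elif variant.kind == "del":
        if variant.ref and "".join(it[3] for it in span) != variant.ref:
            raise HgvsParseError(f"{variant.hgvs_c}: deleted bases do not match reference")
        del out[i0 : i1 + 1]
    elif variant.kind == "delins":
        ins = [("INS", None, None, b) for b in variant.alt]
        out[i0 : i1 + 1] = ins
    elif variant.kind == "ins":
        if i1 != i0 + 1:
            raise HgvsParseError(f"{variant.hgvs_c}: insertion anchors must be adjacent")
        ins = [("INS", None, None, b) for b in variant.alt]
        out[i0 + 1 : i0 + 1] = ins
    elif variant.kind == "dup":
        dup = [("INS", None, None, it[3]) for it in span]
        out[i1 + 1 : i1 + 1] = dup
    return out


# -- mature transcript --------------------------------------------------------


@dataclass
class MatureTranscript:
    """Spliced product: sequence when available, otherwise length accounting.

    ``junctions`` holds the number of mature-transcript bases upstream of each
    splice junction; ``cds_offset`` is the 0-based index of c.1.
    """

    length: int
    net_length_change: int
    junctions: list[int]
    sequence: Optional[str] = None
    cds_offset: Optional[int] = None
    item_tags: Optional[list[tuple]] = None

    @property
    def last_junction(self) -> Optional[int]:
        return self.junctions[-1] if self.junctions else None


def _splice_items(
    items: list[tuple], model: TranscriptModel, plan: _SplicePlan
) -> list[tuple]:
    kept: list[tuple] = []
    prev_keep = False
    for pre_idx, (kind, idx, tag, base) in enumerate(items):
        if kind == "GAP":
            prev_keep = False
            continue
        if kind == "INS":
            keep = prev_keep
        elif kind == "E":
            rng = plan.exon_ranges[idx]
            keep = rng is not None and rng[0] <= tag <= rng[1]
        else:  # intron flank
            if tag > 0:
                keep = tag <= plan.inclusions.get((idx, "donor"), 0)
            else:
                keep = -tag <= plan.inclusions.get((idx, "acceptor"), 0)
        if keep:
            kept.append((pre_idx, kind, idx, tag, base))
        prev_keep = keep
    return kept


def _check_inclusion_coverage(
    model: TranscriptModel, plan: _SplicePlan
) -> None:
    flanks = model.intron_flanks or {}
    for (intron, side), k in plan.inclusions.items():
        donor, acceptor = flanks.get(intron, ("", ""))
        have = len(donor) if side == "donor" else len(acceptor)
        if k > have:
            raise SequenceRequiredError(
                f"inclusion of {k} nt on the {side} side of intron {intron} "
                f"exceeds the stored flank ({have} nt)"
            )


def apply_isoform(
    model: TranscriptModel,
    variant: Optional[VariantSpec],
    isoform: IsoformLabel,
) -> MatureTranscript:
    """Reconstruct the mature transcript for a variant + splice-event set.

    With sequences attached, the actual nucleotide string is returned; without
    them the result carries exact length accounting and junction positions
    (raising only when a computation truly needs bases).
    """
    plan = _build_plan(model, isoform)
    ref_length = sum(e.length for e in model.exons)

    if model.has_sequences:
        _check_inclusion_coverage(model, plan)
        items = _premrna_items(model)
        if variant is not None:
            items = _apply_variant_items(items, model, variant)
        kept = _splice_items(items, model, plan)
        seq = "".join(it[4] for it in kept)
        junctions = []
        for j in range(1, len(kept)):
            if kept[j][0] - kept[j - 1][0] > 1:
                junctions.append(j)
        cds_offset = None
        for j, it in enumerate(kept):
            if it[1] == "E" and it[3] == model.cds_start_c:
                cds_offset = j
                break
        return MatureTranscript(
            length=len(seq),
            net_length_change=len(seq) - ref_length,
            junctions=junctions,
            sequence=seq,
            cds_offset=cds_offset,
            item_tags=[(it[1], it[2], it[3]) for it in kept],
        )

    # arithmetic mode: block lengths only
    variant_delta = 0
    if variant is not None:
        positions = _enumerate_range(model, variant.start, variant.end)
        retained = sum(
            1 for p in positions if _position_retained(plan, model, p)
        )
        if variant.kind == "del":
            variant_delta = -retained
        elif variant.kind == "delins":
            anchor = _position_retained(plan, model, variant.start)
            variant_delta = (len(variant.alt) if anchor else 0) - retained
        elif variant.kind == "ins":
            anchor = _position_retained(plan, model, variant.start)
            variant_delta = len(variant.alt) if anchor else 0
        elif variant.kind == "dup":
            variant_delta = retained

    blocks: list[int] = []
    for e in model.exons:
        rng = plan.exon_ranges[e.index]
        if rng is None:
            continue
        length = rng[1] - rng[0] + 1
        length += plan.inclusions.get((e.index - 1, "acceptor"), 0)
        length += plan.inclusions.get((e.index, "donor"), 0)
        blocks.append(length)
    total = sum(blocks) + variant_delta
    junctions = []
    acc = 0
    for b in blocks[:-1]:
        acc += b
        junctions.append(acc)
    return MatureTranscript(
        length=total,
        net_length_change=total - ref_length + 0,
        junctions=junctions,
    )


# -- consequence --------------------------------------------------------------


@dataclass
class Consequence:
    isoform: IsoformLabel
    net_length_change_nt: int
    frame_preserved: bool
    ptc_present: Optional[bool]
    ptc_c_pos: Optional[int] = None
    nmd_predicted: Optional[bool] = None
    protein_annotation: str = ""
    domains_lost: list[str] = field(default_factory=list)
    category: str = "uncharacterized"  # FL | PTC_NMD | PTC_escape | in_frame | uncharacterized

    @property
    def critical_domain_lost(self) -> bool:
        return bool(self.domains_lost)


def _translate(seq: str) -> tuple[str, bool]:
    """Translate until the first stop; returns (residues, stop_found)."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = _CODON_TABLE.get(seq[i : i + 3], "X")
        if aa == "*":
            return "".join(out), True
        out.append(aa)
    return "".join(out), False


def _protein_annotation(
    ref: str, new: str, stop_found: bool, frame_preserved: bool
) -> str:
    if new == ref and stop_found:
        return "p.(=)"
    # first differing residue
    i = 0
    while i < min(len(ref), len(new)) and ref[i] == new[i]:
        i += 1
    if not frame_preserved or (stop_found and len(new) < len(ref) and i == len(new)):
        if not stop_found:
            return f"p.{_aa3(ref[i])}{i + 1}fs?" if i < len(ref) else "p.?"
        if i >= len(new):  # stop lands exactly at the first changed codon
            return f"p.{_aa3(ref[i])}{i + 1}*"
        return f"p.{_aa3(ref[i])}{i + 1}{_aa3(new[i])}Fs*{len(new) - i + 1}"
    if not stop_found:
        return "p.?"
    # in-frame: strip common suffix
    s = 0
    while (
        s < min(len(ref), len(new)) - i
        and ref[len(ref) - 1 - s] == new[len(new) - 1 - s]
    ):
        s += 1
    ref_core = ref[i : len(ref) - s]
    new_core = new[i : len(new) - s]
    if not ref_core and not new_core:
        return "p.(=)"
    if not new_core:  # pure deletion
        if len(ref_core) == 1:
            return f"p.{_aa3(ref_core)}{i + 1}del"
        return f"p.{_aa3(ref_core[0])}{i + 1}_{_aa3(ref_core[-1])}{i + len(ref_core)}del"
    if not ref_core:  # pure insertion
        left = _aa3(ref[i - 1]) + str(i) if i > 0 else "?"
        right = _aa3(ref[i]) + str(i + 1) if i < len(ref) else "?"
        return f"p.{left}_{right}ins{_aa3(new_core)}"
    if len(ref_core) == 1 and len(new_core) == 1:
        return f"p.{_aa3(ref_core)}{i + 1}{_aa3(new_core)}"
    if len(ref_core) == 1:
        return f"p.{_aa3(ref_core)}{i + 1}delins{_aa3(new_core)}"
    return (
        f"p.{_aa3(ref_core[0])}{i + 1}_{_aa3(ref_core[-1])}{i + len(ref_core)}"
        f"delins{_aa3(new_core)}"
    )


def _event_first_affected_c(model: TranscriptModel, ev: SpliceEvent) -> int:
    if ev.kind is EventKind.EXON_SKIP:
        return model.exon(ev.exon_from).c_start
    exon = model.exon(ev.exon_from)
    if ev.kind is EventKind.EXONIC_DELETION_ACCEPTOR:
        return exon.c_start
    if ev.kind is EventKind.EXONIC_DELETION_DONOR:
        return exon.c_end - ev.shift_nt + 1
    if ev.kind is EventKind.INTRONIC_INCLUSION_ACCEPTOR:
        return exon.c_start
    return exon.c_end  # donor-side inclusion starts right after the exon end


def _deleted_codon_ranges(
    model: TranscriptModel, isoform: IsoformLabel
) -> list[tuple[int, int]]:
    """Fully deleted codon ranges for in-frame arithmetic (approximate:
    counts only codons wholly inside a deleted exonic segment)."""
    ranges = []
    for ev in isoform.events:
        if not ev.kind.is_deletion:
            continue
        if ev.kind is EventKind.EXON_SKIP:
            a = model.exon(ev.exon_from).c_start
            b = model.exon(ev.exon_to).c_end
        elif ev.kind is EventKind.EXONIC_DELETION_ACCEPTOR:
            exon = model.exon(ev.exon_from)
            a, b = exon.c_start, exon.c_start + ev.shift_nt - 1
        else:
            exon = model.exon(ev.exon_from)
            a, b = exon.c_end - ev.shift_nt + 1, exon.c_end
        # first codon wholly inside [a, b]
        first = (a - 1) // 3 + 1 if (a - 1) % 3 == 0 else (a - 1) // 3 + 2
        last = b // 3
        if first <= last:
            ranges.append((first, last))
    return ranges


def _domains_lost(
    domains: Optional[DomainTable],
    frameshift_from_aa: Optional[int],
    inframe_removed: list[tuple[int, int]],
) -> list[str]:
    if domains is None:
        return []
    lost = []
    for d in domains:
        hit = False
        if frameshift_from_aa is not None and d.aa_end >= frameshift_from_aa:
            # truncation/frameshift destroys everything from the first
            # altered residue onward, including partially overlapped domains
            hit = True
        for a, b in inframe_removed:
            if a <= d.aa_start and d.aa_end <= b:
                hit = True
        if hit:
            lost.append(d.name)
    return lost


def analyze_consequence(
    model: TranscriptModel,
    variant: Optional[VariantSpec],
    isoform: IsoformLabel,
    domains: Optional[DomainTable] = None,
    nmd_boundary_nt: int = 50,
) -> Consequence:
    """Full consequence for one transcript of one variant.

    With sequences: scans the edited spliced CDS for the first in-frame stop,
    applies the boundary rule (stop more than ``nmd_boundary_nt`` upstream of
    the last exon-exon junction => NMD-predicted) and derives a protein-level
    annotation by diffing translations.  Without sequences: frame arithmetic
    only, with ``ptc_present`` undetermined.
    """
    mature = apply_isoform(model, variant, isoform)
    net = mature.net_length_change
    frame_ok = net % 3 == 0

    if mature.sequence is None:
        inframe_removed = _deleted_codon_ranges(model, isoform) if frame_ok else []
        fs_from = None
        if not frame_ok and isoform.events:
            first_c = min(_event_first_affected_c(model, ev) for ev in isoform.events)
            fs_from = (first_c - 1) // 3 + 1
        category = (
            "FL"
            if isoform.is_full_length
            else ("in_frame" if frame_ok else "uncharacterized")
        )
        return Consequence(
            isoform=isoform,
            net_length_change_nt=net,
            frame_preserved=frame_ok,
            ptc_present=None,
            protein_annotation="p.?" if isoform.events else "",
            domains_lost=_domains_lost(domains, fs_from, inframe_removed),
            category=category,
        )

    if mature.cds_offset is None:
        raise SequenceRequiredError("translation start (c.1) absent from transcript")

    cds = mature.sequence[mature.cds_offset :]
    new_prot, stop_found = _translate(cds)

    ref_mature = apply_isoform(model, None, IsoformLabel(()))
    ref_prot, _ = _translate(ref_mature.sequence[ref_mature.cds_offset :])

    # native stop check: does the first stop sit on the reference stop codon?
    stop_start = len(new_prot) * 3  # 0-based within CDS
    native_stop_tags = [
        ("E", c) for c in range(model.cds_end_c - 2, model.cds_end_c + 1)
    ]
    ptc = False
    ptc_c_pos = None
    if stop_found:
        tags = mature.item_tags[
            mature.cds_offset + stop_start : mature.cds_offset + stop_start + 3
        ]
        observed = [(k, t) for (k, _i, t) in tags]
        ptc = observed != native_stop_tags
        if ptc:
            ptc_c_pos = stop_start + 1  # 1-based CDS coordinate in this transcript

    nmd = None
    if ptc:
        last_j = mature.last_junction
        if last_j is None:
            nmd = False
        else:
            ptc_start_mature = mature.cds_offset + stop_start  # 0-based
            nmd = (last_j - ptc_start_mature) > nmd_boundary_nt

    annotation = _protein_annotation(ref_prot, new_prot, stop_found, frame_ok)

    fs_from = None
    inframe_removed: list[tuple[int, int]] = []
    i = 0
    while i < min(len(ref_prot), len(new_prot)) and ref_prot[i] == new_prot[i]:
        i += 1
    if not frame_ok or (ptc and len(new_prot) < len(ref_prot)):
        fs_from = i + 1
    elif new_prot != ref_prot:
        s = 0
        while (
            s < min(len(ref_prot), len(new_prot)) - i
            and ref_prot[len(ref_prot) - 1 - s] == new_prot[len(new_prot) - 1 - s]
        ):
            s += 1
        if len(ref_prot) - s >= i + 1:
            inframe_removed.append((i + 1, len(ref_prot) - s))

    if isoform.is_full_length and not ptc:
        category = "FL"
    elif ptc:
        category = "PTC_NMD" if nmd else "PTC_escape"
    elif frame_ok:
        category = "in_frame"
    else:
        category = "uncharacterized"

    return Consequence(
        isoform=isoform,
        net_length_change_nt=net,
        frame_preserved=frame_ok,
        ptc_present=ptc,
        ptc_c_pos=ptc_c_pos,
        nmd_predicted=nmd,
        protein_annotation=annotation,
        domains_lost=_domains_lost(domains, fs_from, inframe_removed),
        category=category,
    )
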