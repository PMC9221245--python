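"""Transcript gene model and coordinate arithmetic.

The model lives entirely in transcript orientation.  Exon boundaries are
expressed in HGVS-style CDS coordinates (``c.``): 1-based, contiguous across
exons, with signed intronic offsets only at the I/O boundary.  Internally all
arithmetic is plain integer work on the spliced transcript.

Sequences are optional.  Length and frame arithmetic work without them;
anything that needs to scan codons raises :class:`SequenceRequiredError`
when they are absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .errors import CoordinateError, InputError, SequenceRequiredError

__all__ = [
    "ExonRecord",
    "TranscriptModel",
    "Locus",
    "DomainRecord",
    "DomainTable",
    "MinigeneLayout",
    "build_rad51c_fixture",
    "rad51c_domain_table",
    "rad51c_minigene_layout",
    "c_to_exon",
    "locus_to_c",
    "attach_from_genomic",
]


@dataclass(frozen=True)
class ExonRecord:
    """One exon, 1-based inclusive boundaries in c. coordinates."""

    index: int
    c_start: int
    c_end: int

    def __post_init__(self) -> None:
        if self.c_end < self.c_start:
            raise InputError(f"exon {self.index}: c_end < c_start")

    @property
    def length(self) -> int:
        return self.c_end - self.c_start + 1


@dataclass(frozen=True)
class Locus:
    """Resolved position: either inside an exon or inside an intron.

    For intronic loci ``intron_index`` is the index of the upstream exon
    (intron *i* separates exon *i* from exon *i+1*), ``side`` is ``"donor"``
    for +offsets and ``"acceptor"`` for -offsets, and ``distance`` is the
    unsigned distance from the splice site (>= 1).
    """

    kind: str  # "exon" | "intron"
    exon_index: Optional[int] = None
    pos_in_exon: Optional[int] = None  # 1-based within the exon
    intron_index: Optional[int] = None
    side: Optional[str] = None
    distance: Optional[int] = None


@dataclass
class TranscriptModel:
    gene_symbol: str
    transcript_id: str
    exons: list[ExonRecord]
    cds_start_c: int = 1
    cds_end_c: int = 0
    exon_sequences: Optional[dict[int, str]] = None
    intron_flanks: Optional[dict[int, tuple[str, str]]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise InputError("model needs at least one exon")
        self.exons = sorted(self.exons, key=lambda e: e.index)
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.index != prev.index + 1:
                raise InputError("exon indices must be consecutive")
            if cur.c_start != prev.c_end + 1:
                raise InputError(
                    f"exons {prev.index}/{cur.index} not contiguous in c. space"
                )
        if not (self.exons[0].c_start <= self.cds_end_c <= self.exons[-1].c_end):
            raise InputError("cds_end_c outside the exon span")
        if self.exon_sequences:
            for idx, seq in self.exon_sequences.items():
                exon = self.exon(idx)
                if len(seq) != exon.length:
                    raise InputError(
                        f"exon {idx}: sequence length {len(seq)} != {exon.length}"
                    )

    # -- structural accessors -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, index: int) -> ExonRecord:
        for e in self.exons:
            if e.index == index:
                return e
        raise CoordinateError(f"no exon {index} in {self.transcript_id}")

    def exon_length(self, index: int) -> int:
        return self.exon(index).length

    def exonic_span(self, first: int, last: int) -> int:
        """Total exonic length of exons ``first..last`` inclusive."""
        return sum(self.exon(i).length for i in range(first, last + 1))

    @property
    def c_min(self) -> int:
        return self.exons[0].c_start

    @property
    def c_max(self) -> int:
        return self.exons[-1].c_end

    @property
    def protein_length(self) -> int:
        """Number of residues encoded by the CDS (stop codon excluded)."""
        n_codons, rem = divmod(self.cds_end_c - self.cds_start_c + 1, 3)
        if rem:
            raise InputError("CDS length is not a multiple of 3")
        return n_codons - 1

    @property
    def has_sequences(self) -> bool:
        return bool(self.exon_sequences) and set(
            e.index for e in self.exons
        ) <= set(self.exon_sequences)

    def require_sequences(self) -> None:
        if not self.has_sequences:
            raise SequenceRequiredError(
                f"{self.transcript_id}: exon sequences are required for this "
                "operation; attach a reference record"
            )

    def intron_flank(self, intron_index: int) -> tuple[str, str]:
        if not self.intron_flanks or intron_index not in self.intron_flanks:
            raise SequenceRequiredError(
                f"no flank sequences stored for intron {intron_index}"
            )
        return self.intron_flanks[intron_index]

    def attach_sequences(
        self,
        exon_sequences: dict[int, str],
        intron_flanks: Optional[dict[int, tuple[str, str]]] = None,
    ) -> None:
        for idx, seq in exon_sequences.items():
            if len(seq) != self.exon(idx).length:
                raise InputError(
                    f"exon {idx}: sequence length {len(seq)} != {self.exon(idx).length}"
                )
        self.exon_sequences = {i: s.upper() for i, s in exon_sequences.items()}
        if intron_flanks is not None:
            self.intron_flanks = {
                i: (d.upper(), a.upper()) for i, (d, a) in intron_flanks.items()
            }

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "gene_symbol": self.gene_symbol,
            "transcript_id": self.transcript_id,
            "cds_start_c": self.cds_start_c,
            "cds_end_c": self.cds_end_c,
            "exons": [
                {"index": e.index, "c_start": e.c_start, "c_end": e.c_end}
                for e in self.exons
            ],
            "metadata": self.metadata,
        }
        if self.exon_sequences:
            d["exon_sequences"] = {str(i): s for i, s in self.exon_sequences.items()}
        if self.intron_flanks:
            d["intron_flanks"] = {
                str(i): [don, acc] for i, (don, acc) in self.intron_flanks.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptModel":
        try:
            exons = [
                ExonRecord(e["index"], e["c_start"], e["c_end"]) for e in d["exons"]
            ]
            return cls(
                gene_symbol=d["gene_symbol"],
                transcript_id=d["transcript_id"],
                exons=exons,
                cds_start_c=d.get("cds_start_c", 1),
                cds_end_c=d["cds_end_c"],
                exon_sequences=(
                    {int(i): s for i, s in d["exon_sequences"].items()}
                    if d.get("exon_sequences")
                    else None
                ),
                intron_flanks=(
                    {int(i): (v[0], v[1]) for i, v in d["intron_flanks"].items()}
                    if d.get("intron_flanks")
                    else None
                ),
                metadata=d.get("metadata", {}),
            )
        except KeyError as exc:
            raise InputError(f"gene model JSON missing key {exc}") from exc

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TranscriptModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def attach_from_genomic(
    model: TranscriptModel,
    genomic: str,
    exon_spans: list[tuple[int, int]],
    flank_len: int = 60,
) -> TranscriptModel:
    """Attach exon sequences and intron flanks sliced from a genomic string.

    ``exon_spans`` holds 0-based half-open coordinates of the model's exons
    within ``genomic`` (transcript orientation, one span per exon in order).
    Intron flanks of up to ``flank_len`` nt are cut from the intervening
    sequence.  Useful for building a sequence-bearing reference from any
    genomic FASTA/GenBank record (e.g. via Bio.SeqIO or pyfaidx).
    """
    if len(exon_spans) != model.n_exons:
        raise InputError(
            f"{len(exon_spans)} spans for {model.n_exons} exons"
        )
    genomic = genomic.upper()
    seqs: dict[int, str] = {}
    flanks: dict[int, tuple[str, str]] = {}
    prev_end = None
    for exon, (start, end) in zip(model.exons, exon_spans):
        if not (0 <= start < end <= len(genomic)):
            raise InputError(f"exon {exon.index}: span outside the genomic record")
        if end - start != exon.length:
            raise InputError(
                f"exon {exon.index}: span length {end - start} != {exon.length}"
            )
        if prev_end is not None:
            if start <= prev_end:
                raise InputError(f"exon {exon.index}: spans overlap or touch")
            half = min(flank_len, (start - prev_end) // 2)
            donor = genomic[prev_end : prev_end + min(flank_len, start - prev_end - half)]
            acceptor = genomic[start - half : start]
            flanks[exon.index - 1] = (donor, acceptor)
        seqs[exon.index] = genomic[start:end]
        prev_end = end
    model.attach_sequences(seqs, flanks)
    return model


# -- domains ------------------------------------------------------------------


@dataclass(frozen=True)
class DomainRecord:
    name: str
    aa_start: int
    aa_end: int
    critical: bool = False

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end or self.aa_start < 1:
            raise InputError(f"domain {self.name}: bad residue range")


@dataclass
class DomainTable:
    entries: list[DomainRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def validate_against(self, model: TranscriptModel) -> None:
        plen = model.protein_length
        for d in self.entries:
            if d.aa_end > plen:
                raise InputError(f"domain {d.name} beyond protein length {plen}")

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("domain_name\taa_start\taa_end\tcritical\n")
            for d in self.entries:
                fh.write(
                    f"{d.name}\t{d.aa_start}\t{d.aa_end}\t"
                    f"{'true' if d.critical else 'false'}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "DomainTable":
        entries = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            want = ["domain_name", "aa_start", "aa_end", "critical"]
            if header != want:
                raise InputError(f"domain TSV header must be {want}")
            for line in fh:
                if not line.strip():
                    continue
                name, s, e, crit = line.rstrip("\n").split("\t")
                entries.append(
                    DomainRecord(name, int(s), int(e), crit.lower() == "true")
                )
        return cls(entries)


@dataclass(frozen=True)
class MinigeneLayout:
    """Which exons the reporter construct carries and how much size the
    vector exons plus primers add to the RT-PCR amplicon."""

    first_exon: int
    last_exon: int
    vector_flank_nt: int

    def __post_init__(self) -> None:
        if self.vector_flank_nt < 0:
            raise InputError("vector_flank_nt must be >= 0")
        if self.last_exon < self.first_exon:
            raise InputError("empty exon range")

    def included_exons(self) -> range:
        return range(self.first_exon, self.last_exon + 1)

    def amplicon_fl(self, model: TranscriptModel) -> int:
        return self.vector_flank_nt + model.exonic_span(self.first_exon, self.last_exon)


# -- coordinate arithmetic ----------------------------------------------------


def c_to_exon(model: TranscriptModel, c_pos: int, intron_offset: int = 0) -> Locus:
    """Resolve a (c. position, intronic offset) pair against the model.

    A zero offset must fall inside an exon; a +k offset requires ``c_pos`` to
    be a donor-side exon end, a -k offset an acceptor-side exon start.
    """
    if not (model.c_min <= c_pos <= model.c_max):
        raise CoordinateError(
            f"c.{c_pos} outside {model.transcript_id} "
            f"({model.c_min}..{model.c_max})"
        )
    if intron_offset == 0:
        for e in model.exons:
            if e.c_start <= c_pos <= e.c_end:
                return Locus(
                    "exon", exon_index=e.index, pos_in_exon=c_pos - e.c_start + 1
                )
        raise CoordinateError(f"c.{c_pos} not in any exon")  # pragma: no cover
    if intron_offset > 0:
        for e in model.exons[:-1]:
            if e.c_end == c_pos:
                return Locus(
                    "intron",
                    intron_index=e.index,
                    side="donor",
                    distance=intron_offset,
                )
        raise CoordinateError(f"c.{c_pos}+{intron_offset}: c.{c_pos} is not an exon end")
    for e in model.exons[1:]:
        if e.c_start == c_pos:
            return Locus(
                "intron",
                intron_index=e.index - 1,
                side="acceptor",
                distance=-intron_offset,
            )
    raise CoordinateError(f"c.{c_pos}{intron_offset}: c.{c_pos} is not an exon start")


def locus_to_c(model: TranscriptModel, locus: Locus) -> tuple[int, int]:
    """Inverse of :func:`c_to_exon`: returns ``(c_pos, intron_offset)``."""
    if locus.kind == "exon":
        e = model.exon(locus.exon_index)
        if not (1 <= locus.pos_in_exon <= e.length):
            raise CoordinateError(f"position {locus.pos_in_exon} outside exon {e.index}")
        return e.c_start + locus.pos_in_exon - 1, 0
    if locus.side == "donor":
        return model.exon(locus.intron_index).c_end, locus.distance
    return model.exon(locus.intron_index + 1).c_start, -locus.distance


# -- reference fixture --------------------------------------------------------

# Exon 2-8 boundaries are fixed by the intron-offset coordinates of the assayed
# variants (e.g. an acceptor variant at c.146-3 and a donor variant at c.404+2
# pin exon 2 to c.146..404).  Exon 1 and exon 9 / CDS end are not derivable the
# same way; they default to the reference-annotation values and are flagged as
# externally sourced.
_RAD51C_EXONS = [
    (1, 1, 145),
    (2, 146, 404),
    (3, 405, 571),
    (4, 572, 705),
    (5, 706, 837),
    (6, 838, 904),
    (7, 905, 965),
    (8, 966, 1026),
    (9, 1027, 1131),
]

RAD51C_CDS_END = 1131  # 376 residues + stop


def build_rad51c_fixture(reference: Optional[str] = None) -> TranscriptModel:
    """RAD51C (NM_058216.3) model with exon 2-8 boundaries pinned by the
    assayed variant coordinates.

    ``reference`` may point to a gene-model JSON carrying exon and intron
    flank sequences (same schema as :meth:`TranscriptModel.to_json`); without
    it the model is sequence-free and supports length/frame arithmetic only.
    """
    model = TranscriptModel(
        gene_symbol="RAD51C",
        transcript_id="NM_058216.3",
        exons=[ExonRecord(i, s, e) for i, s, e in _RAD51C_EXONS],
        cds_start_c=1,
        cds_end_c=RAD51C_CDS_END,
        metadata={
            "exon1_exon9_source": "reference annotation (not assay-derived)",
            "cds_end_verified": False,
        },
    )
    if reference is not None:
        ref = TranscriptModel.from_json(reference)
        if ref.transcript_id != model.transcript_id:
            raise InputError(
                f"reference transcript {ref.transcript_id} != {model.transcript_id}"
            )
        model.attach_sequences(ref.exon_sequences or {}, ref.intron_flanks)
        model.metadata["cds_end_verified"] = ref.metadata.get("cds_end_verified", True)
    return model


def rad51c_minigene_layout() -> MinigeneLayout:
    """Reporter layout: gene exons 2-8 plus 181 nt of vector/primer sequence,
    giving the 1062 nt full-length amplicon."""
    return MinigeneLayout(first_exon=2, last_exon=8, vector_flank_nt=181)


def rad51c_domain_table() -> DomainTable:
    """Functional regions used by the evidence rules.

    Residue ranges are approximate placements consistent with the reported
    exon contents (Walker-B/beta4 and beta5 in exon 5; beta6-9 and the NLS
    encoded from exon 7 onward); they are rule fuel, not structure-grade
    annotation.
    """
    return DomainTable(
        [
            DomainRecord("Walker-B_beta4", 237, 247, critical=True),
            DomainRecord("beta5", 268, 278, critical=True),
            DomainRecord("beta6", 305, 315, critical=True),
            DomainRecord("beta7", 320, 330, critical=True),
            DomainRecord("beta8", 335, 345, critical=True),
            DomainRecord("beta9", 350, 360, critical=True),
            DomainRecord("NLS", 366, 370, critical=True),
        ]
    )
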