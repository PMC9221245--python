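"""Variant pre-selection for splicing assays.

Criteria, applied in order: splice-site proximity window, splice-score
reduction of at least 40%, one variant per splice-site position (with an
exemption for variants additionally predicted to create or activate another
site), at least two database records, and no previously published splicing
assay.  Each rejected variant is audited with the first criterion it failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import InputError
from .gene_model import Locus, TranscriptModel, c_to_exon

__all__ = [
    "CandidateVariant",
    "SelectionPolicy",
    "SelectionResult",
    "in_window",
    "mes_reduction",
    "select",
]


@dataclass(frozen=True)
class NewSitePrediction:
    score: float
    offset_nt: int
    side: str  # donor | acceptor


@dataclass
class CandidateVariant:
    hgvs_c: str
    locus: Locus
    mes_ref_score: float
    mes_alt_score: float
    de_novo_or_cryptic_site: Optional[NewSitePrediction] = None
    clinvar_records: int = 0
    prior_splicing_report: bool = False

    def __post_init__(self) -> None:
        if self.clinvar_records < 0:
            raise InputError(f"{self.hgvs_c}: negative record count")


@dataclass(frozen=True)
class SelectionPolicy:
    intron_window_nt: int = 10
    exon_first_nt: int = 2
    exon_last_nt: int = 3
    min_mes_reduction_percent: float = 40.0
    min_records: int = 2


@dataclass
class SelectionResult:
    selected: list[CandidateVariant]
    audit: list[tuple[str, str]]  # (hgvs_c, "selected" | first failed criterion)

    def reason(self, hgvs_c: str) -> str:
        for v, r in self.audit:
            if v == hgvs_c:
                return r
        raise KeyError(hgvs_c)


def in_window(
    locus: Locus,
    model: Optional[TranscriptModel] = None,
    policy: SelectionPolicy = SelectionPolicy(),
) -> bool:
    """True for intronic positions within the window or exonic positions among
    the first ``exon_first_nt`` / last ``exon_last_nt`` of their exon (the
    exonic check needs the model for exon lengths)."""
    if locus.kind == "intron":
        return locus.distance <= policy.intron_window_nt
    if model is None:
        raise InputError("exonic window check requires the gene model")
    exon = model.exon(locus.exon_index)
    return (
        locus.pos_in_exon <= policy.exon_first_nt
        or locus.pos_in_exon > exon.length - policy.exon_last_nt
    )


def mes_reduction(ref: float, alt: float) -> Optional[float]:
    """Percent score reduction, ``(ref - alt) / ref * 100``.

    Returns None (undefined) for non-positive reference scores instead of
    dividing; negative alt scores legitimately push the reduction past 100%.
    """
    if ref <= 0:
        return None
    return (ref - alt) / ref * 100.0


def _site_key(locus: Locus) -> tuple:
    """Splice-site identity for per-site deduplication."""
    if locus.kind == "intron":
        return (locus.intron_index, locus.side)
    # exonic candidates near the start belong to the acceptor of the upstream
    # intron, near the end to the donor of the downstream intron
    if locus.pos_in_exon <= 2:
        return (locus.exon_index - 1, "acceptor")
    return (locus.exon_index, "donor")


def select(
    variants: list[CandidateVariant],
    model: Optional[TranscriptModel] = None,
    policy: SelectionPolicy = SelectionPolicy(),
) -> SelectionResult:
    """Apply the selection cascade; the audit names exactly one first-failed
    criterion per rejected variant."""
    reasons: dict[str, str] = {}
    stage1: list[CandidateVariant] = []
    for v in variants:
        if not in_window(v.locus, model, policy):
            reasons[v.hgvs_c] = "outside_window"
            continue
        red = mes_reduction(v.mes_ref_score, v.mes_alt_score)
        if red is None:
            reasons[v.hgvs_c] = "undefined_reduction"
            continue
        if red < policy.min_mes_reduction_percent:
            reasons[v.hgvs_c] = f"MES<{policy.min_mes_reduction_percent:.0f}%"
            continue
        stage1.append(v)

    # one variant per splice-site position; ties by records, then reduction,
    # then lexicographic HGVS; variants with a predicted de novo/cryptic site
    # are exempt from deduplication
    by_site: dict[tuple, list[CandidateVariant]] = {}
    for v in stage1:
        by_site.setdefault(_site_key(v.locus), []).append(v)
    stage2: list[CandidateVariant] = []
    for site_variants in by_site.values():
        ranked = sorted(
            site_variants,
            key=lambda v: (
                -v.clinvar_records,
                -(mes_reduction(v.mes_ref_score, v.mes_alt_score) or 0.0),
                v.hgvs_c,
            ),
        )
        keep = {ranked[0].hgvs_c} | {
            v.hgvs_c for v in site_variants if v.de_novo_or_cryptic_site is not None
        }
        for v in site_variants:
            if v.hgvs_c in keep:
                stage2.append(v)
            else:
                reasons[v.hgvs_c] = "site_duplicate"

    selected: list[CandidateVariant] = []
    for v in stage2:
        if v.clinvar_records < policy.min_records:
            reasons[v.hgvs_c] = f"records<{policy.min_records}"
            continue
        if v.prior_splicing_report:
            reasons[v.hgvs_c] = "prior_report"
            continue
        reasons[v.hgvs_c] = "selected"
        selected.append(v)

    order = {v.hgvs_c: i for i, v in enumerate(variants)}
    selected.sort(key=lambda v: order[v.hgvs_c])
    audit = [(v.hgvs_c, reasons[v.hgvs_c]) for v in variants]
    return SelectionResult(selected=selected, audit=audit)
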