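"""Turn capillary-electrophoresis peak tables into transcript fractions.

Peaks below the fluorescence threshold are dropped from both the report and
the denominator; surviving peaks are matched to expected amplicon sizes
within a tolerance (ties resolved toward the larger expected product) or kept
as uncharacterized species named by their rounded size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import InputError, QuantificationError
from .gene_model import MinigeneLayout, TranscriptModel
from .nomenclature import IsoformLabel, format_label

__all__ = [
    "PEAK_COLUMNS",
    "ReadoutEntry",
    "Readout",
    "validate_peak_table",
    "quantify",
    "quantify_all",
    "expected_sizes",
    "uncharacterized_tag",
]

PEAK_COLUMNS = ["variant_id", "replicate", "size_nt", "height_rfu", "area"]

DEFAULT_RFU_MIN = 200.0
DEFAULT_SIZE_TOL_NT = 2.0


@dataclass(frozen=True)
class ReadoutEntry:
    label: str
    mean_percent: float
    sd_percent: float
    isoform: Optional[IsoformLabel] = None

    @property
    def characterized(self) -> bool:
        return self.isoform is not None


@dataclass
class Readout:
    variant_id: str
    entries: list[ReadoutEntry]
    n_replicates: int
    metadata: dict = field(default_factory=dict)

    def fraction(self, label: str) -> float:
        for e in self.entries:
            if e.label == label:
                return e.mean_percent
        return 0.0

    def validate(self, tol: float = 0.2) -> None:
        total = sum(e.mean_percent for e in self.entries)
        if abs(total - 100.0) > tol:
            raise InputError(
                f"{self.variant_id}: transcript fractions sum to {total:.2f}, not 100"
            )
        if any(e.sd_percent < 0 for e in self.entries):
            raise InputError(f"{self.variant_id}: negative SD")


def uncharacterized_tag(size_nt: float) -> str:
    return f"{round(size_nt)} nt"


def validate_peak_table(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise InputError(f"peak table missing columns: {missing}")
    if (peaks["size_nt"] <= 0).any():
        raise InputError("peak table: size_nt must be > 0")
    if (peaks["height_rfu"] < 0).any() or (peaks["area"] < 0).any():
        raise InputError("peak table: height_rfu and area must be >= 0")
    return peaks


def _match_peak(
    size: float,
    expected: Sequence[tuple[IsoformLabel, float]],
    size_tol_nt: float,
) -> Optional[tuple[IsoformLabel, float]]:
    best = None
    for iso, exp_size in expected:
        diff = abs(size - exp_size)
        if diff > size_tol_nt:
            continue
        # nearest match; ties broken toward the larger expected product
        key = (diff, -exp_size)
        if best is None or key < best[0]:
            best = (key, (iso, exp_size))
    return best[1] if best else None


def quantify(
    peaks: pd.DataFrame,
    expected: Sequence[tuple[IsoformLabel, float]],
    rfu_min: float = DEFAULT_RFU_MIN,
    size_tol_nt: float = DEFAULT_SIZE_TOL_NT,
) -> Readout:
    """Quantify one variant's peak table into a :class:`Readout`.

    Per replicate, each surviving peak's share is its area over the total
    surviving area; shares are then averaged across replicates (a transcript
    missing from a replicate counts as 0% there).  SD uses the n-1
    denominator; single-replicate readouts report SD 0 with a warning.
    """
    validate_peak_table(peaks)
    variant_ids = peaks["variant_id"].unique()
    if len(variant_ids) != 1:
        raise InputError(
            f"quantify() expects one variant per table, got {sorted(variant_ids)}"
        )
    variant_id = str(variant_ids[0])

    surviving = peaks[peaks["height_rfu"] >= rfu_min]
    if surviving.empty:
        raise QuantificationError(
            f"{variant_id}: no peaks at or above {rfu_min} RFU"
        )

    per_replicate: dict[int, dict[str, float]] = {}
    label_isoform: dict[str, Optional[IsoformLabel]] = {}
    for rep, group in surviving.groupby("replicate"):
        total = group["area"].sum()
        if total <= 0:
            raise QuantificationError(f"{variant_id}: replicate {rep} has zero area")
        shares: dict[str, float] = {}
        for _, row in group.iterrows():
            match = _match_peak(row["size_nt"], expected, size_tol_nt)
            if match is not None:
                label = format_label(match[0])
                label_isoform.setdefault(label, match[0])
            else:
                label = uncharacterized_tag(row["size_nt"])
                label_isoform.setdefault(label, None)
            shares[label] = shares.get(label, 0.0) + row["area"] / total * 100.0
        per_replicate[int(rep)] = shares

    n = len(per_replicate)
    if n == 1:
        warnings.warn(
            f"{variant_id}: single replicate; reporting SD 0", stacklevel=2
        )
    labels = sorted(label_isoform)
    entries = []
    for label in labels:
        values = [per_replicate[r].get(label, 0.0) for r in sorted(per_replicate)]
        mean = sum(values) / n
        if n > 1:
            var = sum((v - mean) ** 2 for v in values) / (n - 1)
            sd = math.sqrt(var)
        else:
            sd = 0.0
        entries.append(ReadoutEntry(label, mean, sd, label_isoform[label]))
    entries.sort(key=lambda e: -e.mean_percent)
    readout = Readout(
        variant_id=variant_id,
        entries=entries,
        n_replicates=n,
        metadata={
            "rfu_min": rfu_min,
            "size_tol_nt": size_tol_nt,
            "subthreshold_policy": "excluded from report and denominator",
        },
    )
    readout.validate(tol=1e-6)
    return readout


def quantify_all(
    peaks: pd.DataFrame,
    expected: Sequence[tuple[IsoformLabel, float]],
    rfu_min: float = DEFAULT_RFU_MIN,
    size_tol_nt: float = DEFAULT_SIZE_TOL_NT,
) -> list[Readout]:
    """Quantify a multi-variant peak table, one readout per variant."""
    validate_peak_table(peaks)
    return [
        quantify(group, expected, rfu_min=rfu_min, size_tol_nt=size_tol_nt)
        for _, group in peaks.groupby("variant_id", sort=True)
    ]


def expected_sizes(
    model: TranscriptModel,
    layout: MinigeneLayout,
    isoforms: Sequence[IsoformLabel],
) -> list[tuple[IsoformLabel, float]]:
    """Expected RT-PCR amplicon size for each isoform in reporter context:
    vector flank plus the included gene exons, with event deltas applied."""
    exon_lengths = {e.index: e.length for e in model.exons}
    fl = layout.amplicon_fl(model)
    out = []
    for iso in isoforms:
        delta = 0
        for ev in iso.events:
            if not (layout.first_exon <= ev.exon_from <= layout.last_exon):
                raise InputError(
                    f"event on exon {ev.exon_from} outside reporter exons "
                    f"{layout.first_exon}-{layout.last_exon}"
                )
            delta += ev.net_length_change(exon_lengths)
        out.append((iso, float(fl + delta)))
    return out
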