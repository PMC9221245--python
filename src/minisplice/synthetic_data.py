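"""Synthetic gene models, readouts, and raw peak tables.

Everything is reproducible from the single seeded generator in
:class:`SimulationConfig`; ground truth is returned alongside every simulated
artifact so recovery tests are self-describing.  Peak-area noise is
multiplicative lognormal, matching the small coefficients of variation seen
in triplicate fragment-electrophoresis data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .fragment_quant import PEAK_COLUMNS, Readout, ReadoutEntry
from .gene_model import ExonRecord, MinigeneLayout, TranscriptModel
from .nomenclature import IsoformLabel, format_label, parse_label

__all__ = ["SimulationConfig", "simulate_gene", "simulate_readout"]

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_exons: int = 5
    exon_length_range: tuple[int, int] = (60, 150)
    exon_lengths: Optional[Sequence[int]] = None  # overrides the range
    intron_flank_length: int = 60
    isoform_labels: Optional[Sequence[str]] = None
    true_isoform_fractions: Sequence[float] = (80.0, 20.0)
    replicate_noise_cv: float = 0.01
    n_replicates: int = 3
    total_area: float = 1e6
    rfu_per_area: float = 0.1
    rfu_baseline: float = 0.0
    size_jitter_sd: float = 0.2
    forced_heights: dict = field(default_factory=dict)  # label -> RFU override

    def __post_init__(self) -> None:
        if self.n_exons < 3:
            raise InputError("need at least 3 exons")
        if self.replicate_noise_cv < 0:
            raise InputError("noise CV must be >= 0")
        if abs(sum(self.true_isoform_fractions) - 100.0) > 1e-6:
            raise InputError("true fractions must sum to 100")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def resolved_labels(self) -> list[str]:
        if self.isoform_labels is not None:
            labels = list(self.isoform_labels)
        else:
            # FL plus skips of successive internal exons
            labels = ["FL"] + [
                f"Δ(E{i})" for i in range(2, 2 + len(self.true_isoform_fractions) - 1)
            ]
        if len(labels) != len(self.true_isoform_fractions):
            raise InputError("labels and fractions must align")
        return labels


def simulate_gene(config: SimulationConfig) -> TranscriptModel:
    """Random transcript model with sequences: an uninterrupted reading frame
    across all exons, canonical GT/AG intron flank dinucleotides, and a stop
    codon at the CDS end.  Deterministic under the config seed."""
    rng = config.rng()
    if config.exon_lengths is not None:
        lengths = list(config.exon_lengths)
        if len(lengths) != config.n_exons:
            raise InputError("exon_lengths must match n_exons")
    else:
        lo, hi = config.exon_length_range
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_exons)]
    total = sum(lengths)
    n_codons = total // 3
    utr_tail = total - n_codons * 3
    codons = ["ATG"] + [
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons - 2)
    ] + ["TAA"]
    spliced = "".join(codons) + "".join(rng.choice(list("ACGT"), utr_tail))
    assert len(spliced) == total

    exons, seqs = [], {}
    c = 1
    for idx, length in enumerate(lengths, start=1):
        exons.append(ExonRecord(idx, c, c + length - 1))
        seqs[idx] = spliced[c - 1 : c - 1 + length]
        c += length

    k = config.intron_flank_length
    flanks = {}
    for idx in range(1, config.n_exons):
        donor = "GT" + "".join(rng.choice(list("ACGT"), max(k - 2, 0)))
        acceptor = "".join(rng.choice(list("ACGT"), max(k - 2, 0))) + "AG"
        flanks[idx] = (donor, acceptor)

    return TranscriptModel(
        gene_symbol="SIMGENE",
        transcript_id=f"SIM_{config.seed}",
        exons=exons,
        cds_start_c=1,
        cds_end_c=n_codons * 3,
        exon_sequences=seqs,
        intron_flanks=flanks,
        metadata={"simulated": True, "seed": config.seed},
    )


def _expected_native_sizes(
    model: TranscriptModel, isoforms: Sequence[IsoformLabel]
) -> list[float]:
    exon_lengths = {e.index: e.length for e in model.exons}
    fl = sum(exon_lengths.values())
    sizes = []
    for iso in isoforms:
        delta = sum(ev.net_length_change(exon_lengths) for ev in iso.events)
        sizes.append(float(fl + delta))
    return sizes


def simulate_readout(
    model: TranscriptModel,
    config: SimulationConfig,
    variant_id: str = "sim",
    layout: Optional[MinigeneLayout] = None,
) -> tuple[pd.DataFrame, Readout]:
    """Simulate replicate peak tables for the configured isoform mixture.

    Returns the raw peak table (one row per replicate x isoform) and the
    ground-truth readout.  Areas are ``fraction x total_area x LogNormal`` with
    the configured CV; heights scale with area unless overridden via
    ``forced_heights`` (to place deliberate sub-threshold peaks).
    """
    rng = config.rng()
    labels = config.resolved_labels()
    isoforms = [parse_label(label) for label in labels]
    if layout is not None:
        from .fragment_quant import expected_sizes

        sizes = [s for _, s in expected_sizes(model, layout, isoforms)]
    else:
        sizes = _expected_native_sizes(model, isoforms)

    cv = config.replicate_noise_cv
    sigma = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for label, frac, size in zip(labels, config.true_isoform_fractions, sizes):
            if frac <= 0:
                continue
            noise = float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma)) if sigma else 1.0
            area = frac / 100.0 * config.total_area * noise
            if label in config.forced_heights:
                height = float(config.forced_heights[label])
            else:
                height = config.rfu_baseline + area * config.rfu_per_area
            jitter = float(rng.normal(0.0, config.size_jitter_sd)) if config.size_jitter_sd else 0.0
            rows.append(
                {
                    "variant_id": variant_id,
                    "replicate": rep,
                    "size_nt": size + jitter,
                    "height_rfu": height,
                    "area": area,
                }
            )
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)

    truth = Readout(
        variant_id=variant_id,
        entries=[
            ReadoutEntry(
                label=format_label(iso),
                mean_percent=float(frac),
                sd_percent=0.0,
                isoform=iso,
            )
            for iso, frac in zip(isoforms, config.true_isoform_fractions)
        ],
        n_replicates=config.n_replicates,
        metadata={"ground_truth": True, "seed": config.seed},
    )
    return peaks, truth
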