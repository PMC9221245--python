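# minisplice

Turn minigene splicing-assay readouts into ACMG/AMP point-based clinical
classifications. The package covers the full analysis chain for splice-site
variants assayed in a splicing-reporter construct:

1. **gene_model** — transcript architecture in HGVS `c.` coordinates
   (intronic offsets supported), functional domain table, reporter layout,
   and coordinate arithmetic. Ships a RAD51C (NM_058216.3) fixture whose
   exon 2–8 boundaries are pinned by the assayed variant coordinates.
2. **nomenclature** — parser/serializer for the compact transcript label
   grammar: `Δ(E5)` (exon skip), `Δ(E2p3)`/`Δ(E2q175)` (alternative
   acceptor/donor inside the exon), `▼(E8p3)`/`▼(E6q4)` (intronic
   retention at the acceptor/donor), optional `-a`/`-b` allele tags, `FL`.
   ASCII aliases `D(...)`/`v(...)` are accepted on input.
3. **consequence** — applies a DNA variant (on the pre-mRNA, before
   splicing) plus a splice-event set to the model and derives frame status,
   first in-frame premature termination codon, NMD susceptibility (50-nt
   boundary rule against the transcript's last exon–exon junction),
   best-effort protein annotation, and lost domains. Works in pure
   length-arithmetic mode without sequences; PTC/NMD scanning requires a
   sequence-bearing model.
4. **fragment_quant** — converts capillary-electrophoresis peak tables
   (replicate, size, height, area) into transcript fractions: peaks below
   200 RFU are dropped from report *and* denominator, survivors are matched
   to expected amplicon sizes within ±2 nt (ties toward the larger
   product), unmatched peaks become `"<size> nt"` species; mean ± SD across
   replicates (n−1 denominator).
5. **acmg** — per-transcript evidence calls (PTC+NMD → very strong;
   NMD-escaping PTC → strong, upgraded to very strong on critical-domain
   loss; in-frame → very strong on whole-critical-domain removal, else
   supporting with a deleterious in-silico score; wild-type full length →
   benign strong), aggregation into a `PVS1_O`/`BP7_O` code (≥90%
   expression share to apply; weakest strength among transcripts
   individually >10%), the `PM2_P` rarity rule (allele frequency ≤0.01%),
   and the point-sum classifier (P ≥ +10, LP +6..+9, VUS 0..+5, LB −6..−1,
   B ≤ −7). Assay-derived codes replace predictive codes (PVS1/PP3/BP4).
6. **candidate_filter** — variant pre-selection: splice-site window
   (intronic ±10, first 2 / last 3 exonic nt), ≥40% splice-score
   reduction, one variant per splice site (de novo/cryptic-site carriers
   exempt), ≥2 database records, no prior published assay; audited.
7. **synthetic_data** — seeded simulators for sequence-bearing gene models
   and replicate peak tables with lognormal area noise; ground truth is
   returned with every artifact.
8. **io / cli** — TSV/CSV/JSON formats, packaged fixture tables, and the
   end-to-end `classify` pipeline with deterministic outputs.

On the bundled RAD51C cohort (20 splice-site variants, triplicate
fluorescent RT-PCR fractions, gnomAD v2.1 allele counts) the pipeline
reproduces all 20 published verdicts: 16 likely pathogenic (+9 points each)
and 4 of uncertain significance.

## CLI

```bash
# end-to-end verdicts from the packaged fixture tables
minisplice classify --out-dir out/

# your own cohort
minisplice classify --readouts readouts.tsv --variants variants.tsv \
    --model model.json --rules rules.json --out-dir out/

# simulate a gene + peak table, then quantify it
minisplice simulate --seed 1 --fractions 73.8,25.1,1.1 --out-dir sim/
minisplice peaks --peaks sim/peaks.csv --model sim/model.json \
    --isoforms "FL,Δ(E2),Δ(E3)" --out sim/readout.tsv

# one variant x transcript consequence
minisplice annotate --model src/minisplice/data/rad51c_model.json \
    --variant c.965+1G>A --isoform "D(E7)"

# candidate pre-selection with audit trail
minisplice filter --variants candidates.tsv --model model.json --out-dir out/

# pretty-print a verdict table
minisplice report --verdicts out/verdicts.tsv
```

Exit codes: 0 success, 1 validation error, 2 internal error. `--ascii`
writes `D`/`v` instead of `Δ`/`▼`.

### File formats

- **gene model** (JSON): `gene_symbol`, `transcript_id`, `cds_start_c`,
  `cds_end_c`, `exons: [{index, c_start, c_end}]`, optional
  `exon_sequences: {index: seq}` and
  `intron_flanks: {index: [donor_seq, acceptor_seq]}`.
- **readout TSV**: `variant_id, label, mean_percent, sd_percent` plus
  optional `category` (`FL | PTC_NMD | PTC_escape | in_frame |
  uncharacterized`), `critical_domain_lost`, `variant_on_transcript`,
  `provean`, `revel`. When `category` is omitted it is derived with the
  consequence engine (requires sequences).
- **variant TSV**: `hgvs_c, allele_count, allele_number` plus optional
  `predictive_code`, splice-score columns. Allele counts are supplied by
  the data preparer (no live population-database queries); when a variant
  is absent from the population database, substitute the allele number of
  the closest genotyped proxy SNP yourself before building the table.
- **peak CSV**: `variant_id, replicate, size_nt, height_rfu, area`.
- **domains TSV**: `domain_name, aa_start, aa_end, critical`.

## Sequence-dependent analyses

The bundled RAD51C model is sequence-free: frame arithmetic, amplicon
sizes, evidence aggregation and classification all work without sequences.
PTC/NMD scanning and protein annotations additionally need exon sequences
and intron flanks. Build a reference once from any local copy of the
transcript's genomic region:

```python
from minisplice.gene_model import build_rad51c_fixture, attach_from_genomic

model = build_rad51c_fixture()
# genomic: string of the gene region in transcript orientation
# spans: 0-based half-open coordinates of exons 1-9 within that string
attach_from_genomic(model, genomic, spans, flank_len=60)
model.to_json("rad51c_reference.json")
```

Point `MINISPLICE_RAD51C_REFERENCE` at that JSON to enable the
sequence-dependent acceptance tests and the `t10`/`t11` targets of the
acceptance report.

## Notes on the bundled fixtures

- Exon 1, exon 9, and the CDS end are not derivable from the assay
  coordinates; the fixture carries reference-annotation values flagged
  `cds_end_verified: false`.
- Domain residue ranges in `rad51c_domains.tsv` are approximate placements
  consistent with the reported exon contents; they drive the evidence
  rules, not structural claims.
- The readout table stores unrounded fractions; displayed tables elsewhere
  may round (e.g. 25.1% shown as 26%).
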