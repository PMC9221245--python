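{
 "cds_end_c": 1131,
 "cds_start_c": 1,
 "exons": [
  {
   "c_end": 145,
   "c_start": 1,
   "index": 1
  },
  {
   "c_end": 404,
   "c_start": 146,
   "index": 2
  },
  {
   "c_end": 571,
   "c_start": 405,
   "index": 3
  },
  {
   "c_end": 705,
   "c_start": 572,
   "index": 4
  },
  {
   "c_end": 837,
   "c_start": 706,
   "index": 5
  },
  {
   "c_end": 904,
   "c_start": 838,
   "index": 6
  },
  {
   "c_end": 965,
   "c_start": 905,
   "index": 7
  },
  {
   "c_end": 1026,
   "c_start": 966,
   "index": 8
  },
  {
   "c_end": 1131,
   "c_start": 1027,
   "index": 9
  }
 ],
 "gene_symbol": "RAD51C",
 "metadata": {
  "cds_end_verified": false,
  "exon1_exon9_source": "reference annotation (not assay-derived)"
 },
 "transcript_id": "NM_058216.3"
}
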