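hgvs_c	clinvar_accession	allele_count	allele_number	mes_ref	mes_alt	new_site_score	new_site_offset_nt	predictive_code
c.146-4_146-2del	VCV000482181.5	0	250394	9.5	-0.8	5.9	3	PVS1
c.146-3C>G	VCV000484752.4	0	250394	9.5	1.9			PP3
c.404+2T>C	VCV000182835.10	1	246102	4.8	-3.0	5.4	27	PVS1
c.404+3A>G	VCV000409857.4	0	246102	4.8	0.6	5.4	27	PP3
c.405-1G>C	VCV000141823.5	0	251476	7.7	-0.4	4.2	7	PVS1
c.571+1del	VCV000482176.8	1	251452	10.5	-14.1	11.1	-1	PVS1
c.572-3C>G	VCV000633386.5	0	251198	7.4	-1.4			PP3
c.572-1G>C	VCV000480497.10	0	251220	7.4	-0.6			PVS1
c.705+1G>A	VCV000230577.9	0	251038	9.1	0.9			PVS1
c.705+3A>G	VCV000241775.7	0	250946	9.1	4.6	6.1	2	PP3
c.706-1G>T	VCV000452310.4	0	282746	11.1	2.5	4.3	10	PVS1
c.837+1G>T	VCV000241779.3	0	251374	8.6	0.1			PVS1
c.837+4_837+7del	VCV000128212.8	0	251374	8.6	-8.9			PP3
c.838-2A>G	VCV000480508.3	0	250982	10.2	2.2			PVS1
c.904G>A	VCV000478781.9	0	250832	5.6	1.0	6.2	4	PP3
c.904+1G>T	VCV000480510.7	0	250832	5.6	-3.0	6.2	4	PVS1
c.905-3_906del	VCV000182846.7	0	282730	8.2	-8.6	4.5	7	PVS1
c.905-2del	VCV000230587.7	0	282730	8.2	2.1			PVS1
c.965+1G>A	VCV000182838.5	0	251118	8.7	0.5			PVS1
c.966-1G>C	VCV000851327.3	0	251358	7.3	-0.8	6.8	-3	PVS1
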