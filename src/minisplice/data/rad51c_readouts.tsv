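variant_id	label	mean_percent	sd_percent	category	critical_domain_lost	variant_on_transcript	provean	revel
WT	FL	98.6	0.2	FL				
WT	1106 nt	1.4	0.2	uncharacterized				
c.146-4_146-2del	Δ(E2)	73.8	0.8	PTC_NMD				
c.146-4_146-2del	Δ(E2p3)	25.1	0.4	in_frame	false		-10.29	
c.146-4_146-2del	657 nt	1.1	0.9	uncharacterized				
c.146-3C>G	Δ(E2)	94.8	0.9	PTC_NMD				
c.146-3C>G	Δ(E2p3)	5.2	0.9	in_frame	false		-10.29	
c.404+2T>C	▼(E2q27)-a	77.2	1.3	PTC_NMD		true		
c.404+2T>C	Δ(E2)	16.7	0.3	PTC_NMD				
c.404+2T>C	Δ(E2q175)	4.7	0.1	PTC_NMD				
c.404+2T>C	657 nt	1.4	1.2	uncharacterized				
c.404+3A>G	FL	26.3	0.4	FL		false		
c.404+3A>G	▼(E2q27)-b	66.4	1.6	PTC_NMD		true		
c.404+3A>G	Δ(E2q175)	5.4	0.3	PTC_NMD				
c.404+3A>G	657 nt	1.9	1.6	uncharacterized				
c.405-1G>C	Δ(E3p7)	48.9	1.6	PTC_NMD				
c.405-1G>C	Δ(E3)	48.2	1.2	PTC_NMD				
c.405-1G>C	813 nt	2.9	0.3	uncharacterized				
c.571+1del	Δ(E3q1)	98.4	1.4	PTC_NMD				
c.571+1del	800 nt	1.6	1.4	uncharacterized				
c.572-3C>G	Δ(E4)	94.7	0.3	PTC_NMD				
c.572-3C>G	1063 nt	3.0	0.2	uncharacterized				
c.572-3C>G	1008 nt	2.3	0.1	uncharacterized				
c.572-1G>C	Δ(E4)	93.8	0.0	PTC_NMD				
c.572-1G>C	1008 nt	3.2	0.0	uncharacterized				
c.572-1G>C	1063 nt	1.5	0.0	uncharacterized				
c.572-1G>C	976 nt	1.5	0.0	uncharacterized				
c.705+1G>A	Δ(E4)	100.0	0.0	PTC_NMD				
c.705+3A>G	FL	21.3	1.3	FL		false		
c.705+3A>G	Δ(E4)	78.7	1.3	PTC_NMD				
c.706-1G>T	Δ(E5p10)	100.0	0.0	PTC_NMD				
c.837+1G>T	Δ(E5)	95.3	0.4	in_frame	true			
c.837+1G>T	976 nt	4.7	0.4	uncharacterized				
c.837+4_837+7del	Δ(E5)	100.0	0.0	in_frame	true			
c.838-2A>G	Δ(E6)	98.4	1.4	PTC_NMD				
c.838-2A>G	590 nt	1.6	0.4	uncharacterized				
c.904G>A	FL	2.4	0.1	FL		true		0.5
c.904G>A	▼(E6q4)-a	97.6	0.1	PTC_escape	true	true		
c.904+1G>T	▼(E6q4)-b	100.0	0.0	PTC_escape	true	true		
c.905-3_906del	Δ(E7)	100.0	0.0	PTC_escape	true			
c.905-2del	Δ(E7)	100.0	0.0	PTC_escape	true			
c.965+1G>A	Δ(E7)	100.0	0.0	PTC_escape	true			
c.966-1G>C	Δ(E8)	20.6	0.1	PTC_escape	true			
c.966-1G>C	▼(E8p3)	79.4	0.1	in_frame	false	true	-11.94	
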