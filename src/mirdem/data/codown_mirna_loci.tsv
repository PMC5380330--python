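name	accession	chromosome	start	end
hsa-miR-30c-5p	MIMAT0000244	Chr1	41222977	41222994
hsa-miR-30e-5p	MIMAT0000692	Chr1	41220048	41220064
hsa-miR-30e-3p	MIMAT0000693	Chr1	41220089	41220106
hsa-miR-29b-3p	MIMAT0000100	Chr1	207975861	207975841
hsa-miR-29c-3p	MIMAT0000681	Chr1	207975271	207975250
hsa-miR-143-3p	MIMAT0000435	Chr5	148808547	148808561
hsa-miR-145-5p	MIMAT0000437	Chr5	148810229	148810246
hsa-miR-340-5p	MIMAT0004692	Chr5	179442339	179442321
hsa-miR-340-3p	MIMAT0000750	Chr5	179442381	179442361
hsa-miR-30b-5p	MIMAT0000420	Chr8	135812800	135812783
hsa-miR-30d-5p	MIMAT0000245	Chr8	135817145	135817132
hsa-miR-151a-5p	MIMAT0004697	Chr8	141742693	141742677
hsa-miR-151a-3p	MIMAT0000757	Chr8	141742729	141742713
hsa-miR-23b-3p	MIMAT0000418	Chr9	97847551	97847567
hsa-miR-27b-3p	MIMAT0000419	Chr9	97847790	97847807
hsa-miR-126-3p	MIMAT0000445	Chr9	139565109	139565126
hsa-miR-126-5p	MIMAT0000444	Chr9	139565068	139565088
hsa-miR-376a-3p	MIMAT0000729	Chr14	101506457	101506475
hsa-miR-376c-3p	MIMAT0000720	Chr14	101506071	101506089
hsa-miR-22-5p	MIMAT0004495	Chr17	1617232	1617215
hsa-miR-22-3p	MIMAT0000077	Chr17	1617270	1617252
hsa-miR-451a	MIMAT0001631	Chr17	27188424	27188403
hsa-miR-144-5p	MIMAT0004600	Chr17	27188586	27188565
hsa-miR-144-3p	MIMAT0000436	Chr17	27188621	27188602
hsa-miR-193a-5p	MIMAT0004614	Chr17	29887045	29887056
hsa-miR-193a-3p	MIMAT0000459	Chr17	29887075	29887090
hsa-miR-142-5p	MIMAT0000433	Chr17	56408628	56408611
hsa-miR-142-3p	MIMAT0000434	Chr17	56408666	56408645
hsa-miR-99b-5p	MIMAT0000689	Chr19	52195877	52195892
hsa-let-7e-5p	MIMAT0000066	Chr19	52196049	52196067
hsa-miR-125a-5p	MIMAT0000443	Chr19	52196527	52196544
hsa-miR-362-3p	MIMAT0004683	ChrX	49773616	49773634
hsa-miR-660-5p	MIMAT0003338	ChrX	49777867	49777885
hsa-miR-223-5p	MIMAT0004570	ChrX	65238737	65238758
hsa-miR-223-3p	MIMAT0000280	ChrX	65238780	65238800
hsa-miR-542-5p	MIMAT0003340	ChrX	133675408	133675390
hsa-miR-542-3p	MIMAT0003389	ChrX	133675444	133675424
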