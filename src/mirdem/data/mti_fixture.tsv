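mirna	gene	evidence
hsa-let-7c	FasL	curated
hsa-let-7c	Trail	curated
hsa-let-7c	OSM	curated
hsa-miR-199a-5p	GZMB	curated
hsa-miR-199b-5p	GZMB	curated
hsa-miR-30e-5p	PRF1	curated
hsa-miR-30e-5p	TNF-a	curated
hsa-miR-30e-5p	CD40LG	curated
hsa-miR-155-5p	OSM	curated
hsa-miR-155-5p	TNF-a	curated
hsa-miR-155-5p	CD40LG	curated
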