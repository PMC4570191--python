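category	vs	rs
raw_reads	19168474	18052596
high_quality	19048317	17949618
clean_reads	18948210	17893663
adapter3_null	11289	7163
insert_null	7544	1605
adapter5_contaminant	53199	21828
shorter_than_18nt	25663	22629
polyA	2412	2730
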