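metric	CE01	CE02	CE03	CE04	Average
Clean reads	11640333	10922961	11573957	20255682	13598233
Unique sRNAs	365682	469182	426731	219056	370163
Clean reads for miRNAs	7686565	6746516	6772031	15351472	9139146
Unique sRNAs for miRNAs	5845	4705	5319	4116	4996
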