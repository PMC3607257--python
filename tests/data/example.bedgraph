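# synthetic example coverage track for parser tests
track type=bedGraph name="example" description="toy depth"
# comment inside the data block
chr1	0	100	3
chr1	100	250	7.5
chr1	400	500	1
chr2	0	50	2
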