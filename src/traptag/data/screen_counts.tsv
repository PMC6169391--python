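# Promoter-trap remobilization screen of An. stephensi: individuals
# screened and reporter-positive events per donor line.
line_id	locus_label	n_screened	n_events
DO-05-13-F1C	3R (34A)	37500	121
DO-05-13-F1D	3L (45C)	22613	68
DO-05-13-F2A	n/a	34918	274
DO-05-13-F2B	X (6A)	11847	7
DO-05-13-M1	3L (46C)	17500	150
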