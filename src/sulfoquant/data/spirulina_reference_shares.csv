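analyte,share_pct_uhplc_hrms,share_pct_mrm
555,49.45,18.35
791,3.63,5.06
793,5.89,9.36
815,4.94,9.54
817,12.93,21.63
819,2.55,13.55
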