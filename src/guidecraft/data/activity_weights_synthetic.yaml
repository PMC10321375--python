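# SYNTHETIC linear activity model (generated by scripts/make_default_tables.py).
# Shape of a published linear on-target model -- 30-nt context of
# 4 nt upstream flank + 20-nt spacer + 3-nt PAM + 3 nt downstream --
# with synthetic weights; replace with empirically fitted weights for
# publication-grade activity prediction.
source_tag: synthetic-linear-activity-v1
context_length: 30
spacer_start: 4
spacer_length: 20
gc_optimum: 10
intercept: 0.59764
gc_low: -0.20263
gc_high: -0.16659
positional:
  "1:C": 0.05944
  "2:A": -0.0477
  "3:C": 0.16567
  "4:C": -0.1691
  "6:C": -0.00054
  "7:T": 0.03937
  "8:G": -0.14423
  "10:T": -0.19493
  "11:C": -0.10167
  "15:T": -0.0557
  "17:C": 0.15021
  "18:G": 0.00586
  "19:C": 0.00609
  "21:G": 0.17268
  "22:C": -0.01678
  "23:A": 0.11349
  "26:T": -0.00918
  "27:G": -0.04787
dinucleotide:
  "3:CG": -0.00855
  "4:GC": 0.01692
  "5:TT": -0.00167
  "8:AG": 0.0012
  "9:GT": 0.00657
  "10:TT": 0.00525
  "21:AC": -0.02825
  "24:AC": -0.0531
  "26:TC": -0.00748
  "28:AA": -0.06088
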