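# SYNTHETIC PAM penalties: model	masked_pam_key	penalty
# keys mask positions that are N in the canonical pattern back to N;
# canonical PAMs score 1.0, relaxed (first fixed position degenerated)
# PAMs score the per-base penalty below.
#source	synthetic-cfd-shape-v1
SpCas9-NGG	NGG	1.0000
SpCas9-NGG	NAG	0.2600
SpCas9-NGG	NCG	0.1100
SpCas9-NGG	NTG	0.0700
SpCas9-NAG	NAG	1.0000
SpCas9-NAG	NCG	0.1100
SpCas9-NAG	NGG	0.2000
SpCas9-NAG	NTG	0.0700
SpCas9-NG	NG	1.0000
SpCas9-NG	NA	0.2600
SpCas9-NG	NC	0.1100
SpCas9-NG	NT	0.0700
xCas9-NG	NG	1.0000
xCas9-NG	NA	0.2600
xCas9-NG	NC	0.1100
xCas9-NG	NT	0.0700
SpG-NGN	NGN	1.0000
SpG-NGN	NAN	0.2600
SpG-NGN	NCN	0.1100
SpG-NGN	NTN	0.0700
SpRY-NRN	NAN	1.0000
SpRY-NRN	NGN	1.0000
SpRY-NRN	NCN	0.1100
SpRY-NRN	NTN	0.0700
ScCas9-NNG	NNG	1.0000
ScCas9-NNG	NNA	0.2600
ScCas9-NNG	NNC	0.1100
ScCas9-NNG	NNT	0.0700
FnCas9-NGG	NGG	1.0000
FnCas9-NGG	NAG	0.2600
FnCas9-NGG	NCG	0.1100
FnCas9-NGG	NTG	0.0700
SaCas9-NNGRRT	NNGAAT	1.0000
SaCas9-NNGRRT	NNGAGT	1.0000
SaCas9-NNGRRT	NNGGAT	1.0000
SaCas9-NNGRRT	NNGGGT	1.0000
SaCas9-NNGRRT	NNAAAT	0.2600
SaCas9-NNGRRT	NNAAGT	0.2600
SaCas9-NNGRRT	NNAGAT	0.2600
SaCas9-NNGRRT	NNAGGT	0.2600
SaCas9-NNGRRT	NNCAAT	0.1100
SaCas9-NNGRRT	NNCAGT	0.1100
SaCas9-NNGRRT	NNCGAT	0.1100
SaCas9-NNGRRT	NNCGGT	0.1100
SaCas9-NNGRRT	NNTAAT	0.0700
SaCas9-NNGRRT	NNTAGT	0.0700
SaCas9-NNGRRT	NNTGAT	0.0700
SaCas9-NNGRRT	NNTGGT	0.0700
SaCas9KKH-NNNRRT	NNNAAT	1.0000
SaCas9KKH-NNNRRT	NNNAGT	1.0000
SaCas9KKH-NNNRRT	NNNGAT	1.0000
SaCas9KKH-NNNRRT	NNNGGT	1.0000
SaCas9KKH-NNNRRT	NNNCAT	0.1100
SaCas9KKH-NNNRRT	NNNCGT	0.1100
SaCas9KKH-NNNRRT	NNNTAT	0.0700
SaCas9KKH-NNNRRT	NNNTGT	0.0700
NmeCas9-NNNNGATT	NNNNGATT	1.0000
NmeCas9-NNNNGATT	NNNNAATT	0.2600
NmeCas9-NNNNGATT	NNNNCATT	0.1100
NmeCas9-NNNNGATT	NNNNTATT	0.0700
CjCas9-NNNNRYAC	NNNNACAC	1.0000
CjCas9-NNNNRYAC	NNNNATAC	1.0000
CjCas9-NNNNRYAC	NNNNGCAC	1.0000
CjCas9-NNNNRYAC	NNNNGTAC	1.0000
CjCas9-NNNNRYAC	NNNNCCAC	0.1100
CjCas9-NNNNRYAC	NNNNCTAC	0.1100
CjCas9-NNNNRYAC	NNNNTCAC	0.0700
CjCas9-NNNNRYAC	NNNNTTAC	0.0700
StCas9-NNAGAAW	NNAGAAA	1.0000
StCas9-NNAGAAW	NNAGAAT	1.0000
StCas9-NNAGAAW	NNCGAAA	0.1100
StCas9-NNAGAAW	NNCGAAT	0.1100
StCas9-NNAGAAW	NNGGAAA	0.2000
StCas9-NNAGAAW	NNGGAAT	0.2000
StCas9-NNAGAAW	NNTGAAA	0.0700
StCas9-NNAGAAW	NNTGAAT	0.0700
Cas12a-TTTV	TTTA	1.0000
Cas12a-TTTV	TTTC	1.0000
Cas12a-TTTV	TTTG	1.0000
Cas12a-TTTV	ATTA	0.2600
Cas12a-TTTV	ATTC	0.2600
Cas12a-TTTV	ATTG	0.2600
Cas12a-TTTV	CTTA	0.1100
Cas12a-TTTV	CTTC	0.1100
Cas12a-TTTV	CTTG	0.1100
Cas12a-TTTV	GTTA	0.2000
Cas12a-TTTV	GTTC	0.2000
Cas12a-TTTV	GTTG	0.2000
LbCas12a-TTTV	TTTA	1.0000
LbCas12a-TTTV	TTTC	1.0000
LbCas12a-TTTV	TTTG	1.0000
LbCas12a-TTTV	ATTA	0.2600
LbCas12a-TTTV	ATTC	0.2600
LbCas12a-TTTV	ATTG	0.2600
LbCas12a-TTTV	CTTA	0.1100
LbCas12a-TTTV	CTTC	0.1100
LbCas12a-TTTV	CTTG	0.1100
LbCas12a-TTTV	GTTA	0.2000
LbCas12a-TTTV	GTTC	0.2000
LbCas12a-TTTV	GTTG	0.2000
FnCas12a-TTN	TTN	1.0000
FnCas12a-TTN	ATN	0.2600
FnCas12a-TTN	CTN	0.1100
FnCas12a-TTN	GTN	0.2000
Cas12b-TTN	TTN	1.0000
Cas12b-TTN	ATN	0.2600
Cas12b-TTN	CTN	0.1100
Cas12b-TTN	GTN	0.2000
Cas12e-TTCN	TTCN	1.0000
Cas12e-TTCN	ATCN	0.2600
Cas12e-TTCN	CTCN	0.1100
Cas12e-TTCN	GTCN	0.2000
Cas12f-TTTR	TTTA	1.0000
Cas12f-TTTR	TTTG	1.0000
Cas12f-TTTR	ATTA	0.2600
Cas12f-TTTR	ATTG	0.2600
Cas12f-TTTR	CTTA	0.1100
Cas12f-TTTR	CTTG	0.1100
Cas12f-TTTR	GTTA	0.2000
Cas12f-TTTR	GTTG	0.2000
CasMINI-TTTR	TTTA	1.0000
CasMINI-TTTR	TTTG	1.0000
CasMINI-TTTR	ATTA	0.2600
CasMINI-TTTR	ATTG	0.2600
CasMINI-TTTR	CTTA	0.1100
CasMINI-TTTR	CTTG	0.1100
CasMINI-TTTR	GTTA	0.2000
CasMINI-TTTR	GTTG	0.2000
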