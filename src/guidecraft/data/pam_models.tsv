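# PAM model registry: name	pattern	side	spacer_length	cut_offset
# cut_offset: nt from the PAM-proximal end of the spacer (nominal)
SpCas9-NGG	NGG	three_prime	20	-3
SpCas9-NAG	NAG	three_prime	20	-3
SpCas9-NG	NG	three_prime	20	-3
xCas9-NG	NG	three_prime	20	-3
SpG-NGN	NGN	three_prime	20	-3
SpRY-NRN	NRN	three_prime	20	-3
ScCas9-NNG	NNG	three_prime	20	-3
FnCas9-NGG	NGG	three_prime	20	-3
SaCas9-NNGRRT	NNGRRT	three_prime	21	-3
SaCas9KKH-NNNRRT	NNNRRT	three_prime	21	-3
NmeCas9-NNNNGATT	NNNNGATT	three_prime	24	-3
CjCas9-NNNNRYAC	NNNNRYAC	three_prime	22	-3
StCas9-NNAGAAW	NNAGAAW	three_prime	20	-3
Cas12a-TTTV	TTTV	five_prime	23	18
LbCas12a-TTTV	TTTV	five_prime	23	18
FnCas12a-TTN	TTN	five_prime	23	18
Cas12b-TTN	TTN	five_prime	20	17
Cas12e-TTCN	TTCN	five_prime	20	17
Cas12f-TTTR	TTTR	five_prime	20	17
CasMINI-TTTR	TTTR	five_prime	20	17
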