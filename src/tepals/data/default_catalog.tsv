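# Default tepal-arrangement catalog (editable).
# 13 arrangement types frequently observed in flowers with 4-9 tepals.
# The letter encodes the tepal count (A-F correspond to 4-9); the digit
# indexes the type within that count.  Entries are circular I/E/A strings,
# read up to rotation and reflection.  Per count: the whorled type
# (alternating E/I, plus one alternating-class tepal when the count is
# odd), the spiral type (all tepals alternating-class), and for 5 and 6
# tepals a one-reversal spiral.  Replace or extend to suit your taxa;
# loaders validate and deduplicate whatever is listed here.
A1	EIEI
A2	AAAA
B1	EIEIA
B2	AAAAA
B3	AAAEI
C1	EIEIEI
C2	AAAAAA
C3	AAAAEI
D1	EIEIEIA
D2	AAAAAAA
E1	EIEIEIEI
E2	AAAAAAAA
F1	EIEIEIEIA
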