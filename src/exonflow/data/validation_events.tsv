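gene	hypothesis	rt_pcr	qrt_AdCa	qrt_SCC	expected_status
ADD3	cassette exon	4/6	+	+	validated
ANTXR1	alt transcription start	N/A	-	-	devalidated
CLSTN1	cassette exon	4/6	+	-	validated
CTNND1-CE-5p	cassette exon	-	+	+	devalidated
CTNND1-CE-3p	cassette exon	2/6	-	-	devalidated
FN1	cassette exon	5/5	+	+	validated
KIAA1217-ATSS	alt transcription start	N/A	+	+	validated
KIAA1217-IR	intron retention	2/6	-	-	devalidated
MYH14	cassette exon	-	-	-	devalidated
MYO18A	cassette exon	4/6	+	-	validated
NCOR2	alt 5p-splice site	4/6	+	-	validated
NUMB	cassette exon	5/6	+	+	validated
SLK	cassette exon	5/6	+	+	validated
SYNE2	cassette exon	6/6	+	-	validated
TPM1-MX-5p	mutually exclusive exon	N/A	+	+	validated
TPM1-MX-3p	mutually exclusive exon	N/A	+	+	validated
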