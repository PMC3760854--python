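# CoRNR box motif instances reported by a SLiMSearch scan of the human
# proteome with the pattern L[^P]{2}[HI]I[^P]{2}[IAV][IL]:
# 67 instances in 65 proteins.  elm_true_positive marks the two instances
# annotated as true positives in the ELM resource.  One motif string
# (Q562E7) is inconsistent with the generating pattern as printed in the
# source table and is retained verbatim (see package docs).
accession	motif	elm_true_positive
O75376	LADHICQII	1
P05160	LTFIIILII	0
Q9Y618	LEAIIRKAL	1
Q9UBF1	LLIIILSVI	0
Q96BZ9	LIDIILLIL	0
Q8NI22	LINIIDGVL	0
Q07325	LLGIILLVL	0
Q5SVZ6	LKLIIENIL	0
Q96AH8	LKLIIVGAI	0
Q9HAU8	LTFIISSIL	0
Q9NRU3	LEDIIEEII	0
P53618	LMTIIRFVL	0
O75376	LEDIIRKAL	1
Q8IWF6	LRTHIDAII	0
Q8NHV5	LFFIIMGII	0
Q9UPM8	LRLHIIEII	0
Q9Y618	LAQHISEVI	1
Q96N64	LDHIIEDAL	0
O95477	LSRIIWKAL	0
O00273	LASHILTAL	0
Q7Z3J2	LQLIIKKVI	0
Q09161	LNYHIVEVI	0
Q08AE8	LGIIIYKAL	0
Q8TDJ6	LNNHIHDIL	0
P07384	LYQIILKAL	0
Q5MIZ7	LYEIIRGIL	0
Q8TDR0	LHDIITEVI	0
Q96PN6	LKNIITVVI	0
Q8TCG5	LGQHIEDAL	0
Q6ZMV5	LYEIIKGIL	0
Q8IX04	LQYIITNVL	0
Q93100	LVIHIGWII	0
Q8TDL5	LKNIITEII	0
Q9C093	LVDIIVNAI	0
Q7RTX7	LARIIRVIL	0
Q9UIA9	LVYIIGAVI	0
Q8NEG5	LCKHICWVL	0
Q9Y6X3	LLGHIFYVL	0
Q8IZQ1	LAQIILDAI	0
P35556	LNNHIRYVI	0
Q14185	LLSHILEVL	0
O95801	LKAIIRGAL	0
A6NHC0	LYQIIRKAL	0
P56192	LGNIIGCVL	0
A6NES4	LTSIIVAVI	0
O95714	LCTHIGDIL	0
Q8NF50	LVGIILDAL	0
O95450	LGAHINVVL	0
Q8N485	LRHIIAQVL	0
Q8TCG1	LKMHIAKIL	0
Q6R327	LDHIIQKAI	0
Q5T215	LCGIIRGAL	0
Q8WZ26	LSTHICVVL	0
P51124	LTFHIKAAI	0
Q99698	LNSIIDQAL	0
Q562E7	LSDITYYVY	0
Q9UJ70	LGRHIVAVL	0
Q0VDD8	LDKHIKSAI	0
Q8N1T3	LFGIIASVL	0
P17655	LFKIIQKAL	0
P52743	LHVIIDFIL	0
Q6PGP7	LEDIIGFAL	0
Q13572	LLNHIATVL	0
O15072	LGVHINVVL	0
Q8WXS8	LGVHINIAL	0
Q9UG01	LVEHITAAL	0
P30307	LGGHIQGAL	0
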