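name	species	mature_seq	known_match
sca-mir-temp-1	sca	uagauugggcuuggucggcaga	aqu-miR-2016
sca-mir-temp-2	sca	uagauugggcuuggucggcagg	aqu-miR-2016
sca-mir-temp-3	sca	ugguggucgguguuuugugga	aqu-miR-2021
sca-mir-temp-4	sca	aaagugaucggguugccgucu	aqu-miR-2019
sca-mir-temp-5	sca	ucauguauuguggaggggaga	aqu-miR-2015
sca-mir-temp-6	sca	uaccugugcaccugugugccc	aqu-miR-2017
sca-mir-temp-7	sca	uggguagugugucuuuucgga	aqu-miR-2020
sca-mir-temp-8	sca	cggggcguggcgcagcc
sca-mir-temp-11	sca	aauagaaccacgauacagcuugccu
sca-mir-temp-12	sca	cucucaagcucugaauaagcu
sca-mir-temp-13	sca	ugucggagccggagguuc	aqu-miR-2018
xte-mir-temp-1	xte	uagauugggcuuggucggcaga	aqu-miR-2016
xte-mir-temp-2	xte	aaagugaucggguugccgucu	aqu-miR-2019
xte-mir-temp-3	xte	cagauggacagaguagagagu
xte-mir-temp-4	xte	ucauguauuguggaggggaga	aqu-miR-2015
xte-mir-temp-5	xte	auauagauaccaauaggauu
xte-mir-temp-6	xte	ugguggucgguguuucgugga	aqu-miR-2021
xte-mir-temp-7	xte	gagauggacacaguaaagagu
xte-mir-temp-8	xte	uggguagugugucuuuucgga	aqu-miR-2020
xte-mir-temp-12	xte	ccggccaugccuucguacc
xte-mir-temp-16	xte	accccucugcugcuuuuuug
xte-mir-temp-19	xte	caauucuggauuccggc
xte-mir-temp-20	xte	uuccaaucccgauuacguagu
xte-mir-temp-27	xte	auccuguucauccauguaa
xte-mir-temp-31	xte	auccuguucauccauguaa
xte-mir-temp-34	xte	acagcaucuggguggacacc
xte-mir-temp-35	xte	ugccccguacauagccucugauu
xte-mir-temp-39	xte	agggacgcagagcgcuc
xte-mir-temp-44	xte	cucuaccgcugaugaggaggcacu
xte-mir-temp-46	xte	ugaacugugauuccugggau
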