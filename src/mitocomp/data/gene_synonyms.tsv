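alias	name	kind
COX1	cox1	PCG
COI	cox1	PCG
CO1	cox1	PCG
COX2	cox2	PCG
COII	cox2	PCG
CO2	cox2	PCG
COX3	cox3	PCG
COIII	cox3	PCG
CO3	cox3	PCG
ATP6	atp6	PCG
ATPASE6	atp6	PCG
ATP8	atp8	PCG
ATPASE8	atp8	PCG
CYTB	cytb	PCG
COB	cytb	PCG
CYB	cytb	PCG
ND1	nad1	PCG
NAD1	nad1	PCG
ND2	nad2	PCG
NAD2	nad2	PCG
ND3	nad3	PCG
NAD3	nad3	PCG
ND4	nad4	PCG
NAD4	nad4	PCG
ND4L	nad4l	PCG
NAD4L	nad4l	PCG
ND5	nad5	PCG
NAD5	nad5	PCG
ND6	nad6	PCG
NAD6	nad6	PCG
RRNL	rrnL	rRNA
16S	rrnL	rRNA
L-RRNA	rrnL	rRNA
LRRNA	rrnL	rRNA
RRN16	rrnL	rRNA
RRNS	rrnS	rRNA
12S	rrnS	rRNA
S-RRNA	rrnS	rRNA
SRRNA	rrnS	rRNA
RRN12	rrnS	rRNA
D-LOOP	CR	control_region
DLOOP	CR	control_region
CONTROL REGION	CR	control_region
A+T-RICH REGION	CR	control_region
AT-RICH REGION	CR	control_region
CR	CR	control_region
CR2	CR2	control_region
TRNA	trnA	tRNA
TRNR	trnR	tRNA
TRNN	trnN	tRNA
TRND	trnD	tRNA
TRNC	trnC	tRNA
TRNQ	trnQ	tRNA
TRNE	trnE	tRNA
TRNG	trnG	tRNA
TRNH	trnH	tRNA
TRNI	trnI	tRNA
TRNL1	trnL1	tRNA
TRNL2	trnL2	tRNA
TRNK	trnK	tRNA
TRNM	trnM	tRNA
TRNF	trnF	tRNA
TRNP	trnP	tRNA
TRNS1	trnS1	tRNA
TRNS2	trnS2	tRNA
TRNT	trnT	tRNA
TRNW	trnW	tRNA
TRNY	trnY	tRNA
TRNV	trnV	tRNA
TRNL(CUN)	trnL1	tRNA
TRNL(UUR)	trnL2	tRNA
TRNS(AGN)	trnS1	tRNA
TRNS(UCN)	trnS2	tRNA
TRNA-LEU(CUN)	trnL1	tRNA
TRNA-LEU(UUR)	trnL2	tRNA
TRNA-SER(AGN)	trnS1	tRNA
TRNA-SER(UCN)	trnS2	tRNA
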