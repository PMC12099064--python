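# msipipe default marker panel (synthetic stand-in)
# 14 mononucleotide (poly-A) microsatellite markers with randomly drawn
# 12 nt anchoring flanks. The marker sequences of the clinical assay this
# panel emulates are not published; these loci are synthetic and carry no
# genomic coordinates. Columns are tab-delimited.
name	repeat_unit	ref_length	flank5	flank3
MONO01	A	18	TACCGCTTAGTC	CAGTAAATAAGC
MONO02	A	20	GTCCTAAAGGGT	CCCACCAACGGT
MONO03	A	22	ATTCTATGTCGT	TGCCTGAAAGCG
MONO04	A	24	GAATGCGCGACC	TTGAACCCAGTA
MONO05	A	27	GGTCACCCAGAT	CAATCCGGAACG
MONO06	A	19	CGCGTTCCACGC	ACATAGCTGATT
MONO07	A	21	ACAGACGGTTTA	CGTGCCGCTCTC
MONO08	A	23	GTTGTGGCAAAG	GCGTGCCCGCTG
MONO09	A	25	CGGTCATTCCGG	TCCTTTGAGTGA
MONO10	A	26	GGACAGTCGATT	CTGTTCGTAGAC
MONO11	A	18	TCGCCTGGCCCC	GATACGACAGAA
MONO12	A	20	CGGGATGTATCT	GTCTTAAATACA
MONO13	A	22	GCCTGTGATCCA	GCACTATATGTC
MONO14	A	24	TGTGCCATTTCA	AGTATACCTTAT
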