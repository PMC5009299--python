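name	consensus	function
ABRE3HVA22	GCCACGTACA	Abscisic acid-responsive element
ABREBZMRAB28	TCCACGTCTC	Abscisic acid-responsive element in embryos and vegetative tissues
ABREDISTBBNNAPA	GCCACTTGTC	Abscisic acid-responsive element and required for seed-specific expression
ABREMOTIFAOSOSEM	TACGTGTC	Abscisic acid-responsive element
ACGTABOX	TACGTA	Negative regulator of sugar signaling
ACGTATERD1	ACGT	A water-stress responsive element
ACIPVPAL2	CCCACCTACC	Required for vascular-specific gene expression
AGCBOXNPGLB	AGCCGCC	Stress-signaling responsive element
AMMORESIIUDCRNIA1	GGWAGGGT	Ammonium responsive and regulates expression of nitrate reductase
ANAERO4CONSENSUS	GTTTHGCAA	Involved in regulation of the fermentative pathway
ANAERO5CONSENSUS	TTCCCTGTT	Involved in regulation of the fermentative pathway
ARR1AT	NGATT	A cytokinin response regulator (RR) binding motif
ASF1MOTIFCAMV	TGACG	Auxin- and salicylic acid-responsive element
AUXREPSIAA4	KGTCCCAT	Auxin-responsive element
BIHD1OS	TGTCA	Binding site for BIHD1, a BELL class homeodomain factor in stress response
CAATBOX1	CAAT	Reported to regulate flowering in plants
CACGCAATGMGH3	CACGCAAT	Auxin-responsive element
CBFHV	RYCGAC	Dehydration-responsive element
CEREGLUBOX1PSLEGA	TGTTAAAGT	Homologous to the cereal glutenin gene control element
CURECORECR	GTAC	Regulates copper- and oxygen-responsive gene expression
DOFCOREZM	AAAG	Binding site of Dof transcription factors in growth and stress response
E2FAT	TYTCCCGCC	E2F-binding site found in E2F target genes regulating cell cycle
EBOXBNNAPA	CANNTG	E-box sequence responsible for light responsiveness and tissue-specific expression
EMBP1TAEM	CACGTGGC	Involved in ABA-mediated stress-signaling pathway
GADOWNAT	ACGTGTC	Gibberellic acid responsive element
GATABOX	GATA	Binding site for zinc finger factors in light and nitrate-dependent control
GCBP2ZMGAPC4	GTGGGCCCG	Binding site of tobacco nuclear factor GCBP-2
GT1CONSENSUS	GRWAAW	Recognized by GT-1 trihelix DNA-binding proteins
GTGANTG10	GTGA	A pollen-specific cis-element identified in TCP-enriched genes
HY5AT	TGACACGTGGCA	Regulates stimulus-induced development of root and hypocotyl
IBOXCORE	GATAA	Light-responsive element
LTRE1HVBLT49	CCGAAA	Low temperature-responsive element
MNF1ZMPPC1	GTGCCCTT	Light-responsive element
MYB2CONSENSUSAT	YAACKG	Dehydration-responsive element
MYBCORE	CNGTTR	Binding site for plant MYB transcription factors
OCTAMOTIF2	CGCGGCAT	Found in histone-gene-specific consensus sequences
OPAQUE2ZMB32	GATGAYRTGG	Binding site of type I ribosome-inactivating protein gene
PIATGAPB	GTGATCAC	Light-responsive element
POLLEN1LELAT52	AGAAA	Regulatory element for pollen-specific activation of gene expression
RAV1AAT	CAACA	Rosette leaves- and roots-specific element
RGATAOS	CAGAAGATA	Regulator of phloem-specific gene expression
RHERPATEXPA7	KCACGW	Root hair-specific cis-element
RYREPEATBNNAPA	CATGCA	Required for seed-specific expression
SITEIOSPCNA	CCAGGTGG	Regulatory region of proliferating cell nuclear antigen
SORLIP1AT	GCCAC	Light-responsive element
SURE2STPAT21	AATACTAAT	Sucrose regulatory element
TRANSINITDICOTS	AMNAUGGC	Context sequence of translational initiation codon in dicots
VOZATVPP	GCGTNNNNNNNACGC	Regulates pollen development
WBOXNTERF3	TGACY	W-box promoter motif functioning in response to wound signal
WRKY71OS	TGAC	Binding site of rice WRKY71, a repressor of gibberellin signaling
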