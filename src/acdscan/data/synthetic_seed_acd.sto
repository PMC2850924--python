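# STOCKHOLM 1.0
SYN_1SHS_ARCH     EVDVKVLEGHFSVDVLELHVPGFDENVKVIEGKDLVIGSRSAAHGFVRKFVFGQFIREVLPDGVVSSTLSKPVGFLKTDELKI
SYN_1GME_PLANT    EVDVKVDEGKFSVWVLEIHVLGFDSNVKVIEEKFPVIGTSSDTHCIVRKFELGQFIREVKPDRVVSSTLSKDRGVNKTDEKKI
SYN_3GLA_BACT     EVDVKVTEGMFSLDVLELHVPHFLENVKVIEGKDLVDGERSDEHGFVRKFEYGQFIREVLPDAVVSSTLSKNIGVAATDELKI
SYN_2BOL1_WORM    EVDVDVDHMKFSVDVLELKSPGFDMNVKVIEGKDLRIGGRM-ENGPVR-QELGQFIREVLPDTVVSSTLSKNDGVLKTTELKI
SYN_2BOL2_WORM    EVFVKVDEGVFSVDVLELHVAEFDENVKVIEGKDLVIGEDDLGHKFVRKFELGQFIREVLPDGVVSSTLYKRTHLLKTDELKI
SYN_2WJ5_MAMM     EVDVKTDETKFSVFVLELITIGFDENVKVIEEKDLVIGELHDEHGFVRKRLLGQFIREVVPTGVVSSTLSKNDGVLKTDELKI
SYN_2WJ7_HUMAN    QVDVKVDEGKFSVDVVESHAPGFDENQKVIEGPDLVIGELSDEAGEVRSFELGQFIREVIPDGVVSSTLSKTDGVLKTDELKI
SYN_CRYAA_HUMAN   EVDVKVDESSFSVDVLELHCLDFDENVKVIEGKDLNKGSR-DVLGFVLKFELGQFIREVLPDSVVSSTLSDNDGVLKTDENMI
SYN_HSP163_MYCTU  EVDVKVDEGPFSVDVLELHVPGFDENVPVIEGKDGVIGEEQKEHPVVRKTEFGQFIREVLPDGVVSSTLSKNDGVLITDELKI
SYN_HSP26_YEAST   SVDVKVDEGIFSVDVLEKFVPNFDENVKVIEHKVLVIGRRSDEHGFVHKFETGQFIREVQPDGVVSSTLSKNDGVRKTDELKI
SYN_IBPA_ECOLI    EVDVKVGKGKFSVDVLELHVPGFDGNVKVIEGKDLVIHET--VVGFVFEFELGQFIREVLPDGVVSSTLSKNDGVLKTDELKI
#=GC ACD_elements 222222aaaa3333333bbbbbbbb444444ccc5555LLLLLLLLLLLLLL7777777ddddd8888888eeeeee999999
//
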