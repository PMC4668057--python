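orf,role,sequence,segments
YAL023C,PCR1_F,CGACGACAACGACGAAGGTGAGGAACTCCAACTAAAA,
YAL023C,PCR1_R,GATTGCTGGACCACGGTTCGAAACAGAATGACAGTAG,
YAL023C,PCR2_F,AAGCACATACTACGCCACATAGATAAACCGTATATATCTTTACATAAGTACGATATGGTATAACTCACACATTACTTGCCTC,25:40:17
YAL023C,PCR2_R,TCATGCTTCTTGCTTGTCGGCAATGTCCCAAGTGGAAAACCAGTTGATCCCAATACAACAGAT,45:18
YBR052C,PCR1_F,CACCAGTAAGGTTCAAATGTTCGATTTAACTAACGGAAA,
YBR052C,PCR1_R,TATCTATGTGGCGTAGTATGTGCTTATAATAGTGAGTAG,
YBR052C,PCR2_F,TGTTTCGAACCGTGGTCCAGCAATCATTAAGATCATCGTAGTAAGTACATAAGTAAAAAACAAGAAGCGACAAGAAGAGATAG,25:40:18
YBR052C,PCR2_R,TTACAAATCTTTGATACGGTCGTAAAAGGCCTTCCCTTGAAGTTGGATCCCAATACAACAGAT,45:18
YDL174C,PCR1_F,AGTACGGGAGACGGCTTGGACATAGATTTA,
YDL174C,PCR1_R,TGTTCTTGCTTTTGTTTCCAGCTGGATCGG,
YDL174C,PCR2_F,CCAGCTGGAAACAAAAGCAAGAACAGTATCTGATTTTCCTTTTTCACCCTTCACGTAAACCTGAACACACATTACTTGCCTC,25:40:17
YDL174C,PCR2_R,TCACCTGTAATCATTAGCGGGCTCGTTTGGATCAGTTTTAAAGATGATCCCAATACAACAGAT,45:18
YIR013C,PCR1_F,GTTTCTAACCCTCTGATGGCAAGACTTTCATCATCTTCCTGAT,
YIR013C,PCR1_R,AGCGACCCTGTAATGTTATGTTTCTAGCTAGGAACAGAAAGTG,
YIR013C,PCR2_F,AGAAACATAACATTACAGGGTCGCTCCCATTATACTTTTTCAGCTTTCAACCTATCGGGACAAAACACACATTACTTGCCTC,25:40:17
YIR013C,PCR2_R,TCAGAATCTGACAGTTCCGGTAAGTTCTTTGGGGATCCTTCTCTTGATCCCAATACAACAGAT,45:18
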