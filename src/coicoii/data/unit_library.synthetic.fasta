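>TRNA_LEU
GGCAGAATAAGTGCATTGTTAAAGTCCGAACGTCCACGTTAGAGCCGGTAAAGGGCATTA
TTACG
>P
TGGGGACGACTATAGGTAAGCGACTCGGTTAATGTGGAGCTAAGTAGTTTCTTTGCCATG
GTATGAA
>P0
TGGGGACGACTATAGGTAAGCGACTCGGTTAATGTGGAGCTAAGTGTATGAA
>P1
TGGGGACGACTATAGGTATGCAACTCGTAAAAGTGGAGCTAATTAGTTTCTTTGCCATCG
TATGAA
>Q
AGACAGCATGGCGAGGCGGATTGAAGGGGATCGGGTCTTTAGTATTGCCGTACTTGTTTT
TTTCGCCCAGCGTCTCCATCCAACCTTACTCGTGATTGACCAAGTCTTGCATTAGGAGTC
CGGCTGTCACGGATCAGTACGTGGGGGACTAGGATATACCCCGGGCAAGTACTTAGGGAT
TGTGACCTCCCTAGGC
>COX2_STUB
CCCATAACGATAGAAGCTCGGTAAAACGGATATTAGTATTCACGGTCATCAATGATATTG
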