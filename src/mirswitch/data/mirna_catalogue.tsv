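name	sequence	notes
miR-17-5p	CAAAGUGCUUACAGUGCAGGUAG	broadly expressed; high activity in HEK293T
miR-16-5p	UAGCAGCACGUAAAUAUUGGCG	broadly expressed
miR-21-5p	UAGCUUAUCAGACUGAUGUUGA	broadly expressed
miR-18a-5p	UAAGGUGCAUCUAGUGCAGAUAG	miR-17 family
miR-20a-5p	UAAAGUGCUUAUAGUGCAGGUAG	miR-17 family
miR-106a-5p	AAAAGUGCUUACAGUGCAGGUAG	miR-17 family
let-7a-5p	UGAGGUAGUAGGUUGUAUAGUU	broadly expressed
miR-206-3p	UGGAAUGUAAGGAAGUGUGUGG	skeletal-muscle specific; shares seed with miR-1a-3p
miR-1a-3p	UGGAAUGUAAAGAAGUAUGUAU	cardiac/skeletal muscle; shares seed with miR-206-3p
miR-122-5p	UGGAGUGUGACAAUGGUGUUUG	liver enriched
miR-10a-5p	UACCCUGUAGAUCCGAAUUUGUG	expressed but low activity in HEK293T
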