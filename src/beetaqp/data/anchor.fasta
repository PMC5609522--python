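>anchor_PIP2 synthetic PIP2-type anchor scaffold
SERGGDSDTDIIIIIILIVVVALVIVAVVVLESTEAGEGQGKDDDVKDKQTIVFVLILII
FIVLVVIILVVIDTKEESQSSKQTDNPASSGQRRGDGGDEGKIIVIFVVLFALVIILLIF
VIVGKTGEFSKSSIQSGGHSSHDFGQDRHKQTKILLVILVFVLFVIIVIAVIIIDQESTR
VKGDHPHSERESSTIVFLLALIVLIHILIVLAIVVSGGDGNPAKRSRKTKTQRSRQGKKT
QKKEEIVIIISLIAIFFFVWIVVIAIRSRGHGGDRT
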