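A	OC[C@H]1O[C@@H](n2cnc3c(N)ncnc32)[C@H](O)[C@@H]1O
C	OC[C@H]1O[C@@H](N2C=CC(=NC2=O)N)[C@H](O)[C@@H]1O
G	OC[C@H]1O[C@@H](n2cnc3c2N=C(N)NC3=O)[C@H](O)[C@@H]1O
U	OC[C@H]1O[C@@H](N2C=CC(=O)NC2=O)[C@H](O)[C@@H]1O
T	Cc1cn([C@H]2C[C@H](O)[C@@H](CO)O2)c(=O)[nH]c1=O
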