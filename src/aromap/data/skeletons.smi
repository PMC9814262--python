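# curated skeleton pool: small aromatic and quinone ring systems
c1ccccc1 benzene
c1ccc2ccccc2c1 naphthalene
c1ccc2cccc2cc1 azulene
O=C1C=CC(=O)C=C1 benzoquinone
O=C1C=CC(=O)c2ccccc21 naphthoquinone
c1ccoc1 furan
c1cc[nH]c1 pyrrole
c1ccncc1 pyridine
c1ccsc1 thiophene
c1ccc2nsnc2c1 benzothiadiazole
c1nnco1 oxadiazole
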