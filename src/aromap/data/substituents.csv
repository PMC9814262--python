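name,attachment_fragment,donor_acceptor_class
NO2,*[N+](=O)[O-],strong_acceptor
CN,*C#N,strong_acceptor
SO3H,*S(=O)(=O)O,strong_acceptor
CF3,*C(F)(F)F,strong_acceptor
NH2,*N,strong_donor
NMe2,*N(C)C,strong_donor
OH,*O,strong_donor
OMe,*OC,strong_donor
F,*F,other
Cl,*Cl,other
Me,*C,other
COOH,*C(=O)O,other
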