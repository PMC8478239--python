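variant,protein_id,ddg,binds_ligand,n_contacts,catalytic_domain,p_inv,observed_responsive,label_source
N370S,GBA,0.28,False,3,True,183,True,N-nonyl-deoxynojirimycin
L444P,GBA,1.96,False,2,False,43,False,N-nonyl-deoxynojirimycin
G202R,GBA,-1.00,False,2,True,219,True,N-nonyl-deoxynojirimycin
F213I,GBA,1.05,False,5,True,219,True,Ambroxol
R120W,GBA,2.18,False,10,True,145,True,Ambroxol
N188S,GBA,0.42,False,2,True,208,True,Ambroxol
D409H,GBA,0.55,False,2,True,79,False,Ambroxol
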