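id,smiles,role,printed_ic50_nM,printed_mz,provisional
UK-5099,OC(=O)/C(C#N)=C/c1cn(-c2ccccc2)c2ccccc12,active,240,,
BE1976,OC(=O)/C(C#N)=C/c1ccc(-c2nc3ccccc3s2)o1,active,33,297,
BE1978,OC(=O)/C(C#N)=C/c1cnn(-c2ccccc2)c1,active,117,240,
BE1980,OC(=O)/C(C#N)=C/c1c(C)nn(-c2ccccc2)c1C,active,162,268,
BE1984,OC(=O)/C(C#N)=C/c1ccc(C)cc1,active,1533,186,
BE1985,OC(=O)/C(C#N)=C/c1c[nH]nc1-c1cccc(Br)c1,active,638,,provisional
BE2617,OC(=O)/C(C#N)=C/c1n[nH]cc1-c1ccccc1,active,39,240,
BE2623,OC(=O)/C(C#N)=C/c1n[nH]cc1-c1ccc(C)cc1,active,731,254,
BE1975,OC(=O)/C=C/c1ccc(-c2nc3ccccc3s2)o1,inactive_control,,,provisional
BE1988,CCOC(=O)/C(C#N)=C/c1ccc(-c2nc3ccccc3s2)o1,inactive_control,,,provisional
3a,CCOC(=O)/C(C#N)=C/c1ccc(-c2nc3ccccc3s2)o1,inactive_control,,,
3b,CCOC(=O)/C(C#N)=C/c1cnn(-c2ccccc2)c1,inactive_control,,,
3c,CCOC(=O)/C(C#N)=C/c1c(C)nn(-c2ccccc2)c1C,inactive_control,,,
3d,CCOC(=O)/C(C#N)=C/c1ccc(C)cc1,inactive_control,,,
3e,CCOC(=O)/C(C#N)=C/c1n[nH]cc1-c1ccccc1,inactive_control,,,
3f,CCOC(=O)/C(C#N)=C/c1n[nH]cc1-c1ccc(C)cc1,inactive_control,,,
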