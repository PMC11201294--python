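name	metal_class	pattern	group_hint	source
FeFe_L1	FeFe	T[SA]CCP[A-Z]W	A	Vignais & Billoud 2007 (H-cluster L1 motif TSCCPxW)
FeFe_L2	FeFe	[MV]PC[A-Z][A-Z]K[A-Z][A-Z]E		Vignais & Billoud 2007 (H-cluster L2 motif MPCxxKxxE)
FeFe_L3	FeFe	E[A-Z]MAC[A-Z][A-Z]GC[A-Z][A-Z]G		Vignais & Billoud 2007 (H-cluster L3 motif ExMACxxGCxxG)
NiFe_L1	NiFe	R[A-Z]CG[A-Z]C[A-Z][A-Z][A-Z]H		Vignais & Billoud 2007 (N-terminal Ni-binding RxCGxCxxxH)
NiFe_L2	NiFe	DPC[A-Z][A-Z]C[A-Z][A-Z][HR]		Vignais & Billoud 2007 (C-terminal Ni-binding DPCxxCxxH/R)
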