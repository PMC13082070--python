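# Short-linear-motif patterns (name, class, regex), tab-separated.
# Approximate defaults in the style of the Eukaryotic Linear Motif resource;
# edit or replace with a curated table for production scans.
nls_monopartite	NLS	K[KR].[KR]
nls_mono_basic	NLS	[KR]{4}
nls_bipartite	NLS	[KR]{2}.{9,12}[KR]{3}
mod_ck1	MOD	S..[ST]
mod_ck2	MOD	[ST]..[ED]
mod_pka	MOD	[RK][RK].[ST]
mod_camk2	MOD	R..[ST]
mod_gsk3	MOD	[ST]...[ST]
mod_cdk	MOD	[ST]P.[KR]
mod_prodir	MOD	[ST]P
mod_sumo	MOD	[VILMAFP]K.E
mod_nglyc	MOD	N[^P][ST]
rna_rgg	RNA	RGG
rna_rg	RNA	RG
rna_fygg	RNA	[FY]GG
rna_syg	RNA	SYG
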