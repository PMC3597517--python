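motif_id	name	pattern	both_strands
chi	Chi element	GCTGGTGG	1
chi_like	Chi-like element (degenerate)	GCWGGWGG	1
translin_1	Translin target site 1	ATGCAG	1
translin_2	Translin target site 2	GCCCWSSW	1
del_hotspot	Deletion hotspot consensus	TGRRKM	1
igsw_tgggg	Ig class-switch repeat TGGGG	TGGGG	1
igsw_tgagc	Ig class-switch repeat TGAGC	TGAGC	1
igsw_gagct	Ig class-switch repeat GAGCT	GAGCT	1
igsw_gggct	Ig class-switch repeat GGGCT	GGGCT	1
igsw_ggggt	Ig class-switch repeat GGGGT	GGGGT	1
rss_heptamer	V(D)J recombination signal heptamer	CACAGTG	1
rss_nonamer	V(D)J recombination signal nonamer	ACAAAAACC	1
minisat_core	Minisatellite core sequence	GGGCAGGANG	1
minisat_chi	Minisatellite chi-like core	GGCAGG	1
telomere	Telomeric hexamer repeat	TTAGGG	1
l1_en	LINE-1 endonuclease cleavage site	TTAAAA	1
topo1	Topoisomerase I cleavage site	CCCTT	1
topo2	Topoisomerase II cleavage consensus	RNYNNCNNGYNGKTNYNY	1
pol_alpha_pause	DNA polymerase alpha pause site	GAGGAG	1
pol_pause	Polymerase pause site (degenerate)	WGGAG	1
purine_tract	Oligopurine tract	RRRRRRRRRR	0
pyrimidine_tract	Oligopyrimidine tract	YYYYYYYYYY	0
ry_tract	Alternating purine-pyrimidine tract	RYRYRYRYRYRY	0
a_tract	A-tract	AAAAAA	0
t_tract	T-tract	TTTTTT	0
g_tract	G-tract	GGGGG	0
tata	TATA box	TATAWAW	1
caat	CAAT box	CCAAT	1
gc_box	GC box	GGGCGG	1
ap1	AP-1 binding site	TGASTCA	1
octamer	Octamer motif	ATGCAAAT	1
hre_half	Hormone response element half site	AGGTCA	1
sat3	Satellite III pentamer	GGAAT	1
cenpb	CENP-B box (degenerate core)	TTCGNNNNANNCGGG	1
alu_core	Alu 5' core segment	GGCCGGGCGCGGTGG	1
cctg_repeat	CCTG fragile-site repeat	CCTGCCTG	1
ctg_repeat	CTG triplet repeat	CTGCTGCTG	1
gaa_repeat	GAA triplet repeat	GAAGAAGAA	1
cgg_repeat	CGG triplet repeat	CGGCGGCGG	1
vdj_spacer	Immune receptor spacer-like motif	CACAGTGNNNNNNNNNNNNACAAAAACC	1
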