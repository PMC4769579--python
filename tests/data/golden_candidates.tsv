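chrom	start	end	size	partial	n_snps	D	D_se	D_z	D_p	fd	fd_se	fd_z	fd_p	dxy_P2P3	dxy_P1P3	dxy_P1P2	fst	depth_P1	depth_P2	depth_P3	depth_O	sizes	dxy_locus_mean	dxy_chrom_mean	n_dxy_blocks	dxy_mwu_p	dxy_below_mean	dxy_lowest_pair	depth_ok	significant_D	significant_fd	dxy_below_chromosome	tier
chr1	140000	145000	5000	False	736	0.98793	0.00770913	128.151	0	0.895067	0.0147662	60.6158	0	0.06509	0.222826	0.230384	-0.0329245	20.0143	19.8481	20.1347	20.2091	5000;50000	0.0656247	0.19786	50	1.64386e-20	True	True	True	True	True	True	well-supported
chr1	130000	140000	10000	False	1443	0.974125	0.0100868	96.5744	0	0.803824	0.0231645	34.7007	7.6935e-264	0.070751	0.241078	0.24346	0.102132	19.9731	19.9022	19.9942	20.0499	10000;50000	0.0696353	0.19786	100	1.94922e-35	True	True	True	True	True	True	well-supported
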