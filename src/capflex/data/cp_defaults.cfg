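# Default analysis configuration for the actin capping protein (CP).
#
# Selections use author residue numbering with roles alpha -> chain A and
# beta -> chain B.  Deposited chain identifiers vary between entries and
# cannot be assumed; verify against the downloaded files and override
# chain_map (and the selections' chain letters) if an entry labels its
# subunits differently.  The whole-CP selection excludes the mobile
# beta-tentacle (beta residues beyond 244).
#
# Relevant entries: free CP 1IZN (CP_full); CP/V-1 3AAA; ligand-free
# beta-tentacle-truncated CP 3AA7 (CP_bdC); CP/CARMIL-peptide complexes
# 3AA0 (CA21), 3AA6 (CD23), 3AA1 (CK23).

chain_map = A=alpha,B=beta,C=ligand

# whole-CP comparison window (beta-tentacle excluded)
selection.whole_cp = A:9-275,B:3-244

# larger rigid domain (CP-L): alpha 1-258 plus beta 1-42, 175-192, 235-277
selection.cp_l = A:1-258,B:1-42,B:175-192,B:235-277

# smaller rigid domain (CP-S): alpha 259-286 plus beta 43-174, 193-234
selection.cp_s = A:259-286,B:43-174,B:193-234

enm.cutoff = 12.0
enm.spring_constant = 1.0
enm.threshold = 2.0
enm.threshold_mode = absolute
enm.quantile = 0.15

domain.k = 2
domain.linkage = average
domain.max_iterations = 50

seed = 0
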