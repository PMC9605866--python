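# Selections for the structural regression against the deposited models.
#
# The chain identifiers and residue ranges below MUST be taken from the
# deposited coordinate files' own headers/annotations (the publication text
# does not state them).  They are intentionally left blank here; fill them
# in after downloading the files, e.g.:
#   curl -O https://files.rcsb.org/download/7USW.pdb   (expanded state)
#   curl -O https://files.rcsb.org/download/7USX.pdb   (contracted state)
#   curl -O https://files.rcsb.org/download/6WUD.pdb   (CIB3 peptide complex)
# and place them under data/structures/ (or point MECHANOMEM_STRUCTURE_DIR
# at their directory).

[files]
expanded = "7usw.pdb"
contracted = "7usx.pdb"
cib3_complex = "6wud.pdb"

[calm1]
# CALM-1 subunit in the expanded model
chain = ""

[cib3]
# CIB3 chain in the peptide-complex structure
chain = ""

[anchor_protomer]
# pore-subunit protomer used as the superposition anchor
chain = ""

[moving_half]
# chains of the other half-complex (pore subunit + both auxiliary subunits)
chains = []

[tm10]
chain = ""
res_start = 0
res_end = 0

[h3]
chain_a = ""
chain_b = ""
res_start = 0
res_end = 0

[dimer_interface]
# the two pore-subunit chains for the dimer-interface buried area
chain_a = ""
chain_b = ""

[calm1_interface]
# pore-subunit chain and its CALM-1 partner for the second buried area
chain_a = ""
chain_b = ""
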