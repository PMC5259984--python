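# CTD three-way amino-acid partitions, one property per line:
#   property_name: GROUP1, GROUP2, GROUP3
# Groups are disjoint and together cover the 20 standard residues.
# The hydrophobicity partition (neutral / polar / hydrophobic) is the anchor
# of the 188D descriptor; the remaining seven follow the standard CTD
# descriptor tables (Dubchak-lineage partitions as tabulated in PROFEAT).
# version: 1
hydrophobicity: GASTPHY, RKEDQN, CVLIMFW
van_der_waals_volume: GASCTPD, NVEQIL, MHKFRYW
polarity: LIFWCMVY, PATGS, HQRKNED
polarizability: GASDT, CPNVEQIL, KMHFRYW
charge: KR, ANCQGHILMFPSTWYV, DE
surface_tension: GQDNAHR, KTSEC, ILMFPWYV
secondary_structure: EALMQKRH, VIYCWFT, GNPSD
solvent_accessibility: ALFCGIVW, RKQEND, MSPTHY
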