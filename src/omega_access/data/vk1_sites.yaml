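# Site definitions for the synthetic vitamin-K1 tail fragment (residue 2,
# VKF) against the minimal Compound I fragment (residue 1, CPI).
# Selectors are [residue_id, atom_name]; serial numbers are never used.
# neighbor_carbons order is [toward_omega, toward_chain] and fixes the
# substituent priorities for pro-R/pro-S assignment.
reactive_center:
  iron: [1, FE]
  oxo: [1, O1]
sites:
  - label: omega
    carbon: [2, C1]
    hydrogens: [[2, H11], [2, H12], [2, H13]]
    prochiral: false
  - label: omega-1
    carbon: [2, C2]
    hydrogens: [[2, H21]]
    prochiral: false
  - label: omega-2
    carbon: [2, C3]
    hydrogens: [[2, H31], [2, H32]]
    prochiral: true
    neighbor_carbons: [[2, C2], [2, C4]]
  - label: omega-3
    carbon: [2, C4]
    hydrogens: [[2, H41], [2, H42]]
    prochiral: true
    neighbor_carbons: [[2, C3], [2, C5]]
# Terminal branch torsion separating the two tail conformers:
# anti -> conformer 1, gauche -> conformer 2.
torsion:
  atoms: [[2, C2], [2, C3], [2, C4], [2, C5]]
  bins:
    "1": [[120, 180], [-180, -120]]
    "2": [[0, 120]]
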