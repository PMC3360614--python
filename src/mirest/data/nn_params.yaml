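# Nearest-neighbor free-energy parameters (kcal/mol at 37 degC) for RNA helix
# stacking, loop initiation and duplex initiation.
#
# Stacks are keyed "XY/ZW" meaning the motif
#     5'-X Y-3'
#     3'-Z W-5'
# i.e. the outer pair is X:Z and the inner (stacked) pair is Y:W.  Only one
# member of each rotationally symmetric pair of keys is listed; the loader
# expands E(XY/ZW) = E(WZ/YX).  Watson-Crick values follow the standard
# published nearest-neighbor set; G:U wobble values follow the published
# wobble extension.  Values are data: swapping this file changes energies,
# never code.
stacks:
  # Watson-Crick / Watson-Crick
  AA/UU: -0.93
  AU/UA: -1.10
  UA/AU: -1.33
  CU/GA: -2.08
  CA/GU: -2.11
  GU/CA: -2.24
  GA/CU: -2.35
  CG/GC: -2.36
  GG/CC: -3.26
  GC/CG: -3.42
  # Watson-Crick outer, G:U wobble inner (rotational symmetry supplies the
  # wobble-outer orientations)
  AG/UU: -0.55
  AU/UG: -1.36
  UG/AU: -1.00
  UU/AG: -0.70
  CG/GU: -1.41
  CU/GG: -2.11
  GG/CU: -1.53
  GU/CG: -2.51
  # wobble / wobble
  GG/UU: -0.50
  GU/UG: 1.29
  UG/GU: -0.57

# Hairpin-loop initiation by loop length (unpaired nucleotides in the
# terminal loop, minimum 3).  Lengths beyond the table are extrapolated with
# the Jacobson-Stockmayer term dG(n) = dG(n_max) + 1.75*R*T*ln(n/n_max).
hairpin_loop:
  3: 5.4
  4: 5.6
  5: 5.7
  6: 5.4
  7: 6.0
  8: 5.5
  9: 6.4

# Bulge-loop initiation by bulge length (one helix side unpaired).
bulge_loop:
  1: 3.8
  2: 2.8
  3: 3.2
  4: 3.6
  5: 4.0
  6: 4.4

# Internal-loop initiation by total loop size (both sides unpaired, each >= 1).
internal_loop:
  2: 1.5
  3: 1.6
  4: 1.7
  5: 1.8
  6: 2.0
  7: 2.2
  8: 2.3
  9: 2.4
  10: 2.5

# Penalty per nucleotide of internal-loop asymmetry |n1 - n2|, and its cap.
internal_asymmetry: 0.6
internal_asymmetry_max: 3.0

# Largest interior loop (n1 + n2) considered between consecutive stem pairs.
max_interior: 30

# Intermolecular duplex initiation penalty (single configurable constant).
duplex_init: 4.09

# Per-side cap on unpaired gaps between consecutive duplex pairs (kept equal
# on both strands so that duplex energies are reversal-symmetric).
duplex_max_gap: 10
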