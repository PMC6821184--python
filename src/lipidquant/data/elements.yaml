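# Monoisotopic masses (Da) and natural isotope abundances.
# Values: IUPAC/CODATA recommended atomic masses and isotopic compositions.
# shift = nominal mass difference (nucleons) relative to the lightest isotope.
version: 1
elements:
  C:
    - {mass: 12.0, abundance: 0.9893, shift: 0}
    - {mass: 13.00335483507, abundance: 0.0107, shift: 1}
  H:
    - {mass: 1.00782503207, abundance: 0.999885, shift: 0}
    - {mass: 2.01410177812, abundance: 0.000115, shift: 1}
  N:
    - {mass: 14.0030740048, abundance: 0.99636, shift: 0}
    - {mass: 15.0001088989, abundance: 0.00364, shift: 1}
  O:
    - {mass: 15.9949146196, abundance: 0.99757, shift: 0}
    - {mass: 16.9991317012, abundance: 0.00038, shift: 1}
    - {mass: 17.9991610425, abundance: 0.00205, shift: 2}
  P:
    - {mass: 30.97376163, abundance: 1.0, shift: 0}
  S:
    - {mass: 31.97207100, abundance: 0.9499, shift: 0}
    - {mass: 32.97145876, abundance: 0.0075, shift: 1}
    - {mass: 33.96786690, abundance: 0.0425, shift: 2}
    - {mass: 35.96708076, abundance: 0.0001, shift: 4}
  Na:
    - {mass: 22.9897692809, abundance: 1.0, shift: 0}
  K:
    - {mass: 38.96370668, abundance: 0.932581, shift: 0}
    - {mass: 39.96399848, abundance: 0.000117, shift: 1}
    - {mass: 40.96182576, abundance: 0.067302, shift: 2}
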