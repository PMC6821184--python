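# Lipid-class construction rules.
# Each class gives the elemental composition at zero side-chain carbons and
# zero double bonds ("base"). Every side-chain carbon adds CH2; every double
# bond removes H2. Ether (alkyl, [O]) variants replace the sn-1 ester by an
# ether bond: subtract one O, add two H relative to the diacyl counterpart.
# Plasmenyl (alkenyl) species use the alkyl rule with the vinyl-ether double
# bond counted in double_bonds (P-n:m is represented as O-n:m+1).
version: 1
classes:
  PC:  {base: {C: 8, H: 16, N: 1, O: 8, P: 1}, min_carbons: 16, ether: true}
  PE:  {base: {C: 5, H: 10, N: 1, O: 8, P: 1}, min_carbons: 16, ether: true}
  PS:  {base: {C: 6, H: 10, N: 1, O: 10, P: 1}, min_carbons: 16, ether: true}
  PI:  {base: {C: 9, H: 15, O: 13, P: 1}, min_carbons: 16, ether: false}
  PG:  {base: {C: 6, H: 11, O: 10, P: 1}, min_carbons: 16, ether: false}
  PA:  {base: {C: 3, H: 5, O: 8, P: 1}, min_carbons: 16, ether: false}
  BMP: {base: {C: 6, H: 11, O: 10, P: 1}, min_carbons: 16, ether: false}
  CL:  {base: {C: 9, H: 14, O: 17, P: 2}, min_carbons: 32, ether: false}
  SM:  {base: {C: 5, H: 13, N: 2, O: 6, P: 1}, min_carbons: 24, ether: false}
  Cer: {base: {C: 0, H: 1, N: 1, O: 3}, min_carbons: 24, ether: false}
  LPC: {base: {C: 8, H: 18, N: 1, O: 7, P: 1}, min_carbons: 8, ether: true}
  LPE: {base: {C: 5, H: 12, N: 1, O: 7, P: 1}, min_carbons: 8, ether: true}
  LPG: {base: {C: 6, H: 13, O: 9, P: 1}, min_carbons: 8, ether: false}
  LPA: {base: {C: 3, H: 7, O: 7, P: 1}, min_carbons: 8, ether: false}
  DG:  {base: {C: 3, H: 4, O: 5}, min_carbons: 16, ether: true}
  TG:  {base: {C: 3, H: 2, O: 6}, min_carbons: 24, ether: true}
  CE:  {base: {C: 27, H: 44, O: 2}, min_carbons: 10, ether: false}
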