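# Wedge-model deflection angles per dinucleotide step: (roll, tilt) in
# degrees.  The table is duplex-symmetric: the reverse-complement step
# carries the same roll and the negated tilt, so a profile and the
# profile of the reverse complement mirror each other exactly.  The
# dominant AA/TT wedge reproduces phased A-tract macroscopic curvature.
name: wedge
units: degrees
helical_repeat: 10.5
window_bp: 31
values:
  AA: {roll: 0.5, tilt: 8.0}
  TT: {roll: 0.5, tilt: -8.0}
  AC: {roll: 0.7, tilt: 1.0}
  GT: {roll: 0.7, tilt: -1.0}
  AG: {roll: 4.0, tilt: 1.5}
  CT: {roll: 4.0, tilt: -1.5}
  AT: {roll: 1.1, tilt: 0.0}
  CA: {roll: 6.5, tilt: 1.0}
  TG: {roll: 6.5, tilt: -1.0}
  CC: {roll: 1.2, tilt: 0.5}
  GG: {roll: 1.2, tilt: -0.5}
  CG: {roll: 5.4, tilt: 0.0}
  GA: {roll: 2.0, tilt: 1.0}
  TC: {roll: 2.0, tilt: -1.0}
  GC: {roll: 2.5, tilt: 0.0}
  TA: {roll: 4.0, tilt: 0.0}
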