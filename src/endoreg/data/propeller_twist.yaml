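# Base-pair propeller twist by dinucleotide step, degrees (crystallographic
# averages; more negative = more propeller-twisted, stiffer step).
name: propeller_twist
units: degrees
values:
  AA: -18.66
  AC: -13.10
  AG: -14.00
  AT: -15.01
  CA: -9.45
  CC: -8.11
  CG: -10.03
  CT: -14.00
  GA: -13.48
  GC: -11.08
  GG: -8.11
  GT: -13.10
  TA: -11.85
  TC: -13.48
  TG: -9.45
  TT: -18.66
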