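# Family-wide refined positional model of the baculovirus polyadenylation
# cassette.  Distances: mode "gap" = nt strictly between upstream element
# end and downstream element start (CS measured at the cleavage point);
# mode "start" = start-to-start.  pas_anchor constrains the PAS start in
# relative DGR coordinates (stop codon at -3..-1, first downstream base +1).
name: improved2020
classes: [USE, UGUA, PAS, CS, DSE, AuxDSE]
required: [PAS, CS]
pas_anchor: {min: -12, max: 7}
windows:
  - {a: USE, b: PAS, min: 5, max: 30}            # USE 5-30 nt upstream of PAS
  - {a: UGUA, b: PAS, min: 0, max: 8, mode: start}  # immediately upstream / overlapping
  - {a: PAS, b: CS, min: 0, max: 75}             # PAS 0-75 nt upstream of CS
  - {a: PAS, b: DSE, min: 21, max: 29}           # DSE 21-29 nt downstream of PAS
  - {a: CS, b: DSE, min: 0, max: 50}             # DSE 0-50 nt downstream of CS
  - {a: DSE, b: AuxDSE, min: 1, max: 100}        # G-rich Aux-DSE downstream of DSE
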