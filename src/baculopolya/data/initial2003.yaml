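# Initial positional model, derived from the gp64 locus of eight
# alphabaculoviruses.  Same conventions as improved2020.yaml.
name: initial2003
classes: [USE, UGUA, PAS, CS, DSE, AuxDSE]
required: [PAS, CS]
pas_anchor: {min: 1, max: 51}                    # PAS 0-50 nt downstream of stop
windows:
  - {a: USE, b: PAS, min: 5, max: 30}            # USE 5-30 nt upstream of PAS
  - {a: UGUA, b: PAS, min: 0, max: 8, mode: start}
  - {a: PAS, b: CS, min: 12, max: 42}            # PAS 12-42 nt upstream of CS
  - {a: CS, b: DSE, min: 4, max: 40}             # CS 4-40 nt upstream of DSE
  - {a: DSE, b: AuxDSE, min: 1, max: 100}
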