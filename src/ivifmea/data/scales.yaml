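# Bundled rating vocabularies.
#
# severity / preventability share one 6-row IVIF table: each row carries both
# a severity grade code (EI..LI) and a numeric preventability code (1..6),
# so either code resolves in either scale (the numeric code is an alias on
# the severity scale and vice versa).  Every component is strictly positive:
# the importance-score path raises these numbers to fractional powers and a
# zero membership bound would annihilate the score.
#
# occurrence is a 9-term order-of-magnitude ladder (Palin perspective scale)
# with one probability band per decade; bands are half-open [lo, hi) with the
# top band closed, so an exact edge value joins the higher-frequency term.
severity:
  name: severity
  terms:
    - code: EI
      aliases: ["1"]
      description: "Grade 5: Contributed to the death of the patient"
      ivif: [0.65, 0.75, 0.10, 0.25]
    - code: VI
      aliases: ["2"]
      description: "Grade 4: Intervention was needed to keep the patient alive"
      ivif: [0.60, 0.70, 0.15, 0.30]
    - code: I
      aliases: ["3"]
      description: "Grade 3: Contributed to or resulted in permanent harm to the patient"
      ivif: [0.55, 0.65, 0.20, 0.35]
    - code: MI
      aliases: ["4"]
      description: "Grade 2: Contributed to temporary harm to the patient, thereby resulting in longer admission being necessary"
      ivif: [0.50, 0.60, 0.25, 0.40]
    - code: MLI
      aliases: ["5"]
      description: "Grade 1: Adverse events contributed to temporary harm to the patient and intervention was needed"
      ivif: [0.45, 0.55, 0.30, 0.45]
    - code: LI
      aliases: ["6"]
      description: "Grade 0: Without repercussion for the patient (near miss)"
      ivif: [0.25, 0.40, 0.50, 0.60]
preventability:
  name: preventability
  terms:
    - code: "1"
      aliases: [EI]
      description: "Easily preventable (control charts etc.)"
      ivif: [0.65, 0.75, 0.10, 0.25]
    - code: "2"
      aliases: [VI]
      description: "Can be preventable with small system improvements"
      ivif: [0.60, 0.70, 0.15, 0.30]
    - code: "3"
      aliases: [I]
      description: "Can be preventable with training"
      ivif: [0.55, 0.65, 0.20, 0.35]
    - code: "4"
      aliases: [MI]
      description: "Can be preventable with radical improvements"
      ivif: [0.50, 0.60, 0.25, 0.40]
    - code: "5"
      aliases: [MLI]
      description: "Unpreventable but side effects can be preventable"
      ivif: [0.45, 0.55, 0.30, 0.45]
    - code: "6"
      aliases: [LI]
      description: "Unpreventable"
      ivif: [0.25, 0.40, 0.50, 0.60]
occurrence:
  name: occurrence
  terms:
    - code: Rare
      description: "Less than 1 in 100,000,000"
      ivif: [0.0, 0.2, 0.5, 0.8]
      band: [0.0, 1.0e-8]
    - code: Very Low
      description: "1 in 100,000,000"
      ivif: [0.1, 0.3, 0.4, 0.7]
      band: [1.0e-8, 1.0e-7]
    - code: Low
      description: "1 in 10,000,000"
      ivif: [0.2, 0.4, 0.3, 0.6]
      band: [1.0e-7, 1.0e-6]
    - code: Medium-Low
      description: "1 in 1,000,000"
      ivif: [0.3, 0.5, 0.2, 0.5]
      band: [1.0e-6, 1.0e-5]
    - code: Medium
      description: "1 in 100,000"
      ivif: [0.4, 0.6, 0.2, 0.4]
      band: [1.0e-5, 1.0e-4]
    - code: Medium High
      description: "1 in 10,000"
      ivif: [0.5, 0.7, 0.1, 0.3]
      band: [1.0e-4, 1.0e-3]
    - code: High
      description: "1 in 1,000"
      ivif: [0.6, 0.8, 0.0, 0.2]
      band: [1.0e-3, 1.0e-2]
    - code: Very High
      description: "1 in 100"
      ivif: [0.7, 0.9, 0.0, 0.1]
      band: [1.0e-2, 1.0e-1]
    - code: Extremely High
      description: "1 in 10"
      ivif: [0.8, 1.0, 0.0, 0.0]
      band: [1.0e-1, 1.0]
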