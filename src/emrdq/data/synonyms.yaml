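# Term normalization dictionary: canonical token -> free-text variants.
# Variants are matched after lowercasing, punctuation stripping and
# whitespace collapsing; the canonical token itself always maps to itself.
diabetes:
  - diabetes
  - diabetes mellitus
  - diabetes mellitus type 2
  - diabetes mellitus type ii
  - type 2 diabetes
  - type ii diabetes
  - type ii diabetes mellitus
  - type 2 diabetes mellitus
  - type 1 diabetes
  - type i diabetes mellitus
  - dm
  - dm2
  - dm ii
  - niddm
  - iddm
hypertension:
  - hypertension
  - essential hypertension
  - htn
  - high blood pressure
  - elevated blood pressure
hypothyroidism:
  - hypothyroidism
  - hypothyroid
  - low thyroid
  - myxedema
  - underactive thyroid
asthma:
  - asthma
  - asthmatic
  - reactive airway disease
  - rad
obesity:
  - obesity
  - obese
  - morbid obesity
urinary tract infection:
  - urinary tract infection
  - uti
  - cystitis
  - acute cystitis
  - bladder infection
  - recurrent uti
tetanus_conjugate_vaccine:
  - dtap
  - dtap ipv hib
  - dtap ipv
  - dpt
  - dtp
  - pentacel
  - tetanus toxoid conjugate
  - diphtheria tetanus pertussis
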