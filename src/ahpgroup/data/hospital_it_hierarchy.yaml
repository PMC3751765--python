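# Decision hierarchy of the hospital IT innovation study: four main criteria
# under the goal, three of which split into two sub-criteria (7 leaves total).
goal: Added value of IT innovations in hospital care
criteria:
  - id: efficiency
    label: Efficiency
    children:
      - id: self_management
        label: Patient self-management
      - id: organization
        label: Efficiency of organization
  - id: health_gain
    label: Health gain
  - id: satisfaction
    label: Satisfaction
    children:
      - id: professionals
        label: Health care professionals
      - id: patients
        label: Patients
  - id: investments
    label: Investments
    children:
      - id: initial
        label: Initial
      - id: restructuring
        label: Restructuring
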