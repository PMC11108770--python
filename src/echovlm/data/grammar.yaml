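# Default fill-in-the-blank report grammar for synthetic echocardiography
# reports. Slots: SEVERITY (graded term) or NUMBER (literal value; the unit
# text is part of the canonical form). "_" marks each slot.
severity_tokens: [mild, moderate, severe, small, large]
templates:
  # function and pressures
  - canonical_form: "Left ventricular ejection fraction is _%."
    slots: [NUMBER]
    units: ["%"]
  - canonical_form: "Estimated pulmonary artery systolic pressure is _ mmHg."
    slots: [NUMBER]
    units: ["mmHg"]
  # LV wall (hypertrophy)
  - canonical_form: "_ left ventricular hypertrophy."
    slots: [SEVERITY]
  - canonical_form: "No left ventricular hypertrophy."
  # chamber dilation
  - canonical_form: "The left ventricle is _ dilated."
    slots: [SEVERITY]
  - canonical_form: "The left ventricle is normal in size."
  - canonical_form: "The left atrium is _ dilated."
    slots: [SEVERITY]
  - canonical_form: "The left atrium is normal in size."
  - canonical_form: "The right ventricle is _ dilated."
    slots: [SEVERITY]
  - canonical_form: "The right ventricle is normal in size."
  - canonical_form: "The right atrium is _ dilated."
    slots: [SEVERITY]
  - canonical_form: "The right atrium is normal in size."
  # pericardial effusion
  - canonical_form: "There is a _ pericardial effusion."
    slots: [SEVERITY]
  - canonical_form: "No pericardial effusion."
  - canonical_form: "Pericardial effusion with tamponade physiology."
  # devices
  - canonical_form: "A pacemaker lead is visualized in the right heart."
  - canonical_form: "A MitraClip device is present on the mitral valve."
  - canonical_form: "A TAVR prosthesis is seen in the aortic position."
  - canonical_form: "An Impella device is visualized in the left ventricle."
  # boilerplate observations (no latent attribute content)
  - canonical_form: "Study performed in the apical four chamber view."
  - canonical_form: "Image quality is adequate."
  - canonical_form: "The aortic valve is trileaflet."
  - canonical_form: "No intracardiac mass is seen."
  - canonical_form: "The interatrial septum is intact."
  - canonical_form: "Normal sinus rhythm during acquisition."
  - canonical_form: "The aortic root is normal in size."
  - canonical_form: "No left ventricular thrombus is identified."
  - canonical_form: "The inferior vena cava is normal in caliber."
  - canonical_form: "Mitral inflow pattern is normal."
  - canonical_form: "The pulmonic valve is structurally normal."
  - canonical_form: "The estimated left ventricular ejection fraction is _%."
    slots: [NUMBER]
    units: ["%"]
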