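# Target drug dictionary: label -> generic + brand name keywords.
# Matching is case-insensitive substring against DRUGNAME and PROD_AI.
drugs:
  erenumab: [erenumab, aimovig]
  galcanezumab: [galcanezumab, emgality]
  fremanezumab: [fremanezumab, ajovy]
  eptinezumab: [eptinezumab, vyepti]
# Drug-mention roles that attribute a case to a target drug.
# PS = primary suspect, SS = secondary suspect; C (concomitant) and
# I (interacting) are excluded from the default suspect-only policy.
roles: [PS, SS]
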