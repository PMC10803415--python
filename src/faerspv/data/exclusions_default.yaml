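# Default adverse-event exclusion policy.
# Five families are screened out before disproportionality: product
# problems, medication errors, off-label / unlicensed use, indication
# terms, and disease states.  Each entry declares its matching rule:
#   match: exact     -> case-insensitive whole-PT comparison
#   match: substring -> case-insensitive containment
pt_terms:
  - {term: product, match: substring, reason: product-problem}
  - {term: medication error, match: substring, reason: medication-error}
  - {term: accidental overdose, match: exact, reason: medication-error}
  - {term: off label, match: substring, reason: off-label}
  - {term: unlicensed use, match: exact, reason: off-label}
  - {term: migraine, match: substring, reason: indication}
  - {term: headache, match: substring, reason: indication}
  - {term: drug ineffective, match: exact, reason: disease-state}
  - {term: condition aggravated, match: exact, reason: disease-state}
# PTs whose mapped SOC appears here are removed wholesale.
socs:
  - Product issues
# Exact PT terms treated as injection/infusion-related in addition to the
# built-in substring triggers ("injection site", "infusion site",
# "infusion related").  Empty by default: fear-of-injection terms are
# conventionally reported as ordinary co-reported AEs.
injection_terms: []
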