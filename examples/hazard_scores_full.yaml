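# Polymer hazard scores (S_n) for the risk assessment.
#
# Only PP and PVC ship as package defaults; the remaining scores below follow
# the GHS-based chemical hazard ranking of polymers commonly used for such
# assessments and are supplied here as USER CONFIGURATION, not authoritative
# package constants.  Adjust to your preferred ranking before use.
PE: 11
PP: 1
PS: 30
PET: 4
PVC: 10001
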