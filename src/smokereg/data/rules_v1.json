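{
  "version": "1",
  "comment": "Ordered extraction patterns for smoking-behavior quantities. {NUM} expands to the numeric sub-pattern (digits, decimals, and the word numbers one..ten / half / a / an). Every quantity pattern names its capture group 'value'. Tiers are evaluated in the listed order: pack_years short-circuits the rest.",
  "tiers": {
    "pack_years": [
      "\\b(?P<value>{NUM})\\s*\\+?\\s*(?:pack|pk)[\\s-]*(?:years?|yrs?)\\b",
      "\\b(?P<value>{NUM})\\s*p\\.?y\\.?\\b",
      "\\b(?:pack|pk)[\\s-]*(?:years?|yrs?)\\s*(?:history)?\\s*[:=]\\s*(?P<value>{NUM})\\b"
    ],
    "packs_per_day": [
      "\\b(?P<value>{NUM})\\s*ppd\\b",
      "\\b(?P<value>{NUM})\\s*(?:(?:of\\s+)?a\\s+)?(?:packs?|pks?)\\s*(?:per|a|each|/)\\s*d(?:ay)?\\b",
      "\\b(?:packs?\\s*(?:per|/)\\s*day|ppd)\\s*[:=]\\s*(?P<value>{NUM})\\b"
    ],
    "cigarettes_per_day": [
      "\\b(?P<value>{NUM})\\s*(?:cigarettes?|cigs?)\\s*(?:per|a|each|/)\\s*d(?:ay)?\\b",
      "\\b(?P<value>{NUM})\\s*cpd\\b",
      "\\b(?:cigarettes?|cigs?)\\s*(?:per|/)\\s*day\\s*[:=]\\s*(?P<value>{NUM})\\b"
    ],
    "years_smoked": [
      "\\b(?:for|x)\\s*(?P<value>{NUM})\\s*(?:years?|yrs?)\\b",
      "\\bsmok(?:ed|es|ing)?\\s*(?:for\\s*)?(?P<value>{NUM})\\s*(?:years?|yrs?)\\b",
      "\\b(?P<value>{NUM})[\\s-]*(?:years?|yrs?)\\s+(?:of\\s+)?(?:smoking|tobacco|cigarettes?)\\b",
      "\\b(?P<value>{NUM})[\\s-]*(?:years?|yrs?)\\s+(?:smoking\\s+)?(?:hx|history)\\b"
    ]
  },
  "cessation_cues": [
    "\\bquit\\b",
    "\\bstopped\\b",
    "\\bstopped\\s+smoking\\b",
    "\\bcessation\\b",
    "\\bgave\\s+up\\b",
    "\\bdiscontinued\\b",
    "\\bsmoke[\\s-]*free\\s+since\\b",
    "\\btobacco[\\s-]*free\\s+since\\b",
    "\\bex[\\s-]*smoker\\s+since\\b"
  ]
}
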