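{
  "version": "1",
  "comment": "Template bank for the synthetic semi-structured note generator. {smokes} is a status-tensed verb phrase; {v}=pack years, {i}=packs/day, {c}=cigarettes/day, {y}=years smoked; date fields are filled per format. Entries may pin constant quantities via 'const'.",
  "status_sentences": {
    "never": [
      "Patient denies tobacco use",
      "No smoking history",
      "Never smoker",
      "Denies cigarette use",
      "No tobacco use reported",
      "Nonsmoker",
      "Patient has never smoked cigarettes",
      "Negative for tobacco use"
    ],
    "former": [
      "Former smoker",
      "Patient is an ex-smoker",
      "Past tobacco use",
      "Former cigarette smoker",
      "Remote smoking history, now abstinent"
    ],
    "current": [
      "Current smoker",
      "Patient smokes daily",
      "Active tobacco use",
      "Patient continues to smoke cigarettes",
      "Current every day smoker",
      "Ongoing cigarette use"
    ],
    "smoker": [
      "Positive smoking history, temporality unclear",
      "History of tobacco use",
      "Tobacco use documented, unclear if ongoing",
      "Smoking history noted in chart"
    ],
    "unknown_hotspot": [
      "Smoke detector in the home was checked",
      "Counseled on secondhand smoke exposure at work",
      "Home smoke alarm is functional",
      "Reviewed workplace tobacco policy handout"
    ]
  },
  "no_info_social": [
    "Lives alone",
    "Lives with spouse and two children",
    "Works as a teacher",
    "Retired, walks daily",
    "Alcohol use is occasional",
    "Employed full time"
  ],
  "behavior": {
    "complete": [
      {"text": "{v} pack year history"},
      {"text": "Pack years: {v}"},
      {"text": "{v} pack-year smoking history"},
      {"text": "Approximately {v} pack years"}
    ],
    "computed_ppd": [
      {"text": "{smokes} {i} ppd x {y} yrs"},
      {"text": "{smokes} {i} packs per day for {y} years"},
      {"text": "{smokes} {i} pack per day, for {y} years"}
    ],
    "computed_cpd": [
      {"text": "{smokes} {c} cigarettes a day for {y} years"},
      {"text": "{smokes} {c} cigs per day for {y} years"}
    ],
    "partial_ppd": [
      {"text": "{smokes} {i} ppd"},
      {"text": "{smokes} {i} packs per day"},
      {"text": "{smokes} about half a pack per day", "const": {"packs_per_day": 0.5}},
      {"text": "{smokes} a pack a day", "const": {"packs_per_day": 1.0}}
    ],
    "partial_cpd": [
      {"text": "{smokes} {c} cigarettes per day"},
      {"text": "{smokes} roughly {c} cigs a day"}
    ],
    "partial_years": [
      {"text": "{smoked} for {y} years"},
      {"text": "{y} years of smoking"}
    ]
  },
  "cessation": {
    "slash_day": "Quit smoking {mm}/{dd}/{yyyy}",
    "short_slash_day": "Quit smoking {m}/{d}/{yy}",
    "month_day_year": "Patient quit {month} {d}, {yyyy}",
    "month_year": "Stopped smoking {month} {yyyy}",
    "year": "Quit tobacco in {yyyy}",
    "vague_decade": "Patient quit in the late {decade}s"
  },
  "distractor_dates": [
    "CBC drawn {mm}/{dd}/{yyyy}",
    "Labs reviewed from {mm}/{dd}/{yyyy}",
    "Last mammogram {month} {yyyy}",
    "Follow-up visit scheduled {m}/{d}/{yy}",
    "Colonoscopy completed in {yyyy}"
  ],
  "fillers": {
    "health_summary": [
      "Immunizations are up to date",
      "Hypertension, well controlled on lisinopril",
      "Type 2 diabetes, diet controlled",
      "Seasonal allergies",
      "No known drug allergies",
      "Osteoarthritis of the knees"
    ],
    "impressions": [
      "Patient feels well today",
      "No acute distress",
      "Continue current medications",
      "Discussed diet and exercise",
      "Return to clinic as needed",
      "Sleep is adequate"
    ]
  }
}
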