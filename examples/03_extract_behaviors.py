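"""Extract pack-year history and cessation dates from smoker sentences.

Pack-year extraction is a tiered hierarchy: an explicit pack-year statement
wins; otherwise intensity (packs/day or cigarettes/day) is combined with
duration to compute pack-years at 20 cigarettes per pack; intensity or
duration alone yields a partial finding. Cessation dates must share a
sentence with a quit cue, and vague decades or ranges are rejected.
"""

from smokereg import RuleSet, extract_cessation_date, extract_pack_years

rules = RuleSet.load()

print("Pack-year tier hierarchy:")
for text in [
    "45 pack year smoking history.",
    "Smokes 2 packs per day for 15 years.",
    "Smokes 10 cigarettes a day for 10 years.",
    "Smokes about half a pack per day.",
    "Smoked for 30 years.",
]:
    f = extract_pack_years(text, rules)
    print(f"  {text!r}")
    print(f"    kind={f.kind}  pack_years={f.pack_years}  "
          f"ppd={f.packs_per_day}  cpd={f.cigarettes_per_day}  years={f.years_smoked}")

print("\nCessation dates (cue-anchored, same sentence):")
for text in [
    "Quit smoking 03/15/2010.",
    "Patient stopped smoking March 2008.",
    "She quit tobacco in 1995.",
    "Quit in the late 1980s.",          # vague decade -> rejected
    "Labs drawn 03/15/2010. Quit previously.",  # date not in cue sentence -> rejected
]:
    f = extract_cessation_date(text, rules)
    if f is None:
        print(f"  {text!r} -> no finding")
    else:
        print(f"  {text!r} -> {f.date.isoformat()} (precision: {f.precision})")
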