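"""The cleaning cascade and the canonical lookup form.

Free-text drug names are matched iteratively: the raw name first, then
progressively cleaned variants (trailing dots, parentheticals and
symbols, dosage tokens, route/dose-form tokens). All lookups key on a
canonical form that is case-, word-order-, abbreviation- and
spelling-variant-insensitive — but never fuzzy: a misspelling fails.
"""

from faersnorm import canonical_form, clean_cascade

name = "TIMOLOL 0.5% (EYE DROPS)..."
print(f"cascade for {name!r}:")
for stage, variant in clean_cascade(name):
    print(f"  {stage:14s} {variant!r}")

print()
pairs = [
    ("Acetaminophen 500 MG Oral Tablet", "oral tablet acetaminophen 500 mg"),
    ("SULPHASALAZINE", "sulfasalazine"),
    ("Metformin HCL", "metformin hydrochloride"),
]
for a, b in pairs:
    same = canonical_form(a) == canonical_form(b)
    print(f"canonical({a!r}) == canonical({b!r}) -> {same}")

print()
print("The last cascade variant is the bare ingredient name, which is what")
print("an exact vocabulary lookup can match; the canonical-form pairs show")
print("which surface differences are neutralized before any lookup.")
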