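"""Estimate fetal weight from biometry with all four Hadlock formulas.

Typical late-third-trimester measurements (cm) go in; grams come out.  The
four formulas use different measurement subsets and give slightly different
estimates — their spread is one reason volumetric MRI weight is attractive.
"""

from fetalvol import BiometrySet, hadlock_weight

b = BiometrySet(HC=32.5, BPD=9.0, AC=33.0, FL=7.0)
print("biometry:", b)
for formula in (1, 2, 3, 4):
    w = hadlock_weight(formula, b)
    print(f"Hadlock {formula}: {w.grams:7.1f} g   ({w.source})")
# All four should fall in a plausible ~2.5-3.5 kg band for these inputs and
# must increase if any single measurement increases.
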