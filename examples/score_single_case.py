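"""Score one adverse-drug-reaction case directly through the API.

A patient developed a rash after starting a new antibiotic; the rash
improved on withdrawal, there are prior reports of this reaction, and no
alternative cause was found.  We encode the assessor's answers and score
them.
"""

from naranjo import AnswerVector, ResponseOption, assess, build_naranjo_scale

Y, N, X = ResponseOption.YES, ResponseOption.NO, ResponseOption.UNKNOWN

scale = build_naranjo_scale()
answers = AnswerVector({
    1: Y,   # previous conclusive reports exist
    2: Y,   # reaction appeared after the drug was given
    3: Y,   # improved on discontinuation
    4: X,   # drug was not readministered
    5: N,   # no alternative cause
    6: X,   # no placebo trial
    7: X,   # no drug-level measurement
    8: X,   # dose was not changed
    9: N,   # no similar prior reaction
    10: Y,  # rash documented by objective exam
})

result = assess(scale, case_id="rash-001", answers=answers)
print(f"case {result.case_id}: total score {result.total} -> {result.category.label}")
for index, points in sorted(result.contributions.items()):
    print(f"  Q{index}: {points:+d}")

# Total 7 falls in the 5-8 bin: the drug is a Probable cause of the rash.
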