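"""The clustering observation that motivates the plateau method.

Healthy values of a biomarker occupy a narrow min-to-max band while
pathological values spread over a far wider one.  Fasting blood glucose
makes the point: the healthy band is 70-99 mg/dl, while diabetic values
can in theory run from 100 mg/dl to the 2,656 mg/dl survival record.
"""

from enorms import min_max_difference

healthy = min_max_difference([70.0, 99.0])
diabetic = min_max_difference([100.0, 2656.0])

print(f"healthy fasting glucose spread:  {healthy:.0f} mg/dl")
print(f"theoretical diabetic spread:   {diabetic:.0f} mg/dl")
print(f"ratio: {diabetic / healthy:.0f}x wider")
print("On a sorted rank plot the tight healthy cluster becomes a flat "
      "plateau; the wide pathological tails become steep flanks.")
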