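"""Quantify chlorophyll from extract absorbances and convert to area basis.

A 0.2 g leaf sample extracted into 25 mL of 95% ethanol, read at 665 and
649 nm; LMA converts the mass-based content into the area density Cc that
the light-capture nitrogen pool needs.
"""

from leafn import PigmentRecord
from leafn.pigments import quantify_record

record = PigmentRecord(sample_id="leaf-1", a665=0.82, a649=0.31)
result = quantify_record(record, lma=55.0)

print(f"chlorophyll a: {result.chla:.3f} mg/g")
print(f"chlorophyll b: {result.chlb:.3f} mg/g")
print(f"total:         {result.chlt:.3f} mg/g  (a/b ratio {result.chla_chlb_ratio:.2f})")
print(f"area density:  {result.cc:.4f} mmol/m2 at LMA 55 g/m2")
print("\nCc / 2.15 gives the light-capture nitrogen pool Ncl in g N m-2.")
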