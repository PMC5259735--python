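"""Evaluate the three trajectory curves at the published estimates.

Prints day-12 values for the large-seed class: total root length follows
the expolinear curve (exponential phase turning linear with slope Cm),
primary root length follows a Gompertz sigmoid saturating at Wf, and
cotyledon dry weight follows a logistic decay toward the Min plateau as
reserves are remobilized into the seedling.
"""

import seedlingfit as sf

trl = sf.ExpolinearParams(cm=149.52, rm=0.92, tb=6.22)
prl = sf.GompertzParams(wf=26.99, k=0.26, tt=5.51)
cdw = sf.DecayParams(maximum=0.436, minimum=0.058, tt=6.012)

print(f"TRL day 12 : {sf.expolinear_value(trl, 12.0):8.1f} cm "
      "(deep in the linear phase, growing ~Cm = 149.5 cm/d)")
print(f"PRL day 12 : {sf.gompertz_value(prl, 12.0):8.2f} cm "
      f"(approaching the asymptote Wf = {prl.wf} cm)")
print(f"PRL at TT  : {sf.gompertz_value(prl, prl.tt):8.2f} cm "
      "(= Wf/e, the inflection identity)")
print(f"CDW day 12 : {sf.decay_value(cdw, 12.0):8.4f} g  "
      f"(cotyledons nearly exhausted, Min = {cdw.minimum} g)")
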