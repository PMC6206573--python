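# QED desirability parameters (Bickerton et al. 2012, Nat. Chem. 4:90-98).
# Each property's desirability d(x) is an asymmetric double sigmoid:
#   d(x) = [ a + b / (1 + exp(-(x - c + d/2)/e)) * (1 - 1/(1 + exp(-(x - c - d/2)/f))) ] / dmax
# Weights are the mean-information-content weighting (QED_w,mo) of the same reference.
properties:
  mw:     {a: 2.817065973, b: 392.5754953, c: 290.7489764, d: 2.419764353, e: 49.22325677, f: 65.37051707, dmax: 104.9805561}
  alogp:  {a: 3.172690585, b: 137.8624751, c: 2.534937431, d: 4.581497897, e: 0.822739154, f: 0.576295591, dmax: 131.3186604}
  hba:    {a: 2.948620388, b: 160.4605972, c: 3.615294657, d: 4.435986202, e: 0.290141953, f: 1.300669958, dmax: 148.7763046}
  hbd:    {a: 1.618662227, b: 1010.051101, c: 0.985094388, d: 1.0e-09,     e: 0.713820843, f: 0.920922555, dmax: 258.1632616}
  psa:    {a: 1.876861559, b: 125.2232657, c: 62.90773554, d: 87.83366614, e: 12.01999824, f: 28.51324732, dmax: 104.5686167}
  rotb:   {a: 0.01,        b: 272.4121427, c: 2.55837997,  d: 1.565547684, e: 1.271567166, f: 2.758063707, dmax: 105.4420403}
  arom:   {a: 3.21778897,  b: 957.7374108, c: 2.274627939, d: 1.0e-09,     e: 1.317690384, f: 0.375760881, dmax: 312.337261}
  alerts: {a: 0.01,        b: 1199.094025, c: -0.09002883, d: 1.0e-09,     e: 0.185904477, f: 0.875193782, dmax: 417.725314}
weights:
  mw: 0.66
  alogp: 0.46
  hba: 0.05
  hbd: 0.61
  psa: 0.06
  rotb: 0.65
  arom: 0.48
  alerts: 0.95
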