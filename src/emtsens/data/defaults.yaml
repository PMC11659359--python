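# Baseline parameterization of the E-cadherin/Slug EMT switch model and the
# study design built on it.  One key per tabulated quantity:
#
#   dimensional.parameters      assumed value, units and definition of each rate
#                               and half-maximal constant of the dimensional model
#   dimensional.hill            fixed Hill coefficients (never sampled)
#   dimensional.ranges          sampling range of each varied parameter; alpha2 and
#                               k1 are shifted off-center (width preserved) to keep
#                               one-at-a-time sweeps monotone and states nonnegative
#   dimensional.treatments      contact / TGF-beta levels and per-contact initial
#                               conditions (E0, S0) in ng/mL
#   nondimensional.ranges       per-set sampling ranges of the grouped parameters;
#                               `null` marks the grouping that defines the time
#                               scale gamma and is held at 1.00 (not varied);
#                               A2 and K1 are shifted analogously to alpha2 / k1
#   nondimensional.treatments   mu / theta levels and initial conditions (e0, s0)
#   study                       defaults of the full sampling/sensitivity study

dimensional:
  parameters:
    alpha1: {value: 0.19355, units: "ng/(mL*min)", definition: "E-cadherin production"}
    alpha2: {value: 0.080,   units: "ng/(mL*min)", definition: "Slug production"}
    beta1:  {value: 6.035,   units: "1/min",       definition: "E-cadherin degradation"}
    beta2:  {value: 0.830,   units: "1/min",       definition: "Slug degradation"}
    k0:     {value: 0.1245,  units: "ng/(mL*min)", definition: "E-cadherin membrane recruitment by cell-cell contact"}
    k1:     {value: 0.080,   units: "ng/(mL*min)", definition: "Slug suppression by membrane-bound E-cadherin"}
    k2:     {value: 0.040,   units: "ng/(mL*min)", definition: "Slug upregulation via TGF-beta"}
    IC_S:   {value: 0.01920, units: "ng/mL",       definition: "half-maximal Slug for E-cadherin inhibition"}
    IC_E:   {value: 0.010,   units: "ng/mL",       definition: "half-maximal E-cadherin for Slug suppression"}
    IC_T:   {value: 3.64e-6, units: "ng/mL",       definition: "half-maximal TGF-beta for Slug activation"}
    IC_C:   {value: 2.17,    units: "cells",       definition: "half-maximal neighbor count for membrane recruitment"}
  hill: {n1: 3, n2: 4, n3: 2, n4: 3}
  ranges:
    alpha1: [0.1742, 0.2129]
    alpha2: [0.0772, 0.0932]
    beta1:  [5.4315, 6.6385]
    beta2:  [0.7470, 0.9130]
    k0:     [0.1120, 0.1370]
    k1:     [0.0669, 0.0829]
    k2:     [0.0360, 0.0440]
    IC_S:   [0.0173, 0.0211]
    IC_E:   [0.0090, 0.0110]
    IC_T:   [3.2760e-6, 4.0040e-6]
    IC_C:   [1.9530, 2.3870]
  shifted: [alpha2, k1]
  treatments:
    contact_levels: [0.0, 1.0, 2.0, 6.0]
    tgfb_levels: [0.0, 3.64e-6]
    initial_conditions:
      "0": [0.0003, 0.0963]
      "1": [0.0280, 0.0109]
      "2": [0.0399, 0.0057]
      "6": [0.0522, 0.0034]

nondimensional:
  shifted: [A2, K1]
  ranges:
    set1: {A1: null, K0: [0.5814, 0.7106], B1: [0.2808, 0.3432], A2: [0.2073, 0.2503], K1: [0.1800, 0.2230], K2: [0.0972, 0.1188], B2: [0.0387, 0.0473]}
    set2: {A1: [1.3995, 1.7105], K0: null, B1: [0.4365, 0.5335], A2: [0.3230, 0.3900], K1: [0.2805, 0.3475], K2: [0.1503, 0.1837], B2: [0.0603, 0.0737]}
    set3: {A1: [2.8863, 3.5277], K0: [1.8567, 2.2693], B1: null, A2: [0.6651, 0.8031], K1: [0.5778, 0.7158], K2: [0.3105, 0.3795], B2: [0.1242, 0.1518]}
    set4: {A1: [4.1805, 5.1095], K0: [2.6892, 3.2868], B1: [1.3032, 1.5928], A2: null, K1: [0.8364, 1.0364], K2: [0.4500, 0.5500], B2: [0.1791, 0.2189]}
    set5: {A1: [4.1805, 5.1095], K0: [2.6892, 3.2868], B1: [1.3032, 1.5928], A2: [0.9649, 1.1649], K1: null, K2: [0.4500, 0.5500], B2: [0.1791, 0.2189]}
    set6: {A1: [8.3610, 10.2190], K0: [5.3784, 6.5736], B1: [2.6073, 3.1867], A2: [1.9277, 2.3277], K1: [1.6750, 2.0750], K2: null, B2: [0.3582, 0.4378]}
    set7: {A1: [20.9871, 25.6509], K0: [13.5000, 16.5000], B1: [6.5439, 7.9981], A2: [4.8384, 5.8424], K1: [4.2043, 5.2083], K2: [2.2590, 2.7610], B2: null}
  treatments:
    contact_levels: [0.0, 0.46, 0.92, 2.76]
    tgfb_levels: [0.0, 1.0]
    initial_conditions:
      "0":    [0.0251, 5.0220]
      "0.46": [2.7923, 0.5712]
      "0.92": [3.9869, 0.2974]
      "2.76": [5.2185, 0.1780]

study:
  n_samples: 10000
  t_end: 10000.0
  threshold: 0.5
  rounding:
    dimensional: 1.0e-4
    nondimensional: 1.0e-2
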