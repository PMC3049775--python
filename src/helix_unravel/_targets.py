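"""Frozen torsion-space way-point conformations for the scenario generator.

Each target lists phi, psi, chi1, chi2 (degrees) for residues 13..26.
The helical/open/partial/extended states use clash-aware rotamer
selection; the clustered and polar-bridged states were constructed by
dihedral-space energy optimisation (see docs/methods.md). They are
design artifacts of the generator, not fitted quantities.
"""

TARGETS = {
 "helix": {
  "phi": [
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0
  ],
  "psi": [
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0
  ],
  "chi1": [
   60.0,
   90.0,
   90.0,
   120.0,
   90.0,
   180.0,
   120.0,
   120.0,
   180.0,
   120.0,
   120.0,
   -150.0,
   180.0,
   180.0
  ],
  "chi2": [
   90.0,
   90.0,
   180.0,
   180.0,
   175.0,
   0.0,
   90.0,
   90.0,
   0.0,
   180.0,
   0.0,
   0.0,
   0.0,
   0.0
  ]
 },
 "open": {
  "phi": [
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0
  ],
  "psi": [
   -47.0,
   -47.0,
   -47.0,
   -17.0,
   -17.0,
   -17.0,
   -17.0,
   -17.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0
  ],
  "chi1": [
   0.0,
   90.0,
   180.0,
   30.0,
   0.0,
   180.0,
   150.0,
   150.0,
   180.0,
   60.0,
   60.0,
   0.0,
   180.0,
   -60.0
  ],
  "chi2": [
   -150.0,
   90.0,
   -120.0,
   180.0,
   150.0,
   0.0,
   120.0,
   -90.0,
   0.0,
   180.0,
   -30.0,
   0.0,
   0.0,
   0.0
  ]
 },
 "partial": {
  "phi": [
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -57.0,
   -140.0,
   -140.0,
   -57.0,
   -57.0,
   -57.0
  ],
  "psi": [
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   -47.0,
   135.0,
   135.0,
   -47.0,
   -47.0,
   -47.0
  ],
  "chi1": [
   60.0,
   90.0,
   90.0,
   90.0,
   90.0,
   180.0,
   60.0,
   120.0,
   180.0,
   120.0,
   150.0,
   -150.0,
   180.0,
   180.0
  ],
  "chi2": [
   90.0,
   90.0,
   180.0,
   180.0,
   175.0,
   0.0,
   90.0,
   90.0,
   0.0,
   180.0,
   0.0,
   0.0,
   0.0,
   0.0
  ]
 },
 "extended": {
  "phi": [
   -140.0,
   -140.0,
   -140.0,
   -140.0,
   -140.0,
   -140.0,
   -140.0,
   -140.0,
   -140.0,
   -140.0,
   -140.0,
   -140.0,
   -140.0,
   -140.0
  ],
  "psi": [
   135.0,
   135.0,
   135.0,
   135.0,
   135.0,
   135.0,
   135.0,
   135.0,
   135.0,
   135.0,
   135.0,
   135.0,
   135.0,
   135.0
  ],
  "chi1": [
   30.0,
   120.0,
   120.0,
   120.0,
   120.0,
   -60.0,
   120.0,
   120.0,
   180.0,
   120.0,
   120.0,
   -60.0,
   180.0,
   -150.0
  ],
  "chi2": [
   90.0,
   90.0,
   180.0,
   180.0,
   175.0,
   0.0,
   90.0,
   90.0,
   0.0,
   180.0,
   0.0,
   0.0,
   0.0,
   0.0
  ]
 },
 "cluster": {
  "phi": [
   -55.81,
   -56.96,
   -59.35,
   -55.16,
   -19.29,
   -61.36,
   -61.64,
   -59.41,
   -59.73,
   -0.2,
   -104.31,
   -98.86,
   -72.31,
   -57.53
  ],
  "psi": [
   -47.41,
   -49.02,
   -48.16,
   -53.18,
   -30.74,
   -40.78,
   -31.77,
   -39.03,
   -69.84,
   -119.73,
   23.78,
   -32.87,
   53.15,
   -46.82
  ],
  "chi1": [
   59.77,
   89.68,
   89.89,
   119.94,
   180.0,
   180.0,
   73.05,
   172.16,
   180.0,
   119.88,
   120.1,
   -145.89,
   180.0,
   180.0
  ],
  "chi2": [
   89.98,
   89.99,
   180.0,
   180.0,
   158.08,
   0.0,
   80.62,
   1.06,
   0.0,
   180.0,
   -0.04,
   0.0,
   0.0,
   0.0
  ]
 },
 "polar": {
  "phi": [
   -58.59,
   -58.37,
   -62.17,
   -46.7,
   -58.66,
   -82.07,
   -87.98,
   -65.25,
   -69.33,
   -61.77,
   -49.96,
   -51.17,
   -50.73,
   -55.57
  ],
  "psi": [
   -45.31,
   -50.33,
   -39.21,
   -43.63,
   -42.88,
   13.31,
   2.74,
   -56.26,
   -57.26,
   -40.24,
   -37.24,
   -40.92,
   -47.43,
   -49.03
  ],
  "chi1": [
   75.17,
   -160.73,
   148.69,
   180.0,
   90.0,
   -120.46,
   119.02,
   90.11,
   180.0,
   32.42,
   122.61,
   -150.0,
   180.0,
   -120.13
  ],
  "chi2": [
   89.98,
   91.27,
   180.0,
   180.0,
   175.0,
   0.0,
   90.03,
   89.93,
   0.0,
   180.0,
   -1.34,
   0.0,
   0.0,
   0.0
  ]
 }
}
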