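{
 "init": [
  3.61,
  4.09
 ],
 "source": "aptalogic-1.0 RNA/RNA nearest-neighbor set (Turner-style WC + wobble)",
 "stacks": {
  "AA/UU": [
   -6.82,
   -0.93
  ],
  "AG/UU": [
   -3.96,
   -0.55
  ],
  "AU/UA": [
   -9.38,
   -1.1
  ],
  "AU/UG": [
   -7.25,
   -1.36
  ],
  "CA/GU": [
   -10.44,
   -2.11
  ],
  "CG/GC": [
   -10.64,
   -2.36
  ],
  "CG/GU": [
   -5.61,
   -1.41
  ],
  "CU/GA": [
   -10.48,
   -2.08
  ],
  "CU/GG": [
   -9.26,
   -2.11
  ],
  "GA/CU": [
   -12.44,
   -2.35
  ],
  "GA/UU": [
   -6.45,
   -1.27
  ],
  "GC/CG": [
   -14.88,
   -3.42
  ],
  "GC/UG": [
   -8.88,
   -2.11
  ],
  "GG/CC": [
   -13.39,
   -3.26
  ],
  "GG/CU": [
   -7.36,
   -1.53
  ],
  "GG/UC": [
   -9.06,
   -1.8
  ],
  "GG/UU": [
   -4.17,
   -0.5
  ],
  "GU/CA": [
   -11.4,
   -2.24
  ],
  "GU/CG": [
   -9.97,
   -2.51
  ],
  "GU/UG": [
   2.34,
   0.47
  ],
  "UA/AU": [
   -7.69,
   -1.33
  ],
  "UG/AU": [
   -6.8,
   -1.0
  ],
  "UG/GU": [
   -4.61,
   -0.6
  ],
  "UU/GG": [
   -6.21,
   -0.9
  ]
 },
 "terminal_weak": [
  3.72,
  0.45
 ],
 "wobble": true
}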