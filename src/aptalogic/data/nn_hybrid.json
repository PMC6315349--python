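{
 "init": [
  1.9,
  3.1
 ],
 "source": "aptalogic-1.0 RNA/DNA hybrid nearest-neighbor set (Sugimoto style)",
 "stacks": {
  "AA/TT": [
   -7.8,
   -1.0
  ],
  "AC/TG": [
   -5.9,
   -2.1
  ],
  "AG/TC": [
   -9.1,
   -1.8
  ],
  "AU/TA": [
   -8.3,
   -0.9
  ],
  "CA/GT": [
   -9.0,
   -0.9
  ],
  "CC/GG": [
   -9.3,
   -2.1
  ],
  "CG/GC": [
   -16.3,
   -1.7
  ],
  "CU/GA": [
   -7.0,
   -0.9
  ],
  "GA/CT": [
   -5.5,
   -1.3
  ],
  "GC/CG": [
   -8.0,
   -2.7
  ],
  "GG/CC": [
   -12.8,
   -2.9
  ],
  "GU/CA": [
   -7.8,
   -1.1
  ],
  "UA/AT": [
   -7.8,
   -0.6
  ],
  "UC/AG": [
   -8.6,
   -1.5
  ],
  "UG/AC": [
   -10.4,
   -1.6
  ],
  "UU/AA": [
   -11.5,
   -0.2
  ]
 },
 "terminal_weak": [
  0.0,
  0.0
 ],
 "wobble": false
}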