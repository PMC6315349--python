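{
 "init": [
  0.2,
  1.96
 ],
 "source": "aptalogic-1.0 DNA/DNA nearest-neighbor set (SantaLucia-unified style)",
 "stacks": {
  "AA/TT": [
   -7.9,
   -1.0
  ],
  "AT/TA": [
   -7.2,
   -0.88
  ],
  "CA/GT": [
   -8.5,
   -1.45
  ],
  "CG/GC": [
   -10.6,
   -2.17
  ],
  "CT/GA": [
   -7.8,
   -1.28
  ],
  "GA/CT": [
   -8.2,
   -1.3
  ],
  "GC/CG": [
   -9.8,
   -2.24
  ],
  "GG/CC": [
   -8.0,
   -1.84
  ],
  "GT/CA": [
   -8.4,
   -1.44
  ],
  "TA/AT": [
   -7.2,
   -0.58
  ]
 },
 "terminal_weak": [
  2.2,
  0.05
 ],
 "wobble": false
}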