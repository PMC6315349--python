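{
 "bulge": {
  "1": 3.8,
  "2": 2.8,
  "3": 3.2,
  "4": 3.6,
  "5": 4.0,
  "6": 4.4
 },
 "hairpin": {
  "3": 5.4,
  "4": 5.6,
  "5": 5.7,
  "6": 5.4,
  "7": 6.0,
  "8": 5.5,
  "9": 6.4
 },
 "internal": {
  "10": 2.5,
  "2": 1.5,
  "3": 1.6,
  "4": 1.7,
  "5": 1.8,
  "6": 2.0,
  "7": 2.2,
  "8": 2.3,
  "9": 2.4
 },
 "max_tabulated": {
  "bulge": 6,
  "hairpin": 9,
  "internal": 10
 },
 "multiloop_a": 3.4,
 "multiloop_b": 0.4,
 "multiloop_c": 0.0,
 "source": "aptalogic-1.0 loop penalties (Turner-style, entropic T-scaling)"
}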