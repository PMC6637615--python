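{
 "relations": {
  "R1: E1 catalyses M0 -> M1": "published",
  "reg1: TF0 inhibits expression of TF1": "published",
  "reg2: TF0 activates expression of E5": "published",
  "R2: E2 catalyses M1 + water -> M2": "invented",
  "R3: E3 catalyses M2 -> M3": "invented",
  "R4: E4 catalyses M3 -> M4": "invented",
  "R5: E5 catalyses M5 -> M0": "invented",
  "reg3: TF1 activates E2": "invented",
  "reg4: TF1 inhibits E3": "invented",
  "reg5: TF2 activates E4": "invented",
  "reg6: M3 inhibits enzyme E1": "invented",
  "reg7: M5 cofactor of enzyme E1": "invented",
  "tu1: gE2/gE3 co-transcribed": "invented",
  "TF0_dim: homodimer of TF0": "invented"
 },
 "counts": {
  "entities": 24,
  "reactions": 5,
  "regulations": 7,
  "transcription_units": 1
 }
}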