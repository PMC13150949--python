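{
  "description": "Per-D-gene map from germline translation offset (0/1/2) to the Ichihara-Kurosawa reading-frame label. Calibrated on the bundled D set so that RFI is the tyrosine-rich frame, RFII the hydrophobic (valine-rich) frame and RFIII the leucine/arginine/stop-bearing frame.",
  "version": "1",
  "default": {"0": "I", "1": "II", "2": "III"},
  "genes": {
    "D1-1": {"0": "II", "1": "III", "2": "I"},
    "D1-2": {"0": "II", "1": "III", "2": "I"},
    "D2-2": {"0": "II", "1": "III", "2": "I"},
    "D2-3": {"0": "II", "1": "III", "2": "I"},
    "D4-1": {"0": "II", "1": "III", "2": "I"}
  }
}
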