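{
  "name": "Lehninger",
  "source": "Nelson & Cox, Lehninger Principles of Biochemistry, amino-acid pKa table",
  "positive": {"R": 12.48, "K": 10.53, "H": 6.00},
  "negative": {"D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07},
  "n_term": 9.69,
  "c_term": 2.34
}
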