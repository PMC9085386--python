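{
 "names": [
  "AVBL",
  "AVBR",
  "PVCL",
  "PVCR",
  "AVAL",
  "AVAR",
  "AVDL",
  "AVDR",
  "AVEL",
  "AVER"
 ],
 "W": [
  [
   0.0,
   0.9,
   0.5,
   0.5,
   -0.45,
   -0.45,
   0.0,
   0.0,
   -0.15,
   -0.15
  ],
  [
   0.9,
   0.0,
   0.5,
   0.5,
   -0.45,
   -0.45,
   0.0,
   0.0,
   -0.15,
   -0.15
  ],
  [
   0.0,
   0.0,
   0.1,
   0.3,
   -0.3,
   -0.3,
   0.0,
   0.0,
   -0.15,
   -0.15
  ],
  [
   0.0,
   0.0,
   0.3,
   0.0,
   -0.3,
   -0.3,
   0.0,
   0.0,
   -0.15,
   -0.15
  ],
  [
   -0.5,
   -0.5,
   -0.3,
   -0.3,
   0.0,
   0.45,
   0.45,
   0.45,
   0.75,
   0.75
  ],
  [
   -0.5,
   -0.5,
   -0.3,
   -0.3,
   0.45,
   0.0,
   0.45,
   0.45,
   0.75,
   0.75
  ],
  [
   -0.15,
   -0.15,
   0.0,
   0.0,
   0.15,
   0.15,
   0.0,
   0.3,
   0.0,
   0.0
  ],
  [
   -0.15,
   -0.15,
   0.0,
   0.0,
   0.15,
   0.15,
   0.3,
   0.0,
   0.0,
   0.0
  ],
  [
   -0.3,
   -0.3,
   0.0,
   0.0,
   0.5,
   0.5,
   0.0,
   0.0,
   0.0,
   0.1
  ],
  [
   -0.3,
   -0.3,
   0.0,
   0.0,
   0.5,
   0.5,
   0.0,
   0.0,
   0.0,
   0.0
  ]
 ],
 "G": [
  [
   0.0,
   1.5,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   1.5,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   2.0,
   0.3,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   2.0,
   0.0,
   0.0,
   0.3,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.3,
   0.0,
   0.0,
   1.5,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.3,
   1.5,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.0,
   0.0
  ]
 ],
 "tau": 1.0,
 "theta": 0.5,
 "k": 20.0,
 "B": [
  [
   1.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   1.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   1.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   1.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   1.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.0
  ]
 ]
}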