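{
 "version": "1.0",
 "presets": [
  {
   "name": "LN229-Control",
   "cell_line": "LN229",
   "pressure": 0.0,
   "wound_closure_ctrl": 0.57,
   "wound_closure_exp": 0.57,
   "elongated_fraction": 0.22,
   "mixture": {
    "weights": [
     0.95,
     0.05
    ],
    "mus": [
     -0.6831921503501014,
     0.11582868530700327
    ],
    "sigmas": [
     0.7447699011449884,
     0.05
    ]
   },
   "r2_reference": 0.94,
   "notes": "elongated fraction stand-in"
  },
  {
   "name": "LN229-Agar",
   "cell_line": "LN229",
   "pressure": 0.0,
   "wound_closure_ctrl": 0.57,
   "wound_closure_exp": 0.57,
   "elongated_fraction": 0.21,
   "mixture": {
    "weights": [
     0.95,
     0.05
    ],
    "mus": [
     -0.6629379132379314,
     0.17645330712343799
    ],
    "sigmas": [
     0.6902871648454961,
     0.05
    ]
   },
   "r2_reference": 0.98,
   "notes": ""
  },
  {
   "name": "LN229-23Pa",
   "cell_line": "LN229",
   "pressure": 23.0,
   "wound_closure_ctrl": 0.57,
   "wound_closure_exp": 0.802,
   "elongated_fraction": 0.391,
   "mixture": {
    "weights": [
     0.9,
     0.1
    ],
    "mus": [
     -0.3639339022697541,
     0.4886800148186709
    ],
    "sigmas": [
     0.7939259229135377,
     0.01
    ]
   },
   "r2_reference": 0.91,
   "notes": "secondary sigma^2 = 1e-4 (published); weight 0.10: peaks of similar height"
  },
  {
   "name": "LN229-47Pa",
   "cell_line": "LN229",
   "pressure": 47.0,
   "wound_closure_ctrl": 0.57,
   "wound_closure_exp": 0.67,
   "elongated_fraction": 0.25,
   "mixture": {
    "weights": [
     0.95,
     0.05
    ],
    "mus": [
     -0.6905379657399139,
     0.5083176023684519
    ],
    "sigmas": [
     0.8582414519820352,
     0.03872983346207417
    ]
   },
   "r2_reference": 0.99,
   "notes": "secondary sigma^2 = 1.5e-3 (published); closure stand-in"
  },
  {
   "name": "LN229-115Pa",
   "cell_line": "LN229",
   "pressure": 115.0,
   "wound_closure_ctrl": 0.57,
   "wound_closure_exp": 0.54,
   "elongated_fraction": 0.12,
   "mixture": {
    "weights": [
     1.0
    ],
    "mus": [
     -0.9738260307685557
    ],
    "sigmas": [
     0.8287974276342172
    ]
   },
   "r2_reference": 0.95,
   "notes": "closure and elongated fraction stand-ins (negative differential closure)"
  },
  {
   "name": "U251-Control",
   "cell_line": "U251",
   "pressure": 0.0,
   "wound_closure_ctrl": 0.367,
   "wound_closure_exp": 0.367,
   "elongated_fraction": 0.4,
   "mixture": {
    "weights": [
     1.0
    ],
    "mus": [
     -0.318330369484338
    ],
    "sigmas": [
     1.2564989516117966
    ]
   },
   "r2_reference": 0.97,
   "notes": "elongated fraction stand-in"
  },
  {
   "name": "U251-Agar",
   "cell_line": "U251",
   "pressure": 0.0,
   "wound_closure_ctrl": 0.367,
   "wound_closure_exp": 0.4,
   "elongated_fraction": 0.38,
   "mixture": {
    "weights": [
     0.95,
     0.05
    ],
    "mus": [
     -0.3012150439666874,
     -0.3831624808119848
    ],
    "sigmas": [
     1.1889421281648824,
     0.05
    ]
   },
   "r2_reference": 0.97,
   "notes": "closure and elongated fraction stand-ins"
  },
  {
   "name": "U251-23Pa",
   "cell_line": "U251",
   "pressure": 23.0,
   "wound_closure_ctrl": 0.367,
   "wound_closure_exp": 0.545,
   "elongated_fraction": 0.42,
   "mixture": {
    "weights": [
     1.0
    ],
    "mus": [
     -0.22166500549572676
    ],
    "sigmas": [
     1.0979304851147995
    ]
   },
   "r2_reference": 0.97,
   "notes": "elongated fraction stand-in"
  },
  {
   "name": "U251-47Pa",
   "cell_line": "U251",
   "pressure": 47.0,
   "wound_closure_ctrl": 0.367,
   "wound_closure_exp": 0.43,
   "elongated_fraction": 0.392,
   "mixture": {
    "weights": [
     1.0
    ],
    "mus": [
     -0.348615616385916
    ],
    "sigmas": [
     1.2718086491241194
    ]
   },
   "r2_reference": 0.98,
   "notes": "closure and elongated fraction stand-ins"
  },
  {
   "name": "U251-115Pa",
   "cell_line": "U251",
   "pressure": 115.0,
   "wound_closure_ctrl": 0.367,
   "wound_closure_exp": 0.503,
   "elongated_fraction": 0.058,
   "mixture": {
    "weights": [
     0.95,
     0.05
    ],
    "mus": [
     -1.0761285761181996,
     -0.45953545959655884
    ],
    "sigmas": [
     0.6960741139752784,
     0.05
    ]
   },
   "r2_reference": 0.96,
   "notes": ""
  }
 ]
}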