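{
 "covariate_order": [
  "prec-4",
  "prec-5",
  "prec-10",
  "prec-11",
  "bio-14",
  "srad-10",
  "bio-5",
  "su_sym90",
  "awc_class",
  "elev"
 ],
 "models": [
  {
   "response": "lobetyolin",
   "response_id": "Y1",
   "intercept": 16.969,
   "coefficients": {
    "prec-4": -0.04,
    "prec-5": -0.001,
    "prec-10": -0.004,
    "prec-11": 0.022,
    "bio-14": 0.052,
    "srad-10": -0.122,
    "bio-5": 0.001,
    "su_sym90": 0.001,
    "awc_class": -0.037,
    "elev": 0.079
   }
  },
  {
   "response": "atractylenolide III",
   "response_id": "Y2",
   "intercept": 52.84,
   "coefficients": {
    "prec-4": 1.287,
    "prec-5": -0.007,
    "prec-10": 2.748,
    "prec-11": 1.785,
    "bio-14": -0.46,
    "srad-10": -1.695,
    "bio-5": 0.143,
    "su_sym90": 0.013,
    "awc_class": -2.351,
    "elev": 0.269
   }
  },
  {
   "response": "syringin",
   "response_id": "Y3",
   "intercept": 264.857,
   "coefficients": {
    "prec-4": -4.237,
    "prec-5": -0.026,
    "prec-10": 0.424,
    "prec-11": 1.91,
    "bio-14": 2.372,
    "srad-10": -0.712,
    "bio-5": 0.161,
    "su_sym90": 0.019,
    "awc_class": -1.113,
    "elev": -0.547
   }
  },
  {
   "response": "polysaccharides",
   "response_id": "Y4",
   "intercept": 172.485,
   "coefficients": {
    "prec-4": 0.169,
    "prec-5": -0.009,
    "prec-10": -1.378,
    "prec-11": -1.281,
    "bio-14": -0.136,
    "srad-10": -0.273,
    "bio-5": 0.03,
    "su_sym90": -0.006,
    "awc_class": -0.887,
    "elev": 0.444
   }
  },
  {
   "response": "oligosaccharides",
   "response_id": "Y5",
   "intercept": 25.193,
   "coefficients": {
    "prec-4": 0.148,
    "prec-5": 0.001,
    "prec-10": 0.684,
    "prec-11": -0.648,
    "bio-14": 0.436,
    "srad-10": -1.116,
    "bio-5": -0.033,
    "su_sym90": -0.001,
    "awc_class": 0.045,
    "elev": -0.297
   }
  },
  {
   "response": "alcohol extract",
   "response_id": "Y6",
   "intercept": -89.105,
   "coefficients": {
    "prec-4": 0.459,
    "prec-5": 0.013,
    "prec-10": 0.579,
    "prec-11": 0.489,
    "bio-14": 0.417,
    "srad-10": -1.017,
    "bio-5": -0.015,
    "su_sym90": -0.003,
    "awc_class": 0.507,
    "elev": 1.623
   }
  },
  {
   "response": "amino acid",
   "response_id": "Y7",
   "intercept": -157.827,
   "coefficients": {
    "prec-4": -1.546,
    "prec-5": 0.006,
    "prec-10": -0.239,
    "prec-11": 3.612,
    "bio-14": -2.817,
    "srad-10": 6.634,
    "bio-5": 0.121,
    "su_sym90": 0.029,
    "awc_class": 2.206,
    "elev": -3.624
   }
  },
  {
   "response": "protein",
   "response_id": "Y8",
   "intercept": -53.384,
   "coefficients": {
    "prec-4": -0.065,
    "prec-5": 0.003,
    "prec-10": -0.13,
    "prec-11": 0.633,
    "bio-14": -0.373,
    "srad-10": 0.984,
    "bio-5": -0.03,
    "su_sym90": 0.003,
    "awc_class": 0.532,
    "elev": -0.348
   }
  },
  {
   "response": "fat",
   "response_id": "Y9",
   "intercept": -2.803,
   "coefficients": {
    "prec-4": -0.013,
    "prec-5": -0.012,
    "prec-10": 0.064,
    "prec-11": 0.085,
    "bio-14": 0.015,
    "srad-10": -0.024,
    "bio-5": 0.001,
    "su_sym90": 0.001,
    "awc_class": -0.001,
    "elev": 0.002
   }
  },
  {
   "response": "dietary fiber",
   "response_id": "Y10",
   "intercept": 61.543,
   "coefficients": {
    "prec-4": -0.145,
    "prec-5": -0.007,
    "prec-10": 0.495,
    "prec-11": 1.445,
    "bio-14": -1.141,
    "srad-10": 1.778,
    "bio-5": -0.013,
    "su_sym90": 0.01,
    "awc_class": 0.724,
    "elev": -0.259
   }
  },
  {
   "response": "total nutrient elements",
   "response_id": "Y11",
   "intercept": 71.313,
   "coefficients": {
    "prec-4": 0.045,
    "prec-5": -0.007,
    "prec-10": -0.528,
    "prec-11": 0.689,
    "bio-14": 0.052,
    "srad-10": -0.286,
    "bio-5": 0.004,
    "su_sym90": 0.005,
    "awc_class": -0.73,
    "elev": 0.173
   }
  },
  {
   "response": "peak 1 area",
   "response_id": "Y12",
   "intercept": -136.384,
   "coefficients": {
    "prec-4": 2.682,
    "prec-5": 0.032,
    "prec-10": -0.351,
    "prec-11": -7.131,
    "bio-14": -1.305,
    "srad-10": 2.033,
    "bio-5": -0.162,
    "su_sym90": -0.062,
    "awc_class": 4.247,
    "elev": -0.098
   }
  },
  {
   "response": "peak 4 area",
   "response_id": "Y13",
   "intercept": -21.402,
   "coefficients": {
    "prec-4": 0.05,
    "prec-5": 0.003,
    "prec-10": 0.684,
    "prec-11": -0.432,
    "bio-14": 0.413,
    "srad-10": -0.586,
    "bio-5": -0.009,
    "su_sym90": -0.003,
    "awc_class": -0.626,
    "elev": -0.589
   }
  },
  {
   "response": "peak 5 area",
   "response_id": "Y14",
   "intercept": 103.915,
   "coefficients": {
    "prec-4": 0.936,
    "prec-5": 0.006,
    "prec-10": 0.493,
    "prec-11": -4.608,
    "bio-14": -0.667,
    "srad-10": -0.099,
    "bio-5": 0.027,
    "su_sym90": -0.021,
    "awc_class": 0.351,
    "elev": -0.498
   }
  },
  {
   "response": "peak 6 area",
   "response_id": "Y15",
   "intercept": 93.376,
   "coefficients": {
    "prec-4": -0.279,
    "prec-5": -0.015,
    "prec-10": -1.142,
    "prec-11": 2.395,
    "bio-14": -0.215,
    "srad-10": 0.32,
    "bio-5": -0.043,
    "su_sym90": 0.021,
    "awc_class": 1.11,
    "elev": -0.378
   }
  },
  {
   "response": "peak 9 area",
   "response_id": "Y16",
   "intercept": 84.261,
   "coefficients": {
    "prec-4": 1.283,
    "prec-5": 0.001,
    "prec-10": -1.098,
    "prec-11": -1.959,
    "bio-14": -2.461,
    "srad-10": 2.903,
    "bio-5": 0.06,
    "su_sym90": -0.005,
    "awc_class": 3.601,
    "elev": -1.513
   }
  },
  {
   "response": "peak 10 area",
   "response_id": "Y17",
   "intercept": 493.755,
   "coefficients": {
    "prec-4": -0.739,
    "prec-5": -0.007,
    "prec-10": -4.109,
    "prec-11": -10.749,
    "bio-14": -2.51,
    "srad-10": 4.08,
    "bio-5": 0.401,
    "su_sym90": -0.03,
    "awc_class": 2.683,
    "elev": 0.788
   }
  },
  {
   "response": "peak 11 area",
   "response_id": "Y18",
   "intercept": 49.649,
   "coefficients": {
    "prec-4": -0.633,
    "prec-5": 0.002,
    "prec-10": 0.847,
    "prec-11": -2.428,
    "bio-14": 0.053,
    "srad-10": 0.48,
    "bio-5": 0.027,
    "su_sym90": -0.008,
    "awc_class": 2.062,
    "elev": -0.108
   }
  },
  {
   "response": "peak 12 area",
   "response_id": "Y19",
   "intercept": 17.325,
   "coefficients": {
    "prec-4": -0.848,
    "prec-5": 0.008,
    "prec-10": 1.135,
    "prec-11": -3.02,
    "bio-14": -0.031,
    "srad-10": 0.937,
    "bio-5": -0.045,
    "su_sym90": -0.014,
    "awc_class": 1.016,
    "elev": 0.292
   }
  },
  {
   "response": "peak 14 area",
   "response_id": "Y20",
   "intercept": 337.317,
   "coefficients": {
    "prec-4": -2.314,
    "prec-5": 0.015,
    "prec-10": 2.725,
    "prec-11": -17.072,
    "bio-14": 6.403,
    "srad-10": -6.896,
    "bio-5": 0.036,
    "su_sym90": -0.076,
    "awc_class": -2.496,
    "elev": 3.776
   }
  },
  {
   "response": "peak 15 area",
   "response_id": "Y21",
   "intercept": 111.734,
   "coefficients": {
    "prec-4": -0.599,
    "prec-5": -0.005,
    "prec-10": -1.096,
    "prec-11": -1.376,
    "bio-14": 0.266,
    "srad-10": 0.175,
    "bio-5": 0.051,
    "su_sym90": -0.003,
    "awc_class": 0.208,
    "elev": 0.965
   }
  },
  {
   "response": "peak 19 area",
   "response_id": "Y22",
   "intercept": 51.287,
   "coefficients": {
    "prec-4": -0.246,
    "prec-5": -0.002,
    "prec-10": -0.276,
    "prec-11": -0.534,
    "bio-14": -0.05,
    "srad-10": 0.158,
    "bio-5": 0.009,
    "su_sym90": -0.001,
    "awc_class": 0.103,
    "elev": 0.293
   }
  }
 ]
}
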