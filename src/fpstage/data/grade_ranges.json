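{
  "schema_version": 1,
  "notes": {
    "source": "Calibration cohort of 40 UPFP patients (10 per House-Brackmann grade II-V); intervals taken from the published tables' Min/Max rows for partial and total shift differences (mm) and partial asymmetry indices.",
    "FOREHEAD_SD.II": "Printed lower bound 0.40 extended to 0.39 so the interval covers every cohort member (one patient's printed value is 0.39).",
    "TOTAL_AI": "Total-AI intervals are not printed; derived as per-patient means of the two partial indices over the same cohort.",
    "gap_handling": "Values between adjacent intervals are staged to the nearest boundary, ties to the more severe grade; see asymmetry.assign_grade."
  },
  "features": {
    "FOREHEAD_SD": {
      "kind": "sd",
      "unit": "mm",
      "grades": {
        "II": [0.39, 2.86],
        "III": [3.76, 4.46],
        "IV": [4.54, 5.81],
        "V": [6.33, 11.07]
      }
    },
    "MOUTH_SD": {
      "kind": "sd",
      "unit": "mm",
      "grades": {
        "II": [0.32, 2.72],
        "III": [3.0, 3.9],
        "IV": [3.99, 4.65],
        "V": [4.99, 6.24]
      }
    },
    "TOTAL_SD": {
      "kind": "sd",
      "unit": "mm",
      "grades": {
        "II": [1.03, 5.13],
        "III": [6.89, 8.13],
        "IV": [8.98, 10.35],
        "V": [11.49, 16.39]
      }
    },
    "FOREHEAD_AI": {
      "kind": "ai",
      "unit": "ratio",
      "grades": {
        "II": [0.74, 0.98],
        "III": [0.54, 0.68],
        "IV": [0.41, 0.52],
        "V": [0.03, 0.38]
      }
    },
    "MOUTH_AI": {
      "kind": "ai",
      "unit": "ratio",
      "grades": {
        "II": [0.73, 0.94],
        "III": [0.55, 0.69],
        "IV": [0.43, 0.51],
        "V": [0.1, 0.34]
      }
    },
    "TOTAL_AI": {
      "kind": "ai",
      "unit": "ratio",
      "grades": {
        "II": [0.755, 0.93],
        "III": [0.565, 0.665],
        "IV": [0.44, 0.51],
        "V": [0.085, 0.36]
      }
    }
  }
}
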