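{
  "schema_version": 1,
  "description": "Published per-patient staging values of the 40-subject UPFP calibration cohort (10 subjects per House-Brackmann grade II-V): partial shift differences (mm) for forehead frowning and smiling, their totals, and partial asymmetry indices for the frontal and mouth regions. Values are as printed (2 decimals except where noted). printed_summaries holds the tables' own Mean/Max/Min/St.dev. rows, which contain a handful of last-digit inconsistencies with the per-patient columns; see reference.audit_printed_summaries.",
  "grades": ["II", "III", "IV", "V"],
  "n_per_grade": 10,
  "values": {
    "FOREHEAD_SD": {
      "II": [0.87, 0.61, 2.81, 1.66, 0.39, 2.53, 1.58, 2.86, 1.89, 1.26],
      "III": [3.89, 4.24, 4.0, 3.8, 3.75, 3.95, 3.87, 4.23, 4.12, 4.45],
      "IV": [5.56, 5.0, 5.23, 4.54, 5.26, 4.82, 5.01, 4.96, 5.78, 5.8],
      "V": [6.93, 11.07, 6.5, 6.32, 6.65, 7.6, 10.23, 8.65, 9.48, 8.32]
    },
    "MOUTH_SD": {
      "II": [0.93, 2.72, 2.33, 1.65, 0.64, 0.98, 1.33, 0.32, 0.82, 1.73],
      "III": [3.0, 3.13, 3.65, 3.11, 3.31, 3.13, 3.57, 3.9, 3.69, 3.26],
      "IV": [4.56, 3.99, 4.24, 4.65, 3.99, 4.32, 4.04, 4.02, 4.56, 4.11],
      "V": [6.0, 5.33, 5.0, 5.24, 6.13, 5.13, 4.99, 5.55, 5.99, 6.24]
    },
    "TOTAL_SD": {
      "II": [1.8, 3.3, 5.13, 3.31, 1.03, 3.51, 2.91, 3.18, 2.71, 2.98],
      "III": [6.89, 7.36, 7.65, 6.91, 7.06, 7.08, 7.44, 8.13, 7.81, 7.71],
      "IV": [10.12, 8.98, 9.47, 9.19, 9.25, 9.14, 9.05, 8.98, 10.35, 9.91],
      "V": [12.92, 16.39, 11.49, 11.56, 12.78, 12.73, 15.22, 14.2, 15.47, 14.56]
    },
    "FOREHEAD_AI": {
      "II": [0.8, 0.85, 0.98, 0.98, 0.78, 0.92, 0.78, 0.74, 0.76, 0.93],
      "III": [0.55, 0.68, 0.63, 0.65, 0.59, 0.68, 0.54, 0.58, 0.58, 0.64],
      "IV": [0.52, 0.5, 0.5, 0.43, 0.47, 0.41, 0.47, 0.44, 0.48, 0.45],
      "V": [0.03, 0.26, 0.16, 0.12, 0.29, 0.18, 0.38, 0.33, 0.32, 0.17]
    },
    "MOUTH_AI": {
      "II": [0.84, 0.8, 0.77, 0.76, 0.73, 0.94, 0.91, 0.78, 0.84, 0.91],
      "III": [0.64, 0.61, 0.6, 0.61, 0.65, 0.65, 0.69, 0.55, 0.55, 0.68],
      "IV": [0.5, 0.48, 0.48, 0.45, 0.5, 0.51, 0.51, 0.5, 0.43, 0.45],
      "V": [0.14, 0.22, 0.25, 0.14, 0.28, 0.28, 0.34, 0.33, 0.1, 0.33]
    }
  },
  "printed_decimals_exceptions": {
    "FOREHEAD_SD.III.3": 1,
    "FOREHEAD_SD.V.2": 1,
    "TOTAL_SD.II.1": 1
  },
  "printed_summaries": {
    "FOREHEAD_SD": {
      "mean": {"II": 1.65, "III": 4.03, "IV": 5.2, "V": 8.18},
      "max": {"II": 2.86, "III": 4.46, "IV": 5.81, "V": 11.07},
      "min": {"II": 0.4, "III": 3.76, "IV": 4.54, "V": 6.33},
      "sd": {"II": 0.89, "III": 0.23, "IV": 0.42, "V": 1.67}
    },
    "MOUTH_SD": {
      "mean": {"II": 1.34, "III": 3.37, "IV": 4.25, "V": 5.56},
      "max": {"II": 2.72, "III": 3.9, "IV": 4.65, "V": 6.24},
      "min": {"II": 0.32, "III": 3.0, "IV": 3.99, "V": 4.99},
      "sd": {"II": 0.76, "III": 0.3, "IV": 0.26, "V": 0.48}
    },
    "TOTAL_SD": {
      "mean": {"II": 2.99, "III": 7.4, "IV": 9.44, "V": 13.73},
      "max": {"II": 5.13, "III": 8.13, "IV": 10.35, "V": 16.39},
      "min": {"II": 1.03, "III": 6.89, "IV": 8.98, "V": 11.49},
      "sd": {"II": 1.07, "III": 0.41, "IV": 0.5, "V": 1.68}
    },
    "FOREHEAD_AI": {
      "mean": {"II": 0.85, "III": 0.61, "IV": 0.46, "V": 0.22},
      "max": {"II": 0.98, "III": 0.68, "IV": 0.52, "V": 0.38},
      "min": {"II": 0.74, "III": 0.54, "IV": 0.41, "V": 0.03},
      "sd": {"II": 0.09, "III": 0.05, "IV": 0.03, "V": 0.1}
    },
    "MOUTH_AI": {
      "mean": {"II": 0.82, "III": 0.62, "IV": 0.48, "V": 0.24},
      "max": {"II": 0.94, "III": 0.69, "IV": 0.51, "V": 0.34},
      "min": {"II": 0.73, "III": 0.55, "IV": 0.43, "V": 0.1},
      "sd": {"II": 0.07, "III": 0.04, "IV": 0.02, "V": 0.08}
    }
  },
  "published_anova": {
    "FOREHEAD_SD": {"F": 78.02, "R2": 0.9},
    "MOUTH_SD": {"F": 107.7, "R2": 0.92},
    "TOTAL_SD": {"F": 183.0, "R2": 0.95},
    "FOREHEAD_AI": {"F": 96.68, "R2": 0.91},
    "MOUTH_AI": {"F": 220.0, "R2": 0.96},
    "TOTAL_AI": {"F": 207.5, "R2": 0.96}
  }
}
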