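{
  "provenance": "published_fixture",
  "version": "v1",
  "description": "Published adjustment equations and Equivalent-Score thresholds for the telephone language screener. Base measures normed on N=480; backward digit span on N=401; advanced connected-speech measures on N=219 (centering constants stored per measure as printed).",
  "measures": {
    "total": {
      "terms": [
        {"transform": "age3", "coefficient": 9e-06, "center": 191433.997917},
        {"transform": "inv_education", "coefficient": 50.82466, "center": 0.088235}
      ],
      "thresholds": {"oTL": 52.64, "iTL": 54.9, "es1_upper": 56.41, "es2_upper": 58.79, "es3_upper": 61.5, "es4_lower": 61.51}
    },
    "informative_units": {
      "terms": [],
      "thresholds": {"oTL": 3, "iTL": 6, "es1_upper": 7, "es2_upper": 8, "es3_upper": 10, "es4_lower": 11}
    },
    "spelling": {
      "terms": [
        {"transform": "age3", "coefficient": 1e-06, "center": 191433.997917},
        {"transform": "inv_education", "coefficient": 16.71391, "center": 0.088235}
      ],
      "thresholds": {"oTL": 5.86, "iTL": 6.88, "es1_upper": 7.41, "es2_upper": 8.41, "es3_upper": 9.28, "es4_lower": 9.29}
    },
    "semantic_association": {
      "terms": [
        {"transform": "inv_education", "coefficient": 2.153293, "center": 0.088235}
      ],
      "thresholds": {"oTL": 4.94, "iTL": 5.12, "es1_upper": 5.9, "es2_upper": 5.94, "es3_upper": 5.99, "es4_lower": 6}
    },
    "naming_nouns": {
      "terms": [
        {"transform": "age3", "coefficient": 1e-06, "center": 191433.997917},
        {"transform": "inv_education", "coefficient": 5.834264, "center": 0.088235}
      ],
      "thresholds": {"oTL": 3.67, "iTL": 4.13, "es1_upper": 4.64, "es2_upper": 4.97, "es3_upper": 5.72, "es4_lower": 5.73}
    },
    "naming_verbs": {
      "terms": [
        {"transform": "log_100_minus_age", "coefficient": -0.206562, "center": 3.787995},
        {"transform": "inv_education", "coefficient": 5.803237, "center": 0.088235}
      ],
      "thresholds": {"oTL": 3.7, "iTL": 4, "es1_upper": 4.7, "es2_upper": 5.2, "es3_upper": 5.81, "es4_lower": 5.82}
    },
    "cml": {
      "terms": [
        {"transform": "age3", "coefficient": 3e-06, "center": 191433.997917},
        {"transform": "inv_education", "coefficient": 17.26772, "center": 0.088235}
      ],
      "thresholds": {"oTL": 10.52, "iTL": 12.14, "es1_upper": 12.73, "es2_upper": 13.91, "es3_upper": 14.32, "es4_lower": 14.33}
    },
    "repetition_words": {
      "terms": [],
      "thresholds": {"oTL": 4, "iTL": 6, "es1_upper": null, "es2_upper": null, "es3_upper": null, "es4_lower": 6}
    },
    "repetition_nonwords": {
      "terms": [
        {"transform": "age3", "coefficient": 2e-06, "center": 191433.997917}
      ],
      "thresholds": {"oTL": 2.5, "iTL": 2.78, "es1_upper": 3.01, "es2_upper": 3.77, "es3_upper": 4.64, "es4_lower": 4.65}
    },
    "repetition_sentences": {
      "terms": [
        {"transform": "age3", "coefficient": 5e-07, "center": 191433.997917},
        {"transform": "inv_education", "coefficient": 2.697296, "center": 0.088235}
      ],
      "thresholds": {"oTL": 1.41, "iTL": 1.89, "es1_upper": 1.96, "es2_upper": 2.82, "es3_upper": 2.9, "es4_lower": 2.91}
    },
    "bds_total": {
      "terms": [
        {"transform": "age3", "coefficient": 2e-06, "center": 193861.925187},
        {"transform": "inv_education", "coefficient": 16.46647, "center": 0.088601}
      ],
      "thresholds": {"oTL": 1.2, "iTL": 1.92, "es1_upper": 2.5, "es2_upper": 3.53, "es3_upper": 4.78, "es4_lower": 4.79}
    },
    "bds_wm": {
      "terms": [
        {"transform": "age3", "coefficient": 1e-06, "center": 193861.925187},
        {"transform": "inv_education", "coefficient": 10.25621, "center": 0.088601}
      ],
      "thresholds": {"oTL": 1.58, "iTL": 2.9, "es1_upper": 3.49, "es2_upper": 4.0, "es3_upper": 4.81, "es4_lower": 4.82}
    },
    "cs_words": {
      "terms": [
        {"transform": "sqrt_education", "coefficient": -12.54032, "center": 3.575916}
      ],
      "thresholds": {"oTL": 51.14, "iTL": 57.63, "es1_upper": 58.68, "es2_upper": 72.37, "es3_upper": 88.8, "es4_lower": 88.81}
    },
    "cs_sentences": {
      "terms": [
        {"transform": "log_100_minus_age", "coefficient": -2.644981, "center": 3.786775},
        {"transform": "log10_education", "coefficient": -5.560185, "center": 1.095679}
      ],
      "thresholds": {"oTL": 9.78, "iTL": 12.44, "es1_upper": 13.02, "es2_upper": 14.97, "es3_upper": 17.09, "es4_lower": 17.1}
    },
    "cs_nouns_ratio": {
      "terms": [
        {"transform": "age2", "coefficient": 7e-06, "center": 3032.251142}
      ],
      "thresholds": {"oTL": 0.138, "iTL": 0.16, "es1_upper": 0.164, "es2_upper": 0.196, "es3_upper": 0.227, "es4_lower": 0.228}
    },
    "cs_verbs_ratio": {
      "terms": [
        {"transform": "age3", "coefficient": 4.336e-08, "center": 188419.666667}
      ],
      "thresholds": {"oTL": 0.151, "iTL": 0.173, "es1_upper": 0.183, "es2_upper": 0.208, "es3_upper": 0.235, "es4_lower": 0.236}
    },
    "cs_function_ratio": {
      "terms": [],
      "thresholds": {"oTL": 0.306, "iTL": 0.338, "es1_upper": 0.347, "es2_upper": 0.377, "es3_upper": 0.404, "es4_lower": 0.405}
    }
  }
}
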