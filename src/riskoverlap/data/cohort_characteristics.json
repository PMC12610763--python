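{
  "version": "1.0",
  "provenance": "Published characteristics of the 180,398-woman consortium case-control cohort (161,849 European-ancestry; 18,549 Asian-ancestry): per-cell sample sizes, median age (IQR), Gail covariate category counts including 'unknown', and median raw polygenic sum score (IQR). These counts define the default synthetic-cohort generator configuration; the raw consortium data are not deposited.",
  "age_range": [30, 80],
  "cells": {
    "European": {
      "control": {
        "n": 68540,
        "age_median_iqr": [57, 50, 64],
        "prs_median_iqr": [-0.45, -0.86, -0.04],
        "age_menarche": {"lt12": 9825, "12to13": 30243, "ge14": 21133, "unknown": 7339},
        "age_first_birth": {"nulliparous": 8319, "lt20": 5427, "20to24": 21863, "25to29": 17543, "ge30": 8487, "unknown": 6901},
        "n_relatives": {"0": 45629, "1": 5348, "ge2": 791, "unknown": 16772},
        "n_biopsies": {"0": 930, "1": 277, "ge2": 103, "unknown": 67230},
        "atypical_hyperplasia": {"no": 930, "yes": 5, "unknown": 67605}
      },
      "invasive": {
        "n": 83685,
        "age_median_iqr": [57, 49, 65],
        "prs_median_iqr": [-0.09, -0.51, 0.32],
        "age_menarche": {"lt12": 10859, "12to13": 33476, "ge14": 23169, "unknown": 16181},
        "age_first_birth": {"nulliparous": 10769, "lt20": 6138, "20to24": 21927, "25to29": 18174, "ge30": 9973, "unknown": 16704},
        "n_relatives": {"0": 48903, "1": 10256, "ge2": 2064, "unknown": 22462},
        "n_biopsies": {"0": 3181, "1": 3148, "ge2": 1822, "unknown": 75534},
        "atypical_hyperplasia": {"no": 3181, "yes": 49, "unknown": 80455}
      },
      "DCIS": {
        "n": 9624,
        "age_median_iqr": [55, 50, 63],
        "prs_median_iqr": [-0.15, -0.55, 0.27],
        "age_menarche": {"lt12": 1733, "12to13": 4546, "ge14": 2758, "unknown": 587},
        "age_first_birth": {"nulliparous": 1520, "lt20": 794, "20to24": 2899, "25to29": 2382, "ge30": 1386, "unknown": 643},
        "n_relatives": {"0": 4005, "1": 1115, "ge2": 305, "unknown": 4199},
        "n_biopsies": {"0": 96, "1": 216, "ge2": 148, "unknown": 9164},
        "atypical_hyperplasia": {"no": 96, "yes": 8, "unknown": 9520}
      }
    },
    "Asian": {
      "control": {
        "n": 8347,
        "age_median_iqr": [50, 44, 58],
        "prs_median_iqr": [0.16, -0.20, 0.53],
        "age_menarche": {"lt12": 508, "12to13": 3080, "ge14": 4321, "unknown": 438},
        "age_first_birth": {"nulliparous": 1005, "lt20": 316, "20to24": 1948, "25to29": 2836, "ge30": 1149, "unknown": 1093},
        "n_relatives": {"0": 7181, "1": 437, "ge2": 63, "unknown": 666},
        "n_biopsies": {"0": 0, "1": 0, "ge2": 0, "unknown": 8347},
        "atypical_hyperplasia": {"no": 0, "yes": 0, "unknown": 8347}
      },
      "invasive": {
        "n": 9222,
        "age_median_iqr": [49, 43, 57],
        "prs_median_iqr": [0.37, -0.01, 0.76],
        "age_menarche": {"lt12": 586, "12to13": 3278, "ge14": 4186, "unknown": 1172},
        "age_first_birth": {"nulliparous": 1236, "lt20": 362, "20to24": 1810, "25to29": 3030, "ge30": 1554, "unknown": 1230},
        "n_relatives": {"0": 7500, "1": 876, "ge2": 93, "unknown": 753},
        "n_biopsies": {"0": 0, "1": 0, "ge2": 0, "unknown": 9222},
        "atypical_hyperplasia": {"no": 0, "yes": 0, "unknown": 9222}
      },
      "DCIS": {
        "n": 980,
        "age_median_iqr": [49, 43, 56],
        "prs_median_iqr": [0.45, 0.05, 0.83],
        "age_menarche": {"lt12": 61, "12to13": 326, "ge14": 467, "unknown": 126},
        "age_first_birth": {"nulliparous": 158, "lt20": 29, "20to24": 135, "25to29": 293, "ge30": 156, "unknown": 209},
        "n_relatives": {"0": 708, "1": 114, "ge2": 13, "unknown": 145},
        "n_biopsies": {"0": 0, "1": 0, "ge2": 0, "unknown": 980},
        "atypical_hyperplasia": {"no": 0, "yes": 0, "unknown": 980}
      }
    }
  }
}
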