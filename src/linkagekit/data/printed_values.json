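{
  "comment": "Statistics and recombination frequencies as published, for recomputed-vs-printed annotation in reports. Rows whose printed statistic is not reproducible from the printed counts are flagged by the report, not corrected.",
  "crosses": {
    "t2-01": {"chi2": 0.412, "p": 0.521},
    "t2-02": {"chi2": 1.242, "p": 0.265},
    "t2-03": {"chi2": 0.833, "p": 0.361},
    "t2-04": {"chi2": 0.149, "p": 0.685},
    "t2-05": {"chi2": 0.184, "p": 0.668},
    "t2-06": {"chi2": 0.310, "p": 0.577},
    "t2-07": {"chi2": 1.910, "p": 0.167},
    "t2-08": {"chi2": 1.857, "p": 0.173},
    "t2-17": {"chi2": 0.559, "p": 0.455},
    "t2-18": {"chi2": 0.970, "p": 0.325},
    "t2-19": {"chi2": 0.259, "p": 0.611},
    "t3-02": {"chi2": 3.263, "p": 0.353},
    "t3-03": {"chi2": 2.176, "p": 0.537},
    "t3-18": {"chi2": 3.212, "p": 0.360},
    "t4-02": {"chi2": 47.618, "rf": 9.02},
    "t4-03": {"chi2": 65.903, "rf": 5.76},
    "t4-04": {"chi2": 527.171, "rf": 3.45},
    "t4-05": {"chi2": 548.958, "rf": 4.40},
    "t4-15": {"chi2": 82.582, "rf": 3.30},
    "t4-16": {"chi2": 153.286, "rf": 6.28},
    "t5-02": {"chi2": 55.003, "rf": 6.02},
    "t5-03": {"chi2": 83.906, "rf": 10.37},
    "t5-04": {"chi2": 530.855, "rf": 3.29},
    "t5-05": {"chi2": 563.416, "rf": 3.79},
    "t5-17": {"chi2": 115.685, "rf": 5.51},
    "t6-02": {"chi2": 69.832, "rf": 15.79},
    "t6-03": {"chi2": 73.681, "rf": 14.47},
    "t6-04": {"chi2": 372.882, "rf": 10.86},
    "t6-05": {"chi2": 318.924, "rf": 15.48}
  },
  "averages": {
    "S-LEM": {"mean": 5.37, "sd": 2.15},
    "V-LEM": {"mean": 5.80, "sd": 2.80},
    "RLF-LEM": {"mean": 14.15, "sd": 2.26}
  },
  "intervals": {
    "RLF-S": 10.58,
    "S-V": 0.47,
    "V-LEM": 3.79,
    "RLF-LEM": 14.84
  }
}
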