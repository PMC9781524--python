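{
  "description": "Curated high-reproducibility feature list (two-segmentation ICC >= 0.8): 74 of the 107 features, with family counts 3/18/19/9/10/11/4.",
  "threshold": 0.8,
  "selected": {
    "shape": [
      "Elongation",
      "Mesh Volume",
      "Voxel Volume"
    ],
    "firstorder": [
      "10th Percentile",
      "90th Percentile",
      "Energy",
      "Entropy",
      "Interquartile Range",
      "Kurtosis",
      "Maximum",
      "Mean Absolute Deviation",
      "Mean",
      "Median",
      "Minimum",
      "Range",
      "Robust Mean Absolute Deviation",
      "Root Mean Squared",
      "Skewness",
      "Total Energy",
      "Uniformity",
      "Variance"
    ],
    "glcm": [
      "Autocorrelation",
      "Cluster Prominence",
      "Cluster Shade",
      "Cluster Tendency",
      "Contrast",
      "Correlation",
      "Difference Average",
      "Difference Entropy",
      "Difference Variance",
      "Imc1",
      "Imc2",
      "Inverse Variance",
      "Joint Average",
      "Joint Energy",
      "Joint Entropy",
      "Maximum Probability",
      "Sum Average",
      "Sum Entropy",
      "Sum Squares"
    ],
    "gldm": [
      "Dependence Entropy",
      "Dependence Non-Uniformity",
      "Dependence Variance",
      "Gray Level Variance",
      "High Gray Level Emphasis",
      "Large Dependence Emphasis",
      "Large Dependence Low Gray Level Emphasis",
      "Small Dependence Emphasis",
      "Small Dependence High Gray Level Emphasis"
    ],
    "glrlm": [
      "Gray Level Non-Uniformity Normalized",
      "Gray Level Variance",
      "High Gray Level Run Emphasis",
      "Long Run Emphasis",
      "Long Run High Gray Level Emphasis",
      "Long Run Low Gray Level Emphasis",
      "Run Entropy",
      "Run Length Non-Uniformity",
      "Run Variance",
      "Short Run High Gray Level Emphasis"
    ],
    "glszm": [
      "Gray Level Non-Uniformity",
      "Gray Level Non-Uniformity Normalized",
      "Gray Level Variance",
      "High Gray Level Zone Emphasis",
      "Large Area Low Gray Level Emphasis",
      "Size Zone Non-Uniformity",
      "Size Zone Non-Uniformity Normalized",
      "Small Area Emphasis",
      "Small Area High Gray Level Emphasis",
      "Zone Entropy",
      "Zone Percentage"
    ],
    "ngtdm": [
      "Busyness",
      "Complexity",
      "Contrast",
      "Strength"
    ]
  }
}
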