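{
  "feature_sets": ["X", "A", "R", "G", "XA", "XR", "XG", "AR", "AG", "RG", "XAR", "XAG", "XRG", "ARG", "XARG"],
  "mars": {
    "degree":  [2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "penalty": [2, 6, 5, 6, 7, 2, 6, 7, 6, 5, 6, 7, 6, 5, 6]
  },
  "knn": {
    "k": [15, 13, 14, 16, 9, 19, 17, 19, 18, 17, 18, 19, 17, 18, 19],
    "q": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
  },
  "svm": {
    "C":       [2, 2, 1, 1, 1, 4, 1, 2, 2, 1, 1, 2, 2, 1, 2],
    "epsilon": [0.5, 0.0, 0.25, 0.25, 0.125, 0.125, 0.25, 0.25, 0.25, 0.125, 0.25, 0.125, 0.125, 0.125, 0.25],
    "sigma":   [1.0, 0.25, 0.125, 0.25, 0.25, 0.031, 0.031, 0.031, 0.125, 0.031, 0.125, 0.031, 0.031, 0.031, 0.031]
  },
  "rf": {
    "mtry": [3, 18, 8, 7, 31, 5, 8, 10, 16, 17, 14, 20, 21, 25, 35]
  },
  "brt": {
    "interaction_depth": [15, 17, 18, 16, 19, 15, 18, 19, 17, 16, 16, 20, 18, 17, 20],
    "n_trees":           [1114, 1523, 1573, 1208, 1371, 2113, 1610, 2950, 2181, 2303, 2213, 2590, 2854, 2921, 2859]
  }
}
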