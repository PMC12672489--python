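{
  "description": "Printed six-component loading matrix, eigenvalues, norm values, communalities and group labels for the 20-indicator total data set, plus the in-text pairwise correlation statements used for minimum-data-set pruning.",
  "components": ["PC1", "PC2", "PC3", "PC4", "PC5", "PC6"],
  "eigenvalues": [6.366, 2.196, 1.948, 1.759, 1.368, 1.101],
  "contribution_rate": [31.828, 10.980, 9.739, 8.795, 6.839, 5.504],
  "cumulative_rate": [31.828, 42.808, 52.547, 61.341, 68.181, 73.684],
  "indicators": [
    {"name": "SM",  "loadings": [0.598, -0.374, 0.012, -0.017, -0.267, -0.083], "norm": 1.640, "communality": 0.575, "group": 1},
    {"name": "BD",  "loadings": [-0.552, 0.229, 0.125, 0.250, 0.214, 0.021],    "norm": 1.503, "communality": 0.481, "group": 1},
    {"name": "TN",  "loadings": [0.849, 0.222, 0.157, -0.029, 0.051, -0.142],   "norm": 2.185, "communality": 0.819, "group": 1},
    {"name": "TP",  "loadings": [0.042, -0.102, 0.004, 0.269, 0.545, 0.628],    "norm": 1.001, "communality": 0.776, "group": 6},
    {"name": "SOC", "loadings": [0.853, 0.205, 0.201, -0.115, -0.026, -0.126],  "norm": 2.201, "communality": 0.839, "group": 1},
    {"name": "MBC", "loadings": [0.845, 0.117, -0.171, 0.094, 0.154, 0.045],    "norm": 2.164, "communality": 0.791, "group": 1},
    {"name": "NH4", "loadings": [0.484, -0.178, -0.685, 0.093, 0.036, -0.010],  "norm": 1.579, "communality": 0.745, "group": 3},
    {"name": "NO3", "loadings": [0.162, 0.608, -0.347, -0.248, 0.363, 0.135],   "norm": 1.234, "communality": 0.728, "group": 2},
    {"name": "MBN", "loadings": [0.850, 0.102, -0.102, 0.177, 0.025, 0.007],    "norm": 2.168, "communality": 0.775, "group": 1},
    {"name": "MBP", "loadings": [0.733, 0.222, -0.166, -0.197, 0.295, 0.025],   "norm": 1.942, "communality": 0.741, "group": 1},
    {"name": "AP",  "loadings": [0.547, -0.344, -0.163, -0.428, 0.004, 0.344],  "norm": 1.634, "communality": 0.745, "group": 1},
    {"name": "POD", "loadings": [0.375, -0.245, 0.385, -0.617, -0.122, 0.112],  "norm": 1.421, "communality": 0.757, "group": 4},
    {"name": "LAP", "loadings": [0.572, 0.228, 0.165, 0.461, -0.182, 0.057],    "norm": 1.635, "communality": 0.655, "group": 1},
    {"name": "BX",  "loadings": [0.176, -0.173, -0.483, 0.672, -0.321, 0.026],  "norm": 1.286, "communality": 0.850, "group": 4},
    {"name": "ALP", "loadings": [0.895, -0.007, 0.009, 0.079, -0.053, -0.122],  "norm": 2.265, "communality": 0.825, "group": 1},
    {"name": "URE", "loadings": [0.578, -0.363, 0.459, 0.164, 0.145, -0.128],   "norm": 1.709, "communality": 0.740, "group": 1},
    {"name": "CBH", "loadings": [0.142, -0.653, 0.112, 0.104, -0.136, 0.444],   "norm": 1.162, "communality": 0.686, "group": 2},
    {"name": "NAG", "loadings": [0.037, -0.349, 0.485, 0.362, 0.556, -0.184],   "norm": 1.194, "communality": 0.833, "group": 5},
    {"name": "ACP", "loadings": [0.255, 0.473, 0.465, 0.225, -0.134, 0.127],    "norm": 1.207, "communality": 0.590, "group": 2},
    {"name": "BG",  "loadings": [0.023, 0.514, 0.317, 0.072, -0.430, 0.479],    "norm": 1.138, "communality": 0.784, "group": 2}
  ],
  "correlation_facts": [
    {"pair": ["ALP", "SOC"], "r": 0.40,  "significant": true,  "source": "stated"},
    {"pair": ["ALP", "TN"],  "r": 0.37,  "significant": true,  "source": "stated"},
    {"pair": ["ALP", "MBC"], "r": 0.59,  "significant": true,  "source": "stated"},
    {"pair": ["ALP", "MBN"], "r": 0.62,  "significant": true,  "source": "stated"},
    {"pair": ["NO3", "CBH"], "r": -0.38, "significant": true,  "source": "stated"},
    {"pair": ["NO3", "ACP"], "r": null,  "significant": false, "source": "implied"},
    {"pair": ["NO3", "BG"],  "r": null,  "significant": false, "source": "implied"},
    {"pair": ["ACP", "BG"],  "r": null,  "significant": false, "source": "implied"},
    {"pair": ["POD", "BX"],  "r": null,  "significant": false, "source": "stated"}
  ]
}
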