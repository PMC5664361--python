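{
  "enrichment": {
    "class:C1": {
      "enrichment": 9.0,
      "f_all": 0.05555555555555555,
      "f_pw": 0.5,
      "n_f": 4
    },
    "class:C2": {
      "enrichment": null,
      "f_all": 0.0,
      "f_pw": 0.0,
      "n_f": 5
    },
    "class:C3": {
      "enrichment": 4.0,
      "f_all": 0.03571428571428571,
      "f_pw": 0.14285714285714285,
      "n_f": 7
    },
    "map:M001": {
      "enrichment": 14.0,
      "f_all": 0.07142857142857142,
      "f_pw": 1.0,
      "n_f": 3
    },
    "map:M002": {
      "enrichment": null,
      "f_all": 0.0,
      "f_pw": null,
      "n_f": 1
    },
    "map:M003": {
      "enrichment": null,
      "f_all": 0.0,
      "f_pw": null,
      "n_f": 1
    },
    "map:M004": {
      "enrichment": null,
      "f_all": 0.0,
      "f_pw": 0.0,
      "n_f": 4
    },
    "map:M005": {
      "enrichment": 6.499999999999999,
      "f_all": 0.046153846153846156,
      "f_pw": 0.3,
      "n_f": 5
    },
    "map:M006": {
      "enrichment": null,
      "f_all": 0.0,
      "f_pw": 0.0,
      "n_f": 2
    }
  },
  "n_families": 12,
  "n_objects": 16,
  "n_singletons": 4,
  "n_unique_profiles": 12,
  "partition": {
    "F0001_SP01_1": 0,
    "F0001_SP01_2": 0,
    "F0001_SP04_1": 0,
    "F0001_SP06_1": 0,
    "F0002_SP04_1": 1,
    "F0002_SP04_2": 1,
    "F0002_SP06_1": 1,
    "F0003_SP02_1": 2,
    "F0003_SP02_2": 2,
    "F0003_SP04_1": 2,
    "F0003_SP05_1": 2,
    "F0004_SP01_1": 3,
    "F0004_SP02_1": 3,
    "F0004_SP04_1": 3,
    "F0004_SP04_2": 3,
    "F0004_SP05_1": 3,
    "F0005_SP01_1": 4,
    "F0005_SP01_2": 4,
    "F0005_SP02_1": 4,
    "F0005_SP04_1": 4,
    "F0005_SP04_2": 4,
    "F0005_SP05_1": 4,
    "F0006_SP01_1": 5,
    "F0006_SP01_2": 5,
    "F0006_SP03_1": 5,
    "F0006_SP05_1": 5,
    "F0006_SP06_1": 5,
    "F0007_SP01_1": 6,
    "F0007_SP01_2": 6,
    "F0007_SP01_3": 6,
    "F0007_SP02_1": 6,
    "F0007_SP03_1": 6,
    "F0007_SP04_1": 6,
    "F0007_SP06_1": 6,
    "F0008_SP01_1": 7,
    "F0008_SP02_1": 7,
    "F0008_SP06_1": 7,
    "F0009_SP01_1": 8,
    "F0009_SP02_1": 8,
    "F0009_SP03_1": 8,
    "F0009_SP03_2": 8,
    "F0009_SP05_1": 8,
    "F0009_SP05_2": 8,
    "F0010_SP01_1": 9,
    "F0010_SP04_1": 9,
    "F0010_SP04_2": 9,
    "F0010_SP06_1": 9,
    "F0010_SP06_2": 9,
    "F0011_SP01_1": 10,
    "F0011_SP04_1": 10,
    "F0011_SP04_2": 10,
    "F0011_SP06_1": 10,
    "F0012_SP01_1": 11,
    "F0012_SP02_1": 11,
    "F0012_SP02_2": 11,
    "F0012_SP04_1": 11,
    "F0012_SP05_1": 11,
    "S0001_SP04_1": 12,
    "S0002_SP01_1": 13,
    "S0003_SP03_1": 14,
    "S0004_SP06_1": 15
  },
  "profiles": {
    "0": "100101",
    "1": "000101",
    "10": "100101",
    "11": "110110",
    "12": "000100",
    "13": "100000",
    "14": "001000",
    "15": "000001",
    "2": "010110",
    "3": "110110",
    "4": "110110",
    "5": "101011",
    "6": "111101",
    "7": "110001",
    "8": "111010",
    "9": "100101"
  }
}
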