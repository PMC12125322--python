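{
  "description": "Published covariate-by-subtype contingency counts for a 538-patient surgical colorectal cancer cohort (481 classified). Rows: covariate levels; columns: CMS-resembling subtypes. Per-covariate totals differ where covariate values were missing.",
  "subtypes": ["CMS1-like", "CMS2-like", "CMS3-like", "CMS4-like"],
  "printed_p": {
    "age_group": 0.027,
    "sex": 0.61,
    "stage": 0.47,
    "pT": 0.249,
    "pN": 0.064,
    "pM": 0.50,
    "grade": 0.056,
    "location": 0.001,
    "histology": 0.001
  },
  "variables": {
    "age_group": {
      "levels": ["<69", ">=69"],
      "counts": [[38, 93, 74, 28], [38, 75, 111, 24]]
    },
    "sex": {
      "levels": ["female", "male"],
      "counts": [[41, 78, 83, 24], [35, 90, 102, 28]]
    },
    "stage": {
      "levels": ["I", "II", "III", "IV"],
      "counts": [[9, 37, 37, 7], [25, 53, 52, 13], [27, 56, 63, 23], [15, 21, 33, 9]]
    },
    "pT": {
      "levels": ["1", "2", "3", "4"],
      "counts": [[0, 10, 8, 2], [11, 35, 43, 8], [52, 110, 112, 35], [10, 11, 19, 7]]
    },
    "pN": {
      "levels": ["0", "1", "2"],
      "counts": [[37, 93, 95, 22], [23, 47, 53, 11], [14, 26, 33, 19]]
    },
    "pM": {
      "levels": ["0", "1"],
      "counts": [[61, 146, 152, 43], [15, 21, 30, 9]]
    },
    "grade": {
      "levels": ["low", "high"],
      "counts": [[57, 147, 158, 43], [15, 15, 18, 8]]
    },
    "location": {
      "levels": ["right colon", "left colon", "rectum"],
      "counts": [[46, 29, 54, 12], [10, 53, 45, 7], [20, 86, 86, 33]]
    },
    "histology": {
      "levels": ["non-mucinous", "mucinous"],
      "counts": [[59, 144, 148, 44], [11, 2, 12, 5]]
    }
  }
}
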