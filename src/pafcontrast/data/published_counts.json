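{
  "description": "Published summary counts from the motivating candidate-gene array study: literature-comparison bin tallies (totals and differing SNPs per study-frequency range) and the functional-group differing-SNP tallies, with the rounded empirical base rate the group probabilities were computed under.",
  "bin_labels": ["0%", ">0-20%", ">20-40%", ">40-60%", ">60-80%", ">80-<100%", "100%"],
  "literature_comparisons": [
    {"name": "NHANES", "european": true,
     "totals": [1, 3, 1, 10, 14, 9, 0], "differing": [0, 1, 1, 7, 12, 7, 0]},
    {"name": "Cross_European", "european": true,
     "totals": [0, 1, 4, 11, 8, 3, 0], "differing": [0, 1, 2, 9, 6, 3, 0]},
    {"name": "Cross_AmericanIndian", "european": false,
     "totals": [0, 1, 4, 11, 8, 3, 0], "differing": [0, 1, 4, 7, 5, 2, 0]},
    {"name": "Huang", "european": true,
     "totals": [0, 2, 3, 5, 13, 4, 0], "differing": [0, 2, 2, 5, 9, 4, 0]}
  ],
  "functional_groups": {
    "base_rate": 0.471,
    "alpha": 0.05,
    "n_groups": 53,
    "n_significant": 7,
    "n_more": 28,
    "n_less": 25,
    "rows": [
      {"group": "2", "total_snps": 70, "differing": 38, "genes": 12, "direction": "MORE"},
      {"group": "5", "total_snps": 130, "differing": 67, "genes": 15, "direction": "MORE"},
      {"group": "6", "total_snps": 100, "differing": 49, "genes": 12, "direction": "MORE"},
      {"group": "7", "total_snps": 144, "differing": 49, "genes": 7, "direction": "LESS"},
      {"group": "8", "total_snps": 834, "differing": 378, "genes": 93, "direction": "LESS"},
      {"group": "9", "total_snps": 76, "differing": 31, "genes": 6, "direction": "LESS"},
      {"group": "10", "total_snps": 84, "differing": 45, "genes": 9, "direction": "MORE"},
      {"group": "11", "total_snps": 16, "differing": 9, "genes": 7, "direction": "MORE"},
      {"group": "12", "total_snps": 40, "differing": 17, "genes": 5, "direction": "LESS"},
      {"group": "14", "total_snps": 367, "differing": 159, "genes": 31, "direction": "LESS"},
      {"group": "15", "total_snps": 65, "differing": 27, "genes": 6, "direction": "LESS"},
      {"group": "17", "total_snps": 62, "differing": 34, "genes": 5, "direction": "MORE"},
      {"group": "18", "total_snps": 49, "differing": 25, "genes": 6, "direction": "MORE"},
      {"group": "19", "total_snps": 145, "differing": 65, "genes": 12, "direction": "LESS"},
      {"group": "20", "total_snps": 94, "differing": 40, "genes": 7, "direction": "LESS"},
      {"group": "21", "total_snps": 105, "differing": 38, "genes": 5, "direction": "LESS"},
      {"group": "22", "total_snps": 50, "differing": 24, "genes": 9, "direction": "MORE"},
      {"group": "23", "total_snps": 91, "differing": 36, "genes": 6, "direction": "LESS"},
      {"group": "24", "total_snps": 72, "differing": 40, "genes": 5, "direction": "MORE"},
      {"group": "25", "total_snps": 107, "differing": 48, "genes": 13, "direction": "LESS"},
      {"group": "26", "total_snps": 50, "differing": 20, "genes": 8, "direction": "LESS"},
      {"group": "27", "total_snps": 84, "differing": 43, "genes": 12, "direction": "MORE"},
      {"group": "28", "total_snps": 18, "differing": 14, "genes": 5, "direction": "MORE"},
      {"group": "29", "total_snps": 343, "differing": 147, "genes": 15, "direction": "LESS"},
      {"group": "30", "total_snps": 551, "differing": 254, "genes": 18, "direction": "MORE"},
      {"group": "31", "total_snps": 75, "differing": 32, "genes": 5, "direction": "MORE"},
      {"group": "32", "total_snps": 551, "differing": 266, "genes": 27, "direction": "MORE"},
      {"group": "33", "total_snps": 628, "differing": 301, "genes": 62, "direction": "MORE"},
      {"group": "34", "total_snps": 334, "differing": 172, "genes": 25, "direction": "MORE"},
      {"group": "35", "total_snps": 143, "differing": 82, "genes": 10, "direction": "MORE"},
      {"group": "36", "total_snps": 31, "differing": 20, "genes": 6, "direction": "MORE"},
      {"group": "37", "total_snps": 25, "differing": 10, "genes": 11, "direction": "LESS"},
      {"group": "39", "total_snps": 93, "differing": 46, "genes": 13, "direction": "MORE"},
      {"group": "40", "total_snps": 423, "differing": 184, "genes": 10, "direction": "LESS"},
      {"group": "41", "total_snps": 60, "differing": 30, "genes": 5, "direction": "MORE"},
      {"group": "42", "total_snps": 71, "differing": 37, "genes": 6, "direction": "MORE"},
      {"group": "44", "total_snps": 32, "differing": 17, "genes": 8, "direction": "MORE"},
      {"group": "46", "total_snps": 83, "differing": 34, "genes": 9, "direction": "LESS"},
      {"group": "47", "total_snps": 104, "differing": 40, "genes": 23, "direction": "LESS"},
      {"group": "49", "total_snps": 16, "differing": 8, "genes": 6, "direction": "LESS"},
      {"group": "50", "total_snps": 37, "differing": 21, "genes": 6, "direction": "MORE"},
      {"group": "52", "total_snps": 99, "differing": 42, "genes": 32, "direction": "LESS"},
      {"group": "53", "total_snps": 41, "differing": 14, "genes": 5, "direction": "LESS"}
    ]
  }
}
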