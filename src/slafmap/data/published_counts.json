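{
  "description": "Published marker counts and per-chromosome map figures from the sorghum F2 SLAF-seq mapping study this package models; inputs for the desk-scale summary arithmetic.",
  "slaf_identification": {
    "polymorphic": 6353,
    "non_polymorphic": 46575,
    "total": 52928
  },
  "genotyping": {
    "polymorphic": 6353,
    "genotyped": 5829,
    "aabb_pattern": 5093,
    "mapped": 2246
  },
  "map_per_lg": [
    {"lg": 1, "n_markers": 200, "snp_only": 199, "indel_only": 1, "snp_indel": 0, "total_distance_cM": 238.7, "avg_distance_cM": 1.20, "largest_gap_cM": 14.1, "pct_gaps_le5": 97.5, "n_distorted": 132, "n_sdr": 4},
    {"lg": 2, "n_markers": 292, "snp_only": 290, "indel_only": 0, "snp_indel": 2, "total_distance_cM": 287.9, "avg_distance_cM": 0.99, "largest_gap_cM": 8.5, "pct_gaps_le5": 99.0, "n_distorted": 112, "n_sdr": 7},
    {"lg": 3, "n_markers": 250, "snp_only": 249, "indel_only": 0, "snp_indel": 1, "total_distance_cM": 286.7, "avg_distance_cM": 1.15, "largest_gap_cM": 7.4, "pct_gaps_le5": 98.4, "n_distorted": 156, "n_sdr": 13},
    {"lg": 4, "n_markers": 315, "snp_only": 314, "indel_only": 0, "snp_indel": 1, "total_distance_cM": 300.4, "avg_distance_cM": 0.96, "largest_gap_cM": 13.7, "pct_gaps_le5": 98.1, "n_distorted": 188, "n_sdr": 14},
    {"lg": 5, "n_markers": 218, "snp_only": 217, "indel_only": 1, "snp_indel": 0, "total_distance_cM": 183.7, "avg_distance_cM": 0.85, "largest_gap_cM": 9.4, "pct_gaps_le5": 97.2, "n_distorted": 140, "n_sdr": 7},
    {"lg": 6, "n_markers": 216, "snp_only": 213, "indel_only": 1, "snp_indel": 2, "total_distance_cM": 175.0, "avg_distance_cM": 0.81, "largest_gap_cM": 10.7, "pct_gaps_le5": 98.1, "n_distorted": 74, "n_sdr": 7},
    {"lg": 7, "n_markers": 217, "snp_only": 217, "indel_only": 0, "snp_indel": 0, "total_distance_cM": 266.3, "avg_distance_cM": 1.23, "largest_gap_cM": 15.7, "pct_gaps_le5": 96.3, "n_distorted": 131, "n_sdr": 10},
    {"lg": 8, "n_markers": 189, "snp_only": 189, "indel_only": 0, "snp_indel": 0, "total_distance_cM": 134.6, "avg_distance_cM": 0.72, "largest_gap_cM": 8.6, "pct_gaps_le5": 98.9, "n_distorted": 101, "n_sdr": 8},
    {"lg": 9, "n_markers": 123, "snp_only": 123, "indel_only": 0, "snp_indel": 0, "total_distance_cM": 152.2, "avg_distance_cM": 1.25, "largest_gap_cM": 4.3, "pct_gaps_le5": 100.0, "n_distorted": 72, "n_sdr": 6},
    {"lg": 10, "n_markers": 226, "snp_only": 226, "indel_only": 0, "snp_indel": 0, "total_distance_cM": 132.8, "avg_distance_cM": 0.59, "largest_gap_cM": 9.7, "pct_gaps_le5": 97.8, "n_distorted": 86, "n_sdr": 5}
  ],
  "snp_types": {"R": 915, "Y": 914, "S": 255, "W": 243, "K": 231, "M": 234},
  "distortion": {"total_distorted": 1192, "total_mapped": 2246, "n_sdr": 98}
}
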