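{
 "1": "f01_attenuation",
 "2": "f02_attenuation_contrast",
 "3": "f03_attenuation_heterogeneity",
 "4": "f04_contrast_heterogeneity",
 "5": "f05_mean_lesion_contrast",
 "6": "f06_mean_boundary",
 "7": "f07_boundary_heterogeneity",
 "8": "f08_boundary_contrast",
 "9": "f09_boundary_het_contrast",
 "10": "f10_boundary_lesion_contrast",
 "11": "f11_dermis_lesion_het_contrast",
 "12": "f12_boundary_lesion_het_contrast",
 "13": "f13_skewness",
 "14": "f14_kurtosis",
 "15": "f15_entropy",
 "16": "f16_curvature_std",
 "17": "f17_circularity",
 "18": "f18_axis_ratio",
 "19": "f19_pa_ratio",
 "20": "f20_compactness",
 "21": "f21_contrast_lesion_h",
 "22": "f22_corr1_lesion_h",
 "23": "f23_corr2_lesion_h",
 "24": "f24_dissimilarity_lesion_h",
 "25": "f25_maxprob_lesion_h",
 "26": "f26_diffvar_lesion_h",
 "27": "f27_diffent_lesion_h",
 "28": "f28_infocorr1_lesion_h",
 "29": "f29_contrast_lesion_v",
 "30": "f30_corr1_lesion_v",
 "31": "f31_corr2_lesion_v",
 "32": "f32_dissimilarity_lesion_v",
 "33": "f33_energy_lesion_v",
 "34": "f34_entropy_lesion_v",
 "35": "f35_hom1_lesion_v",
 "36": "f36_hom2_lesion_v",
 "37": "f37_maxprob_lesion_v",
 "38": "f38_diffvar_lesion_v",
 "39": "f39_diffent_lesion_v",
 "40": "f40_infocorr1_lesion_v",
 "41": "f41_infocorr2_lesion_v",
 "42": "f42_contrast_dermis_h",
 "43": "f43_corr1_dermis_h",
 "44": "f44_corr2_dermis_h",
 "45": "f45_dissimilarity_dermis_h",
 "46": "f46_maxprob_dermis_h",
 "47": "f47_diffvar_dermis_h",
 "48": "f48_diffent_dermis_h",
 "49": "f49_infocorr1_dermis_h",
 "50": "f50_contrast_dermis_v",
 "51": "f51_corr1_dermis_v",
 "52": "f52_corr2_dermis_v",
 "53": "f53_dissimilarity_dermis_v",
 "54": "f54_energy_dermis_v",
 "55": "f55_entropy_dermis_v",
 "56": "f56_hom1_dermis_v",
 "57": "f57_hom2_dermis_v",
 "58": "f58_maxprob_dermis_v",
 "59": "f59_diffvar_dermis_v",
 "60": "f60_diffent_dermis_v",
 "61": "f61_infocorr1_dermis_v",
 "62": "f62_infocorr2_dermis_v"
}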