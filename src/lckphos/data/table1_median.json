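{
 "k_on": 8.9e-4,
 "k_on_csk": 5.9e-4,
 "k_off_1": 1.0e-1,
 "k_off_2": 4.9e2,
 "k_off_3": 6.1e5,
 "k_off_4": 2.6e7,
 "k_off_5": 6.4e2,
 "k_off_6": 7.6e-4,
 "k_off_7": 1.1e-3,
 "k_off_8": 1.2e-3,
 "k_off_9": 2.3e2,
 "k_off_10": 5.3e1,
 "k_off_11": 7.7e4,
 "k_off_12": 5.4e1,
 "k_off_13": 1.6e1,
 "k_off_14": 5.6e6,
 "k_off_15": 2.4e-11,
 "k_off_16": 1.6e0,
 "k_cat_1": 2.7e3,
 "k_cat_2": 4.2e1,
 "k_cat_3": 7.6e-11,
 "k_cat_4": 2.2e-3,
 "k_cat_5": 3.9e1,
 "k_cat_6": 4.6e-6,
 "k_cat_7": 5.9e-12,
 "k_cat_8": 6.6e-11,
 "k_cat_9": 1.3e1,
 "k_cat_10": 6.3e-8,
 "k_cat_11": 9.5e-3,
 "k_cat_12": 1.9e-6,
 "k_cat_13": 9.2e2,
 "k_cat_14": 5.8e-11,
 "k_cat_15": 8.1e-4,
 "k_cat_16": 6.3e-2,
 "k_off_csk_uu": 4.4e-2,
 "k_off_csk_pu": 1.3e-6,
 "k_cat_csk_uu": 2.1e-3,
 "k_cat_csk_pu": 1.8e7
}
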