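{
 "k_on": [6.8e-4, 1.9e-3],
 "k_on_csk": [4.4e-4, 1.2e-3],
 "k_off_1": [4.8e-7, 3.0e-2],
 "k_off_2": [4.1e2, 1.5e3],
 "k_off_3": [9.7e4, 2.8e6],
 "k_off_4": [4.6e3, 2.8e7],
 "k_off_5": [5.5e2, 5.1e3],
 "k_off_6": [2.6e-5, 1.5e-3],
 "k_off_7": [1.2e-3, 1.8e-2],
 "k_off_8": [1.9e-3, 6.1e-2],
 "k_off_9": [1.8e2, 7.0e2],
 "k_off_10": [1.3e0, 7.7e3],
 "k_off_11": [1.3e0, 2.1e4],
 "k_off_12": [1.0e1, 1.1e4],
 "k_off_13": [1.8e-3, 5.1e1],
 "k_off_14": [1.1e6, 9.1e6],
 "k_off_15": [1.8e-11, 9.7e-10],
 "k_off_16": [6.8e-1, 2.5e0],
 "k_cat_1": [2.1e3, 6.5e3],
 "k_cat_2": [2.9e1, 8.4e1],
 "k_cat_3": [2.5e-11, 5.2e-8],
 "k_cat_4": [5.1e-6, 1.3e-1],
 "k_cat_5": [5.4e-1, 5.0e1],
 "k_cat_6": [1.2e-8, 6.6e-6],
 "k_cat_7": [8.3e-12, 3.8e-10],
 "k_cat_8": [1.0e-11, 1.8e-9],
 "k_cat_9": [9.4e0, 3.0e1],
 "k_cat_10": [1.9e-8, 2.2e-3],
 "k_cat_11": [2.3e-5, 5.4e-1],
 "k_cat_12": [3.4e-7, 1.0e-4],
 "k_cat_13": [2.0e2, 9.1e3],
 "k_cat_14": [3.0e-12, 6.5e-9],
 "k_cat_15": [8.1e-4, 8.1e-4],
 "k_cat_16": [9.0e-5, 6.6e-2],
 "k_off_csk_uu": [2.5e-2, 8.6e-2],
 "k_off_csk_pu": [1.4e-7, 1.4e-5],
 "k_cat_csk_uu": [1.5e-3, 2.0e-3],
 "k_cat_csk_pu": [9.3e5, 2.6e7]
}
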