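{
 "v_txn_p": 0.26726,
 "K_txn_p": 0.33468,
 "K_b": 0.00117,
 "v_deg_p": 0.55011,
 "K_deg_p": 0.00146,
 "v_txn_c1": 0.08212,
 "v_txn_c2": 0.07313,
 "K_txn_c": 0.28353,
 "v_deg_c1": 0.58013,
 "v_deg_c2": 0.52993,
 "K_deg_c": 1.98812,
 "v_txn_ror": 0.08178,
 "K_txn_ror": 0.23693,
 "v_deg_ror": 0.51117,
 "K_deg_ror": 1.20013,
 "v_txn_rev": 1.15003,
 "K_txn_rev": 0.09945,
 "v_deg_rev": 25.9998,
 "K_deg_rev": 2.69984,
 "K_tln_p": 2.00001,
 "v_deg_P": 4.65,
 "K_deg_P": 0.00031,
 "v_a_CP": 0.00882,
 "v_d_CP": 0.05999,
 "v_deg_C1": 1.59984,
 "K_deg_C": 2.08639,
 "v_deg_C2": 1.51491,
 "K_tln_ror": 0.35918,
 "v_deg_ROR": 1.29973,
 "K_deg_ROR": 1.95961,
 "K_tln_rev": 0.25461,
 "v_deg_REV": 1.29951,
 "K_deg_REV": 1.9601,
 "v_txn_ROR": 1.81951,
 "v_txn_REV": 2.01031,
 "K_txn_REV": 1.72406,
 "K_txn_ROR": 1.07518,
 "v_deg_b": 1.93448,
 "K_deg_b": 0.55369,
 "K_tln_b": 0.37069,
 "v_deg_B": 1.86141,
 "K_deg_B": 2.71612,
 "v_deg_C1N": 0.07588,
 "K_deg_CP": 0.05499,
 "v_deg_C2N": 0.2301,
 "K_tln_c1": 0.84609,
 "K_tln_c2": 0.98606
}
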