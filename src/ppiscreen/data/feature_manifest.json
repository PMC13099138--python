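{
  "version": "1.0",
  "confidence": [
    "ipae_top_quarter",
    "tpae_top_quarter",
    "mean_interchain_pae",
    "mean_iface_plddt",
    "min_entity_mean_plddt",
    "ptm",
    "iptm"
  ],
  "counting": [
    "n_iface_res_total",
    "n_iface_res_e1",
    "n_iface_res_e2",
    "n_charged_interface",
    "n_positive_iface",
    "n_negative_iface",
    "n_polar_iface",
    "n_hydrophobic_iface",
    "n_aromatic_iface",
    "n_gly_iface",
    "n_pro_iface",
    "contact_charged_charged",
    "contact_charged_polar",
    "contact_charged_hydrophobic",
    "contact_charged_special",
    "contact_polar_polar",
    "contact_polar_hydrophobic",
    "contact_polar_special",
    "contact_hydrophobic_hydrophobic",
    "contact_hydrophobic_special",
    "contact_special_special",
    "prop_iface_H_e1",
    "prop_iface_E_e1",
    "prop_iface_C_e1",
    "prop_iface_H_e2",
    "prop_iface_E_e2",
    "prop_iface_C_e2",
    "prop_iface_beta",
    "n_contact_pairs",
    "mean_pairs_per_iface_res",
    "prop_charged_iface",
    "prop_hydrophobic_iface",
    "prop_polar_iface"
  ],
  "energy": [
    "total_lj_atr",
    "total_lj_rep",
    "total_solv",
    "total_elec",
    "total_hbond",
    "avg_lj_atr",
    "avg_lj_rep",
    "avg_solv",
    "avg_elec",
    "avg_hbond",
    "weighted_total",
    "avg_weighted_total",
    "mean_pair_lj_atr",
    "mean_pair_lj_rep",
    "mean_pair_elec",
    "min_residue_weighted",
    "max_residue_rep"
  ]
}
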