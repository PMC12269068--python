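{
  "_provenance": {
    "pzc_logk": "point of zero charge of the goethite used here (Weng et al. 2008); protonation logK of singly and triply coordinated sites in the 1-pK MUSIC convention",
    "singly_site_density": "singly coordinated FeOH site density of goethite, sites nm^-2 (Hiemstra goethite model)",
    "triply_site_density": "triply coordinated Fe3O site density, sites nm^-2; literature default from the Hiemstra goethite model, not printed in the source study",
    "c1_F_m2": "inner Stern capacitance, F m^-2; literature default for goethite (Hiemstra et al.), not printed in the source study",
    "c2_F_m2": "outer Stern capacitance, F m^-2; literature default for goethite (Hiemstra et al.), not printed in the source study",
    "na_pair_logk": "formation logK of the FeOH(-0.5)-Na+ outer-sphere pair, Na+ charge in plane 1; literature default (Hiemstra et al.)",
    "no3_pair_dlogk": "logK of FeOH2(+0.5)-NO3- relative to site protonation; literature default (Hiemstra et al.)",
    "fenomh_logk_h": "protonation constant log K_H of the inner-sphere NOM complex; value depends on the NOM material (Deng et al.); literature-informed default for humic acid, not printed in the source study",
    "logk_water": "water autoprotolysis at 25 C",
    "pmg_aqueous_logk": "cumulative protonation logK of glyphosate from PMG(3-): amine, second phosphonate, carboxylate, first phosphonate steps (pKa 10.14, 5.46, 2.23, 0.8); literature values, the study's own table is not printed",
    "pmg_surface_species": "glyphosate surface complexes on goethite (monodentate and bidentate phosphonate binding, amine/carboxylate charge placed outward in the Stern layer); literature-informed defaults in the CD-MUSIC style (cf. Geysels et al. 2024), not printed in the source study",
    "ssa_m2_g": "BET specific surface area of the goethite, m2 g^-1",
    "lod_M": "limit of detection of dissolved PMG, mol L^-1 (lowest reported measurable concentration)"
  },
  "pzc_logk": 9.3,
  "singly_site_density": 3.45,
  "triply_site_density": 2.7,
  "c1_F_m2": 0.9,
  "c2_F_m2": 0.74,
  "na_pair_logk": -0.6,
  "no3_pair_dlogk": -0.6,
  "fenomh_logk_h": 5.0,
  "logk_water": -14.0,
  "pmg_aqueous_logk": [10.14, 15.6, 17.83, 18.63],
  "pmg_surface_species": [
    {"name": "FeOPMG-H2", "n_feoh": 1, "n_h": 2, "logK": 22.5, "dz": [0.3, -0.8, -0.5]},
    {"name": "FeOPMG-H", "n_feoh": 1, "n_h": 1, "logK": 15.5, "dz": [0.3, -1.3, -1.0]},
    {"name": "(FeO)2PMG-H3", "n_feoh": 2, "n_h": 3, "logK": 31.5, "dz": [0.5, 0.0, -0.5]}
  ],
  "ssa_m2_g": 94.0,
  "lod_M": 6e-7
}
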