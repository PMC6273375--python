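{
  "components": [
    {
      "component_id": "NA",
      "molar_mass": 122.12,
      "segment_number": 4.6485,
      "segment_diameter": 2.1775,
      "dispersion_energy": 176.69,
      "assoc_energy": 2195.3,
      "assoc_volume": 0.02,
      "n_donor_sites": 2,
      "n_acceptor_sites": 2,
      "induced_association": false
    },
    {
      "component_id": "SA",
      "molar_mass": 118.09,
      "segment_number": 4.3346,
      "segment_diameter": 3.0546,
      "dispersion_energy": 477.44,
      "assoc_energy": 1701.69,
      "assoc_volume": 0.02,
      "n_donor_sites": 2,
      "n_acceptor_sites": 2,
      "induced_association": false
    },
    {
      "component_id": "water",
      "molar_mass": 18.015,
      "segment_number": 1.2047,
      "segment_diameter": 2.7927,
      "sigma_rule": "water",
      "dispersion_energy": 353.94,
      "assoc_energy": 2424.67,
      "assoc_volume": 0.045,
      "n_donor_sites": 1,
      "n_acceptor_sites": 1,
      "induced_association": false
    },
    {
      "component_id": "acetonitrile",
      "molar_mass": 41.052,
      "segment_number": 2.329,
      "segment_diameter": 3.1898,
      "dispersion_energy": 311.31,
      "assoc_energy": 0.0,
      "assoc_volume": 0.01,
      "n_donor_sites": 1,
      "n_acceptor_sites": 1,
      "induced_association": true
    },
    {
      "component_id": "ethanol",
      "molar_mass": 46.069,
      "segment_number": 2.3827,
      "segment_diameter": 3.1771,
      "dispersion_energy": 198.24,
      "assoc_energy": 2653.4,
      "assoc_volume": 0.03284,
      "n_donor_sites": 1,
      "n_acceptor_sites": 1,
      "induced_association": false
    },
    {
      "component_id": "ethyl_acetate",
      "molar_mass": 88.105,
      "segment_number": 3.5375,
      "segment_diameter": 3.3079,
      "dispersion_energy": 230.8,
      "assoc_energy": 0.0,
      "assoc_volume": 0.01,
      "n_donor_sites": 1,
      "n_acceptor_sites": 1,
      "induced_association": true
    }
  ],
  "melting": [
    {
      "component_id": "NA",
      "melting_temperature": 401.15,
      "fusion_enthalpy": 28.0,
      "delta_cp": 78.12
    },
    {
      "component_id": "SA",
      "melting_temperature": 461.15,
      "fusion_enthalpy": 38.91,
      "delta_cp": 69.79
    }
  ],
  "binaries": [
    {
      "pair": ["NA", "water"],
      "k_slope": 9.46e-05,
      "k_intercept": -0.0294,
      "valid_T_range": [298.0, 328.0],
      "provenance": "solubility-fitted"
    },
    {
      "pair": ["NA", "acetonitrile"],
      "k_slope": 0.000292,
      "k_intercept": -0.0846,
      "valid_T_range": [288.47, 309.4],
      "provenance": "solubility-fitted"
    },
    {
      "pair": ["NA", "ethanol"],
      "k_slope": 8.39e-05,
      "k_intercept": -0.021,
      "valid_T_range": [293.51, 318.05],
      "provenance": "solubility-fitted"
    },
    {
      "pair": ["NA", "ethyl_acetate"],
      "k_slope": 0.000768,
      "k_intercept": -0.266,
      "valid_T_range": [288.15, 318.15],
      "provenance": "solubility-fitted"
    },
    {
      "pair": ["SA", "water"],
      "k_slope": -7.3e-05,
      "k_intercept": -0.00556,
      "valid_T_range": [293.15, 318.15],
      "provenance": "solubility-fitted"
    },
    {
      "pair": ["SA", "acetonitrile"],
      "k_slope": 4.7e-05,
      "k_intercept": -0.238,
      "valid_T_range": [293.15, 318.15],
      "provenance": "solubility-fitted"
    },
    {
      "pair": ["SA", "ethanol"],
      "k_slope": 0.000263,
      "k_intercept": -0.3,
      "valid_T_range": [293.15, 318.15],
      "provenance": "solubility-fitted"
    },
    {
      "pair": ["SA", "ethyl_acetate"],
      "k_slope": 0.000153,
      "k_intercept": -0.274,
      "valid_T_range": [293.15, 318.15],
      "provenance": "solubility-fitted"
    },
    {
      "pair": ["ethanol", "water"],
      "k_slope": 0.0,
      "k_intercept": -0.0382,
      "valid_T_range": [343.0, 343.0],
      "provenance": "VLE-fitted"
    },
    {
      "pair": ["ethanol", "acetonitrile"],
      "k_slope": 0.0,
      "k_intercept": -0.005,
      "valid_T_range": [293.15, 293.15],
      "provenance": "VLE-fitted"
    },
    {
      "pair": ["ethanol", "ethyl_acetate"],
      "k_slope": 0.0,
      "k_intercept": -0.018,
      "valid_T_range": [344.58, 350.55],
      "provenance": "VLE-fitted"
    }
  ],
  "cocrystals": [
    {
      "api_id": "NA",
      "cf_id": "SA",
      "nu_api": 2,
      "nu_cf": 1,
      "ks_ref": 3.7e-07,
      "t_ref": 298.15,
      "dh_ref": 64.75
    }
  ]
}
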