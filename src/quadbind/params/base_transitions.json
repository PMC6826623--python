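{
  "_comment": "Representative pi-pi* monomer transitions of the DNA nucleobases: vertical energy (eV), electric transition dipole magnitude (Debye), and in-plane polarization angle (degrees, measured from the base frame x-axis, i.e. the glycosidic C1'->N direction, toward the y-axis). Edit freely; quadbind orients each dipole with the instantaneous base frame.",
  "A": [
    {"energy_ev": 4.75, "mu_debye": 3.5, "angle_deg": 66.0},
    {"energy_ev": 4.97, "mu_debye": 1.5, "angle_deg": 19.0}
  ],
  "G": [
    {"energy_ev": 4.56, "mu_debye": 3.2, "angle_deg": -25.0},
    {"energy_ev": 4.95, "mu_debye": 3.5, "angle_deg": 75.0}
  ],
  "C": [
    {"energy_ev": 4.66, "mu_debye": 2.9, "angle_deg": 25.0},
    {"energy_ev": 5.39, "mu_debye": 2.2, "angle_deg": -35.0}
  ],
  "T": [
    {"energy_ev": 4.68, "mu_debye": 3.0, "angle_deg": -19.0},
    {"energy_ev": 5.30, "mu_debye": 2.0, "angle_deg": 50.0}
  ]
}
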