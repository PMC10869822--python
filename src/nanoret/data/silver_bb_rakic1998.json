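{
  "name": "Ag-BB-Rakic1998",
  "description": "Brendel-Bormann fit of the dielectric function of silver. Parameters from the published fit of Rakic, Djurisic, Elazar and Majewski, Applied Optics 37, 5271 (1998), Table 1 (plasma energy) and Table 3 (BB oscillators). Validity roughly 0.1-6 eV.",
  "provenance": "Published parameter table reproduced by hand (the table is carried verbatim in many open optics codes); swap this file to use a different fit.",
  "eps_inf": 1.0,
  "plasma_energy_eV": 9.01,
  "drude_strength": 0.821,
  "drude_damping_eV": 0.049,
  "oscillators": [
    [0.050, 2.025, 0.189, 1.894],
    [0.133, 5.185, 0.067, 0.665],
    [0.051, 4.343, 0.019, 0.189],
    [0.467, 9.809, 0.117, 1.170],
    [4.000, 18.56, 0.052, 0.516]
  ],
  "oscillator_columns": ["strength_f", "energy_eV", "damping_eV", "gaussian_width_eV"]
}
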