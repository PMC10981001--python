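# Physical nuclide data (ICRP-107-style compendium values).
# half_life_hours: physical half-life.
# emissions: mean energy per decay (MeV) and per-parent-decay yield, grouped by
#   kind (alpha, beta_or_electron, photon). Energies here are already
#   yield-weighted means per decay, so yield is 1.0 unless a branch applies.
# progeny: daughters assumed in secular equilibrium in situ, with branching
#   fractions per parent decay.
# rbe: per-kind relative biological effectiveness weights (default 1).
ga68:
  half_life_hours: 1.1285
  emissions:
    - {kind: beta_or_electron, energy_mev: 0.7399, yield: 1.0}
    - {kind: photon, energy_mev: 1.077, yield: 1.0}
lu177:
  half_life_hours: 159.528
  emissions:
    - {kind: beta_or_electron, energy_mev: 0.1479, yield: 1.0}
    - {kind: photon, energy_mev: 0.0336, yield: 1.0}
ac225:
  half_life_hours: 238.08
  emissions:
    - {kind: alpha, energy_mev: 5.830, yield: 1.0}
    - {kind: beta_or_electron, energy_mev: 0.0216, yield: 1.0}
    - {kind: photon, energy_mev: 0.0179, yield: 1.0}
  rbe: {alpha: 5.0}
  progeny:
    - {name: fr221, branching: 1.0}
fr221:
  half_life_hours: 0.08167
  emissions:
    - {kind: alpha, energy_mev: 6.300, yield: 1.0}
    - {kind: beta_or_electron, energy_mev: 0.0105, yield: 1.0}
    - {kind: photon, energy_mev: 0.0310, yield: 1.0}
  rbe: {alpha: 5.0}
  progeny:
    - {name: at217, branching: 1.0}
at217:
  half_life_hours: 8.97e-6
  emissions:
    - {kind: alpha, energy_mev: 7.066, yield: 1.0}
  rbe: {alpha: 5.0}
  progeny:
    - {name: bi213, branching: 1.0}
bi213:
  half_life_hours: 0.7600
  emissions:
    - {kind: alpha, energy_mev: 5.870, yield: 0.0214}
    - {kind: beta_or_electron, energy_mev: 0.4350, yield: 1.0}
    - {kind: photon, energy_mev: 0.1300, yield: 1.0}
  rbe: {alpha: 5.0}
  progeny:
    - {name: po213, branching: 0.9786}
    - {name: tl209, branching: 0.0214}
po213:
  half_life_hours: 1.167e-9
  emissions:
    - {kind: alpha, energy_mev: 8.376, yield: 1.0}
  rbe: {alpha: 5.0}
  progeny:
    - {name: pb209, branching: 1.0}
tl209:
  half_life_hours: 0.0367
  emissions:
    - {kind: beta_or_electron, energy_mev: 0.6600, yield: 1.0}
    - {kind: photon, energy_mev: 1.5600, yield: 1.0}
  rbe: {alpha: 5.0}
  progeny:
    - {name: pb209, branching: 1.0}
pb209:
  half_life_hours: 3.253
  emissions:
    - {kind: beta_or_electron, energy_mev: 0.1980, yield: 1.0}
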