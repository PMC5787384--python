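{
 "hamiltonian": {
  "kind": "exciton",
  "alpha": 1.46,
  "beta": 0.037,
  "ell": 1.24
 },
 "ansatz": {
  "kind": "single_qubit"
 },
 "ground": {
  "n_particles": 10,
  "n_epochs": 15,
  "temperature": 1.25,
  "shots_per_basis": 10000,
  "branch_hint": [
   0.09916951332346947,
   0.3408304866765305
  ]
 },
 "excited": {
  "n_particles": 10,
  "n_epochs": 15,
  "shots_per_basis": 10000,
  "branch_hint": [
   0.09916951332346947,
   0.3408304866765305
  ]
 },
 "excitations": [
  "exciton"
 ],
 "ipea": {
  "n_bits": 32,
  "shots_per_bit": 0,
  "branch_hint": [
   0.09916951332346947,
   0.3408304866765305
  ]
 },
 "t": 26.0,
 "seed": 0
}
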