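{
 "rat_d50.csv": {
  "sha256": "5544440709dc7d51d78be0fb4d30d0de5fc5bd980e350f7a26a2eb7c3b7c971d",
  "n_rows": 29
 },
 "rim_cohorts.csv": {
  "sha256": "4d38d83a7e9568fd4148eb16f62e7cc1c941e038f5178d692a86853c0924c043",
  "n_rows": 41
 },
 "corrections.csv": {
  "sha256": "62e46ee7dbe9b377c4ac91b0041f33261e208ec78cbfb5fae6e9dd1ffb205f11",
  "n_rows": 3
 }
}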