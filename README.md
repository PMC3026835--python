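# gnmpath

Fastest-mode Gaussian network model (GNM) analysis of ligand binding.
From an **unbound** (apo) protein structure, `gnmpath` predicts:

- the **interaction pathway** — the set of residues with non-zero total
  coupling `C_T` in the largest-eigenvalue (fastest) GNM mode, averaged over
  five contact-cutoff stations between 6.9 and 7.2 Å;
- the **hub residue** (global `C_T` maximum) and secondary peaks;
- **gate residues** at the extremities of each connected path component;
- **triad cliques** — three residues mutually within a tight cutoff
  (default 6.2 Å, sweep 6.0–6.4 Å) yet well separated along the sequence;

and validates them against the **bound** (holo) complex: a residue is a
*contacting residue* when any of its heavy atoms is strictly within 3.5 Å of
a ligand atom and it carries non-zero apo `C_T`.

## Library sketch

```python
from gnmpath import (load_calpha_chain, total_coupling_averaged,
                     extract_pathways, find_triad_cliques)

chain   = load_calpha_chain("1ni6.pdb", "B")
profile = total_coupling_averaged(chain)        # stations 6.9–7.2 Å × 5
print(profile.hub, profile.peaks[:3])
report  = extract_pathways(chain, profile)      # paths, gates, pair table
cliques = find_triad_cliques(chain, cutoff=6.2) # stiff residue triads
```

## CLI

```
gnmpath couple   --pdb apo.pdb --chain A            # C_T profile, hub, pathways
gnmpath cliques  --pdb apo.pdb --chain A --cutoff 6.2
gnmpath contacts --apo apo.pdb --holo holo.pdb --chain A --ligand HEM
gnmpath scan     --pdb-dir structures/ --what contacts
gnmpath toy      --kind clustered --n 40 --complex  # synthetic fixtures
```

Every command accepts `--config file` (`key = value` lines mirroring the
flags), writes TSV/CSV reports plus a `run.log` with full parameter
provenance into `--outdir`, and exits 0/1/2 (success / runtime error / bad
usage).

## Method parameters (defaults)

| quantity | default |
|---|---|
| contact condition | Cα–Cα distance ≤ cutoff (closed ball) |
| coupling stations | 6.9, 6.975, 7.05, 7.125, 7.2 Å (max-normalized, averaged) |
| mode | largest eigenvalue (`--mode-rank`, `--mode-weight {lambda,inv-lambda,none}`) |
| "non-zero" C_T threshold | 0.02 of the profile maximum |
| pair table | path residues ≤ 7.2 Å apart, sequence separation ≥ 10 |
| cliques | cutoff 6.2 Å (sweep 6.0–6.4), pairwise separation ≥ 4 |
| contact rule | any heavy atom < 3.5 Å from any ligand atom |

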