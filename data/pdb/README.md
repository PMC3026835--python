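# Benchmark structures (not bundled)

The per-structure acceptance targets and the optional tier of the test suite
run on six apo crystal structures that must be downloaded separately (this
repository ships no third-party coordinate files). Place them here as
lower-case `<id>.pdb`:

```
for id in 1ni6 1k3o 2hnp 3glk 2cbe 1k9p; do
  wget "https://files.rcsb.org/download/${id^^}.pdb" -O "data/pdb/${id}.pdb"
done
```

The bound-complex counterparts (1N3U, 1K3Y, 1BZC, 3GID, 1A42, 1K9K) are only
needed for the `gnmpath contacts` validation workflow.

With the files in place, `python scripts/acceptance.py --seed 1 --out
results/acceptance.json` reports every target, and the skipped tests in
`tests/test_acceptance.py` activate.
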