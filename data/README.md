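# Reference data (not shipped)

The tests that reproduce published TRPM8-family numbers need the real
protein sequences, which are not redistributed with this package. Place
them here:

- `real/trpm8_complete.fasta` — the 24 full-length vertebrate TRPM8
  proteins listed in the shipped manifest
  (`domevol.trpm8_manifest()`, `src/domevol/data/trpm8_manifest.tsv`),
  plus ideally the fragmented ones (coelacanth ENSLACP00000016045 is used
  by the identity checks). FASTA ids must be the accessions.
- `real/trpm_invertebrate.fasta` — invertebrate TRPM-like proteins; the
  lancelet entry XP_002592165.1 (*Branchiostoma floridae*) is used by the
  identity check.

`python scripts/fetch_real_data.py --email you@example.org` fetches the
NCBI/GenBank accessions automatically (network required). Accessions from
Ensembl archive releases are not fetchable through Entrez and must be
exported from an Ensembl archive browser by hand.

Without these files the corresponding acceptance tests in
`tests/test_acceptance.py` fail with an explanatory message; everything
else in the test suite is self-contained (synthetic data generated at
test time).
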