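#!/usr/bin/env python
"""Fetch the real TRPM8 reference sequences (requires network access).

Downloads every NCBI/GenBank accession in the shipped manifest into
data/real/trpm8_complete.fasta. Ensembl-archive accessions (and the
invertebrate TRPM-like set, data/real/trpm_invertebrate.fasta) cannot be
fetched automatically from old releases and must be exported by hand; see
data/README.md for the full accession lists.

Usage:
    python scripts/fetch_real_data.py --email you@example.org
"""

import argparse
from pathlib import Path

from domevol import trpm8_manifest
from domevol.fetch import fetch_ncbi


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="NCBI Entrez contact email")
    parser.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parents[1] / "data" / "real" / "trpm8_complete.fasta",
    )
    args = parser.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    records = fetch_ncbi(trpm8_manifest(), args.email, args.out)
    print(f"fetched {len(records)} sequences -> {args.out}")


if __name__ == "__main__":
    main()
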