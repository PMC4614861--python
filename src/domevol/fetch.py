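"""Optional network plumbing: fetch manifest accessions from NCBI.

Nothing in the library or test suite requires network access; this module is
for users who want to rebuild the real reference data set. Ensembl-archive
protein ids from old releases may no longer resolve — NCBI/GenBank accessions
are fetched here, and the rest must be exported from an Ensembl archive by
hand.
"""

from __future__ import annotations

import time
import warnings
from pathlib import Path

from .io import Manifest, SequenceRecord, write_fasta


def fetch_ncbi(
    manifest: Manifest,
    email: str,
    out_path: str | Path,
    delay: float = 0.4,
) -> list[SequenceRecord]:
    """Fetch all NCBI/GenBank accessions in a manifest and write a FASTA.

    Requires network access. Ensembl rows are skipped with a warning.
    """
    from Bio import Entrez, SeqIO

    Entrez.email = email
    records: list[SequenceRecord] = []
    for row in manifest.table.itertuples():
        if row.source not in {"NCBI", "GenBank"}:
            warnings.warn(f"skipping non-NCBI accession {row.accession} ({row.source})")
            continue
        with Entrez.efetch(
            db="protein", id=row.accession, rettype="fasta", retmode="text"
        ) as handle:
            rec = SeqIO.read(handle, "fasta")
        records.append(
            SequenceRecord(str(row.accession), str(rec.seq).upper(), species=str(row.species))
        )
        time.sleep(delay)
    write_fasta(records, out_path)
    return records
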