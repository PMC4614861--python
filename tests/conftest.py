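import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from domevol import Alignment, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_msa():
    """Small gapped alignment with a reference row for coordinate tests."""
    return Alignment(
        [
            SequenceRecord("ref", "AC-DEFG-HI"),
            SequenceRecord("s2", "ACQDEFGGHI"),
            SequenceRecord("s3", "AC-DE-G-HI"),
        ]
    )


def random_alignment(rng, n_rows=6, n_cols=40, gap_frac=0.1, ids=None):
    from domevol.io import AMINO_ACIDS

    letters = np.array(list(AMINO_ACIDS))
    rows = []
    ids = ids or [f"s{i}" for i in range(n_rows)]
    for rid in ids:
        chars = letters[rng.integers(0, 20, n_cols)]
        mask = rng.random(n_cols) < gap_frac
        chars = np.where(mask, "-", chars)
        rows.append(SequenceRecord(rid, "".join(chars)))
    aln = Alignment(rows)
    aln, _ = aln.drop_allgap_columns()
    return aln
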