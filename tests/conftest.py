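import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from infospectra import AlignmentSet, SequenceRecord


def make_alignment(rows, species="sp", aligned=True):
    """Build an AlignmentSet from a list of residue strings."""
    records = [
        SequenceRecord(f"{species}_{i + 1}", f"{species}_{i + 1} test sequence", row)
        for i, row in enumerate(rows)
    ]
    return AlignmentSet(species, records, aligned=aligned)


@pytest.fixture
def aln():
    return make_alignment


@pytest.fixture
def worked_alignment():
    """Eight aligned sequences over four columns: fully conserved, 50/50
    two-state, a three-state column, and an equiprobable four-state column
    — the worked vertical-entropy example."""
    c1 = "A" * 8
    c2 = "A" * 4 + "G" * 4
    c3 = "A" * 4 + "G" * 2 + "C" * 2
    c4 = "ACGT" * 2
    rows = ["".join(cs) for cs in zip(c1, c2, c3, c4)]
    return make_alignment(rows, species="worked")


def random_alignment(rng, n=None, L=None, alphabet="ACGT"):
    n = n if n is not None else int(rng.integers(2, 7))
    L = L if L is not None else int(rng.integers(2, 9))
    mat = rng.integers(0, len(alphabet), size=(n, L))
    rows = ["".join(alphabet[c] for c in row) for row in mat]
    return make_alignment(rows, species="rand")
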