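import numpy as np
import pytest

from barcodegap.distance import DistanceMatrix
from barcodegap.seqio import GeneAlignment, LabeledSequence


def make_seq(specimen_id, residues, species="spX", gene="COI", group="", fragment_class=""):
    return LabeledSequence(
        specimen_id=specimen_id,
        species=species,
        residues=residues,
        gene=gene,
        group=group,
        fragment_class=fragment_class,
    )


def make_alignment(rows, gene="COI"):
    """rows: iterable of (specimen_id, species, residues)."""
    return GeneAlignment(
        [make_seq(sid, res, species=sp, gene=gene) for sid, sp, res in rows],
        gene=gene,
    )


def matrix_from_dict(ids, entries):
    """Symmetric DistanceMatrix from {(a, b): distance} (missing -> 0)."""
    n = len(ids)
    idx = {name: i for i, name in enumerate(ids)}
    values = np.zeros((n, n))
    for (a, b), d in entries.items():
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = d
    counts = np.full((n, n), 100, dtype=int)
    return DistanceMatrix(list(ids), values, counts)


@pytest.fixture
def small_alignment():
    return make_alignment(
        [
            ("a1", "spA", "ACGTACGTAC"),
            ("a2", "spA", "ACGTACGTAT"),
            ("b1", "spB", "ACGAACGAAC"),
            ("b2", "spB", "ACGAACGAAT"),
        ]
    )
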