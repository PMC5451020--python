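"""Pseudogene (NUMT) screening of protein-coding barcode fragments.

Nuclear copies of mitochondrial genes accumulate frameshifts and premature
stop codons because they are released from coding constraint; a COI
fragment showing in-frame stops in every reading frame is therefore suspect.
The screen translates the ungapped sequence in all three frames under the
invertebrate mitochondrial code (NCBI table 5 by default), picks the frame
with the fewest internal stops, and flags sequences as ``stop_codon`` (the
best frame still contains internal stops) or ``frameshift_suspect`` (every
frame is stop-rich, the signature of an indel shifting the frame).

Without a reference reading frame the best frame is chosen by minimum
internal stop count — standard practice in NUMT screening when sequences
are aligned as codons against nothing in particular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from Bio.Data import CodonTable

_BASES = set("ACGT")


@dataclass(frozen=True)
class PseudogeneReport:
    """Stop-codon screen result for one specimen.

    ``verdict`` is ``clean`` (no internal stops in the best frame, no
    frameshift signature), ``stop_codon`` or ``frameshift_suspect``.
    """

    specimen_id: str
    best_frame: int
    stop_count_per_frame: tuple[int, int, int]
    internal_stops_best_frame: int
    frameshift_suspect: bool
    verdict: str


def _internal_stops(ungapped: str, frame: int, stops: frozenset[str]) -> int:
    codons = [
        ungapped[i : i + 3]
        for i in range(frame, len(ungapped) - 2, 3)
    ]
    if not codons:
        return 0
    count = 0
    for idx, codon in enumerate(codons):
        if not _BASES.issuperset(codon):
            continue  # ambiguity/N: codon skipped
        if codon in stops and idx != len(codons) - 1:
            count += 1  # terminal codon stop is not internal
    return count


def screen_coding_sequence(seq, genetic_code: int = 5) -> PseudogeneReport:
    """Screen one protein-coding sequence for pseudogene signatures.

    Gaps are removed before framing, so the report is invariant to
    alignment gaps.  Codons containing N or ambiguity codes are skipped.
    ``frameshift_suspect`` is raised when every frame carries at least
    ceil(L/300) internal stops (L = ungapped length) — roughly the expected
    stop load of non-coding sequence, scaled to fragment length.
    """
    gene = getattr(seq, "gene", "")
    if gene and gene.upper() not in ("COI", "COX1", "CO1"):
        raise ValueError(f"codon screen undefined for this gene: {gene!r}")
    residues = getattr(seq, "residues", seq)
    specimen_id = getattr(seq, "specimen_id", "")
    ungapped = residues.replace("-", "")
    if len(ungapped) < 30:
        raise ValueError(
            f"{specimen_id}: sequence too short for codon screening "
            f"({len(ungapped)} nt < 30)"
        )
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    stops = frozenset(table.stop_codons)
    counts = tuple(_internal_stops(ungapped, f, stops) for f in range(3))
    best_frame = min(range(3), key=lambda f: (counts[f], f))
    threshold = math.ceil(len(ungapped) / 300)
    frameshift = all(c >= threshold for c in counts)
    if counts[best_frame] == 0 and not frameshift:
        verdict = "clean"
    elif frameshift:
        verdict = "frameshift_suspect"
    else:
        verdict = "stop_codon"
    return PseudogeneReport(
        specimen_id=specimen_id,
        best_frame=best_frame,
        stop_count_per_frame=counts,
        internal_stops_best_frame=counts[best_frame],
        frameshift_suspect=frameshift,
        verdict=verdict,
    )


def screen_alignment(alignment, genetic_code: int = 5) -> list[PseudogeneReport]:
    """Screen every sequence of a protein-coding alignment."""
    return [screen_coding_sequence(seq, genetic_code) for seq in alignment]


def write_qc_table(reports: Iterable[PseudogeneReport], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("specimen_id\tbest_frame\tinternal_stops\tframeshift_suspect\tverdict\n")
        for rep in reports:
            fh.write(
                f"{rep.specimen_id}\t{rep.best_frame}\t"
                f"{rep.internal_stops_best_frame}\t"
                f"{str(rep.frameshift_suspect).lower()}\t{rep.verdict}\n"
            )
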