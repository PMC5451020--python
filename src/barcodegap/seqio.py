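"""Sequence and tree I/O with species/group metadata.

Aligned multi-FASTA is the native input.  Headers carry metadata in
pipe-delimited fields, ``Species|SpecimenID|Gene[|FragmentClass]``; a TSV
sidecar (columns ``specimen_id, species, group, gene, fragment_class``)
overrides header-derived fields, which keeps headers flexible when specimen
codes (e.g. ``ALful036``) carry no species string.

Genes amplified as several overlapping fragments (such as a ~468 bp and a
~342 bp 16S amplicon) are reduced to the region shared by every sequence
with :func:`trim_to_overlap` before distance analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide one-letter codes, alignment gap and hard-masked N.
ALPHABET = frozenset("ACGTURYSWKMBDHVN-")

#: Characters treated as missing data (never compared between sequences).
MISSING = frozenset(ALPHABET - set("ACGTU"))


class AlignmentError(ValueError):
    """Malformed alignment input (ragged lengths, bad residues, duplicates)."""


@dataclass(frozen=True)
class LabeledSequence:
    """One aligned sequence plus its specimen metadata.

    Residues are stored uppercase; allowed characters are the IUPAC
    nucleotide codes, ``-`` (gap) and ``N``.
    """

    specimen_id: str
    species: str
    residues: str
    gene: str = ""
    group: str = ""
    fragment_class: str = ""

    def __post_init__(self) -> None:
        res = self.residues.upper().replace("U", "T")
        if not res:
            raise AlignmentError(f"{self.specimen_id}: empty residue string")
        for pos, ch in enumerate(res):
            if ch not in ALPHABET:
                raise AlignmentError(
                    f"{self.specimen_id}: unknown residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        """Residues with alignment gaps removed."""
        return self.residues.replace("-", "")


@dataclass
class GeneAlignment:
    """Equal-length collection of :class:`LabeledSequence` for one gene."""

    sequences: list[LabeledSequence]
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("no records")
        length = len(self.sequences[0])
        seen: set[str] = set()
        for seq in self.sequences:
            if len(seq) != length:
                raise AlignmentError(
                    f"unequal sequence lengths: {seq.specimen_id} has "
                    f"{len(seq)} columns, expected {length}"
                )
            if seq.specimen_id in seen:
                raise AlignmentError(f"duplicate specimen_id {seq.specimen_id!r}")
            seen.add(seq.specimen_id)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.specimen_id for s in self.sequences]

    def species_map(self) -> dict[str, str]:
        """specimen_id -> species for all members."""
        return {s.specimen_id: s.species for s in self.sequences}

    def subset(self, ids: Iterable[str]) -> "GeneAlignment":
        wanted = set(ids)
        kept = [s for s in self.sequences if s.specimen_id in wanted]
        return GeneAlignment(kept, gene=self.gene)


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a TSV metadata sidecar into ``{specimen_id: {field: value}}``.

    Expected header columns: ``specimen_id`` (required) plus any of
    ``species, group, gene, fragment_class``.
    """
    table: dict[str, dict[str, str]] = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if "specimen_id" not in header:
            raise ValueError(f"{path}: metadata table lacks a specimen_id column")
        for line in handle:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            table[row["specimen_id"]] = row
    return table


def _parse_header(header: str, delimiter: str, defaults: Mapping[str, str]) -> dict:
    parts = header.split(delimiter)
    fields = dict(defaults)
    if len(parts) >= 2:
        fields["species"] = parts[0]
        fields["specimen_id"] = parts[1]
        if len(parts) >= 3 and parts[2]:
            fields["gene"] = parts[2]
        if len(parts) >= 4 and parts[3]:
            fields["fragment_class"] = parts[3]
    else:
        # Bare identifier: species must come from metadata or defaults.
        fields["specimen_id"] = parts[0]
    return fields


def read_labeled_fasta(
    path: str | Path | io.TextIOBase,
    delimiter: str = "|",
    defaults: Mapping[str, str] | None = None,
    metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> GeneAlignment:
    """Read an aligned multi-FASTA with pipe-delimited metadata headers.

    Parameters
    ----------
    path:
        FASTA file (aligned; all records equal length).
    delimiter:
        Field separator inside headers.
    defaults:
        Fallback metadata applied when neither header nor sidecar supplies a
        field (e.g. ``{"gene": "COI", "group": "Aphidiinae"}``).
    metadata:
        Sidecar mapping from :func:`read_metadata`; overrides header fields.
    """
    defaults = dict(defaults or {})
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise AlignmentError("no records")
    sequences = []
    for rec in records:
        fields = _parse_header(rec.description, delimiter, defaults)
        if metadata and fields.get("specimen_id") in metadata:
            side = metadata[fields["specimen_id"]]
            for key in ("species", "group", "gene", "fragment_class"):
                if side.get(key):
                    fields[key] = side[key]
        if "species" not in fields:
            raise AlignmentError(
                f"{fields.get('specimen_id', rec.id)}: species not given by "
                "header, metadata or defaults"
            )
        sequences.append(
            LabeledSequence(
                specimen_id=fields["specimen_id"],
                species=fields["species"],
                residues=str(rec.seq),
                gene=fields.get("gene", ""),
                group=fields.get("group", ""),
                fragment_class=fields.get("fragment_class", ""),
            )
        )
    gene = sequences[0].gene
    return GeneAlignment(sequences, gene=gene)


def write_fasta(
    alignment: GeneAlignment, path: str | Path | io.TextIOBase, delimiter: str = "|"
) -> None:
    """Write an alignment back to multi-FASTA with metadata headers."""
    records = []
    for seq in alignment:
        header_fields = [seq.species, seq.specimen_id, seq.gene, seq.fragment_class]
        while header_fields and not header_fields[-1]:
            header_fields.pop()
        records.append(
            SeqRecord(Seq(seq.residues), id=delimiter.join(header_fields), description="")
        )
    SeqIO.write(records, path, "fasta")


def _covered_span(residues: str) -> tuple[int, int]:
    """Half-open column span excluding leading/trailing gap-or-N flanks.

    Internal gaps do not shrink the span: fragments are contiguous
    subregions of the full amplicon, not fragmented alignments.
    """
    flank = set("-N")
    start = 0
    end = len(residues)
    while start < end and residues[start] in flank:
        start += 1
    while end > start and residues[end - 1] in flank:
        end -= 1
    return start, end


def trim_to_overlap(alignment: GeneAlignment) -> GeneAlignment:
    """Restrict an alignment to the column range covered by every sequence.

    Each sequence covers the columns between its first and last non-gap,
    non-N residue; the output keeps the intersection of those spans (the
    shared overlap region of multi-fragment genes, e.g. the 342 bp region
    common to ~468 bp and ~342 bp 16S amplicons).  Sequence count and
    metadata are preserved.
    """
    start = 0
    end = alignment.length
    for seq in alignment:
        s, e = _covered_span(seq.residues)
        start = max(start, s)
        end = min(end, e)
    if start >= end:
        raise AlignmentError("no shared region: sequence spans are disjoint")
    trimmed = [replace(seq, residues=seq.residues[start:end]) for seq in alignment]
    return GeneAlignment(trimmed, gene=alignment.gene)


def write_newick(tree, path: str | Path | io.TextIOBase) -> None:
    """Serialize a tree to Newick (branch lengths to 6 dp, integer supports)."""
    text = tree.to_newick()
    if hasattr(path, "write"):
        path.write(text + "\n")
    else:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(text + "\n")


def read_newick(path: str | Path | io.TextIOBase):
    """Parse a Newick file into a :class:`barcodegap.njtree.PhyloTree`."""
    from .njtree import PhyloTree

    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    return PhyloTree.from_newick(text)
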