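"""Published sequence counts for the European cereal-aphid parasitoid library.

Per-species numbers of usable aligned sequences per gene in the reference
dataset of primary parasitoids (Aphidiinae, Aphelinidae) and hyperparasitoids
of European cereal aphids: newly generated specimens plus public GenBank
records.  For COI only the full-length (~658 bp) barcode fragments count —
the short ~339 bp amplicons carry too few diagnostic characters and were
deposited but not analysed.  For 16S the ~468 bp and ~342 bp amplicons both
count (they are reduced to their 342 bp overlap before analysis).

These counts drive denominator bookkeeping: a species with a single sequence
has no within-species distance, so it is excluded from the barcoding-gap
analysis but still contributes between-species distances to the
overall-cutoff analysis.
"""

from __future__ import annotations

_TSV = """\
species	group	COI	16S	18S
Aphelinus abdominalis	nonAphidiinae	7	4	2
Aphelinus asychis	nonAphidiinae	1	3	1
Aphelinus chaonia	nonAphidiinae	3	3	3
Aphelinus mali	nonAphidiinae	3	2	1
Aphelinus varipes	nonAphidiinae	6	3	1
Adialytus ambiguus	Aphidiinae	10	2	2
Aphidius avenae	Aphidiinae	7	2	4
Aphidius colemani	Aphidiinae	9	3	2
Aphidius ervi	Aphidiinae	13	7	3
Aphidius matricariae	Aphidiinae	6	5	3
Aphidius microlophii	Aphidiinae	7	2	3
Aphidius rhopalosiphi	Aphidiinae	21	5	5
Aphidius uzbekistanicus	Aphidiinae	5	2	2
Binodoxys angelicae	Aphidiinae	4	2	0
Diaeretiella rapae	Aphidiinae	14	9	3
Ephedrus persicae	Aphidiinae	3	3	2
Ephedrus plagiator	Aphidiinae	9	3	4
Lipolexis gracilis	Aphidiinae	3	3	2
Lysiphlebus fabarum	Aphidiinae	28	9	3
Lysiphlebus testaceipes	Aphidiinae	10	8	3
Monoctonus crepidis	Aphidiinae	6	2	2
Praon abjectum	Aphidiinae	5	2	1
Praon gallicum	Aphidiinae	5	2	2
Praon necans	Aphidiinae	2	3	4
Praon volucre	Aphidiinae	8	10	2
Toxares deltiger	Aphidiinae	1	1	1
Trioxys auctus	Aphidiinae	1	1	2
Trioxys sp. A	Aphidiinae	2	0	1
Syrphophagus aphidivorus	nonAphidiinae	3	0	2
Alloxysta brachyptera	nonAphidiinae	1	0	0
Alloxysta brevis	nonAphidiinae	2	1	2
Alloxysta fulviceps	nonAphidiinae	6	3	2
Alloxysta pedestris	nonAphidiinae	2	1	1
Alloxysta victrix	nonAphidiinae	6	4	4
Alloxysta sp. A	nonAphidiinae	1	1	1
Alloxysta sp. B	nonAphidiinae	1	0	0
Alloxysta sp. C	nonAphidiinae	0	1	0
Phaenoglyphis villosa	nonAphidiinae	6	4	3
Dendrocerus carpenteri	nonAphidiinae	3	4	2
Dendrocerus laticeps	nonAphidiinae	0	2	2
Asaphes suspensus	nonAphidiinae	2	5	4
Asaphes vulgaris	nonAphidiinae	7	4	3
Coruna clavata	nonAphidiinae	1	3	2
Pachyneuron aphidis	nonAphidiinae	6	3	4
Pachyneuron formosum	nonAphidiinae	0	1	0
Pachyneuron muscarum	nonAphidiinae	1	3	2
Pachyneuron solitarium	nonAphidiinae	1	2	3
"""

GENES = ("COI", "16S", "18S")
GROUPS = ("Aphidiinae", "nonAphidiinae")


def reference_counts() -> dict[str, dict]:
    """Parse the embedded table into ``{species: {"group": ..., gene: int}}``."""
    lines = _TSV.strip().split("\n")
    header = lines[0].split("\t")
    out: dict[str, dict] = {}
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        out[row["species"]] = {
            "group": row["group"],
            **{gene: int(row[gene]) for gene in GENES},
        }
    return out


def species_sizes(gene: str, group: str) -> dict[str, int]:
    """Sequence count per species for one gene within one group.

    Species without any sequence for the gene are omitted (they do not take
    part in any analysis of that marker).
    """
    if gene not in GENES:
        raise ValueError(f"unknown gene {gene!r}")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    return {
        sp: rec[gene]
        for sp, rec in reference_counts().items()
        if rec["group"] == group and rec[gene] > 0
    }
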