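"""Barcoding-gap and conservative-cutoff statistics over species pairs.

For a species pair, the "barcoding gap" holds when the smallest
between-species distance (Min-BSD) exceeds the largest within-species
distance (Max-WSD) of either species; pairs without a gap are difficult or
impossible to identify from the marker.  The largest Max-WSD across a whole
group (the *overall* Max-WSD) serves as a conservative identification
cutoff: any species pair whose Min-BSD falls below it risks
misidentification.

Singleton species (one sequence) have no within-species distance.  They are
excluded from the gap analysis but retained in the cutoff analysis, where
only their between-species distances matter.  Ties (Min-BSD equal to the
pair's Max-WSD) count as *no* gap — the conservative reading.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .distance import DistanceMatrix, encode, _MISSING

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesPairRecord:
    """Gap/cutoff verdicts for one unordered species pair.

    ``max_wsd_a``/``max_wsd_b`` are None for singleton species (absent
    within-species distance); ``has_gap`` is None when the pair-level
    Max-WSD is undefined (cutoff-only pairs).
    """

    species_a: str
    species_b: str
    min_bsd: float
    max_wsd_a: float | None
    max_wsd_b: float | None
    pair_max_wsd: float | None
    has_gap: bool | None
    below_overall_cutoff: bool | None = None

    def __post_init__(self):
        if self.species_a > self.species_b:
            raise ValueError("species must be in canonical (sorted) order")


@dataclass(frozen=True)
class GapSummary:
    """Group-level gap and cutoff percentages for one gene.

    The two analyses use different denominators: the gap analysis covers
    only pairs of species that both have a within-species distance
    (C(k, 2) for k non-singleton species), while the cutoff analysis covers
    all species pairs (C(m, 2) for m species).
    """

    gene: str
    group: str
    n_pairs_gap_analysis: int
    n_no_gap: int
    pct_no_gap: float
    overall_max_wsd: float
    n_pairs_cutoff_analysis: int
    n_below_cutoff: int
    pct_below_cutoff: float


def _species_ids(labels: Mapping[str, str]) -> dict[str, list[str]]:
    by_species: dict[str, list[str]] = {}
    for specimen, species in labels.items():
        by_species.setdefault(species, []).append(specimen)
    return by_species


def species_max_wsd(
    matrix: DistanceMatrix, labels: Mapping[str, str], species: str
) -> float | None:
    """Maximum defined within-species (conspecific) distance.

    Returns None for singleton species — no within-species distance exists —
    and, with a warning, when every conspecific pair is UNDEFINED.
    """
    by_species = _species_ids({i: labels[i] for i in matrix.ids})
    if species not in by_species:
        raise KeyError(f"species {species!r} not present in labels")
    members = by_species[species]
    if len(members) < 2:
        return None
    dists = [
        matrix.get(a, b) for a, b in combinations(members, 2)
    ]
    defined = [d for d in dists if not math.isnan(d)]
    if not defined:
        logger.warning(
            "species %s: all %d conspecific pairs UNDEFINED", species, len(dists)
        )
        return None
    return max(defined)


def pair_min_bsd(
    matrix: DistanceMatrix, labels: Mapping[str, str], a: str, b: str
) -> float:
    """Minimum defined between-species distance over all cross pairs."""
    by_species = _species_ids({i: labels[i] for i in matrix.ids})
    for sp in (a, b):
        if sp not in by_species:
            raise KeyError(f"species {sp!r} not present in labels")
    cross = matrix.pair_distances(by_species[a], by_species[b])
    defined = cross[~np.isnan(cross)]
    if defined.size == 0:
        raise ValueError(f"no defined between-species distance for {a!r} vs {b!r}")
    return float(defined.min())


def gap_table(
    matrix: DistanceMatrix, labels: Mapping[str, str]
) -> list[SpeciesPairRecord]:
    """Barcoding-gap verdict for every eligible species pair.

    Eligible pairs are those where both species have a defined Max-WSD
    (singletons and all-UNDEFINED species drop out).  The pair-level
    Max-WSD is the larger of the two species' maxima; the gap holds when
    Min-BSD strictly exceeds it.
    """
    wsd = {sp: species_max_wsd(matrix, labels, sp) for sp in set(labels.values())}
    eligible = sorted(sp for sp, w in wsd.items() if w is not None)
    if len(eligible) < 2:
        raise ValueError("fewer than 2 species with defined within-species distances")
    records = []
    for a, b in combinations(eligible, 2):
        min_bsd = pair_min_bsd(matrix, labels, a, b)
        pair_max = max(wsd[a], wsd[b])
        records.append(
            SpeciesPairRecord(
                species_a=a,
                species_b=b,
                min_bsd=min_bsd,
                max_wsd_a=wsd[a],
                max_wsd_b=wsd[b],
                pair_max_wsd=pair_max,
                has_gap=min_bsd > pair_max,
            )
        )
    return records


def overall_max_wsd(matrix: DistanceMatrix, labels: Mapping[str, str]) -> float:
    """Largest within-species distance across all species of the group."""
    maxima = [
        w
        for sp in set(labels.values())
        if (w := species_max_wsd(matrix, labels, sp)) is not None
    ]
    if not maxima:
        raise ValueError("all species are singletons: overall Max-WSD undefined")
    return max(maxima)


def cutoff_table(
    matrix: DistanceMatrix, labels: Mapping[str, str], cutoff: float
) -> list[SpeciesPairRecord]:
    """Flag species pairs whose Min-BSD falls strictly below a cutoff.

    All unordered species pairs take part, including pairs involving
    singletons (between-species distances exist regardless of sample size).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    wsd = {sp: species_max_wsd(matrix, labels, sp) for sp in set(labels.values())}
    records = []
    for a, b in combinations(sorted(wsd), 2):
        min_bsd = pair_min_bsd(matrix, labels, a, b)
        pair_max = (
            max(wsd[a], wsd[b])
            if wsd[a] is not None and wsd[b] is not None
            else None
        )
        records.append(
            SpeciesPairRecord(
                species_a=a,
                species_b=b,
                min_bsd=min_bsd,
                max_wsd_a=wsd[a],
                max_wsd_b=wsd[b],
                pair_max_wsd=pair_max,
                has_gap=(min_bsd > pair_max) if pair_max is not None else None,
                below_overall_cutoff=min_bsd < cutoff,
            )
        )
    return records


def identical_species_groups(alignment) -> list[list[str]]:
    """Species groups connected by character-identical sequences.

    Two sequences are identical when they agree at every site where both
    carry an unambiguous base (gap/N/ambiguity columns are ignored pair by
    pair, so fragments of different lengths can still match on their shared
    region; at least one comparable site is required).  Species are nodes,
    any identical cross-species sequence pair is an edge, and the connected
    components of size >= 2 are returned, each sorted, ordered by first
    member.
    """
    seqs = list(alignment)
    enc = [encode(s) for s in seqs]
    species = sorted({s.species for s in seqs})
    parent = {sp: sp for sp in species}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if seqs[i].species == seqs[j].species:
                continue
            valid = (enc[i] != _MISSING) & (enc[j] != _MISSING)
            if valid.any() and (enc[i][valid] == enc[j][valid]).all():
                ra, rb = find(seqs[i].species), find(seqs[j].species)
                if ra != rb:
                    parent[ra] = rb
    components: dict[str, list[str]] = {}
    for sp in species:
        components.setdefault(find(sp), []).append(sp)
    return sorted(
        (sorted(group) for group in components.values() if len(group) >= 2),
        key=lambda g: g[0],
    )


def gap_summary(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    gene: str = "",
    group: str = "",
) -> GapSummary:
    """Combined gap and overall-cutoff summary for one gene x group.

    The cutoff is the group's overall Max-WSD.  Percentages use the two
    analyses' own denominators (non-singleton pairs vs all pairs).
    """
    cutoff = overall_max_wsd(matrix, labels)
    gaps = gap_table(matrix, labels)
    cuts = cutoff_table(matrix, labels, cutoff)
    n_no_gap = sum(1 for r in gaps if not r.has_gap)
    n_below = sum(1 for r in cuts if r.below_overall_cutoff)
    return GapSummary(
        gene=gene,
        group=group,
        n_pairs_gap_analysis=len(gaps),
        n_no_gap=n_no_gap,
        pct_no_gap=100.0 * n_no_gap / len(gaps),
        overall_max_wsd=cutoff,
        n_pairs_cutoff_analysis=len(cuts),
        n_below_cutoff=n_below,
        pct_below_cutoff=100.0 * n_below / len(cuts) if cuts else 0.0,
    )


def pair_counts_from_species_sizes(sizes: Mapping[str, int]) -> tuple[int, int]:
    """Denominators implied by per-species sequence counts.

    Given ``{species: n_sequences}``, returns ``(n_pairs_gap_analysis,
    n_pairs_cutoff_analysis)``: C(k, 2) over the k species with >= 2
    sequences, and C(m, 2) over all m species with >= 1 sequence.
    """
    m = sum(1 for n in sizes.values() if n >= 1)
    k = sum(1 for n in sizes.values() if n >= 2)
    return k * (k - 1) // 2, m * (m - 1) // 2


def write_pair_table(records: Sequence[SpeciesPairRecord], path) -> None:
    """TSV export of species-pair records (also the Max-WSD/Min-BSD scatter)."""

    def fmt(x):
        if x is None:
            return "NA"
        if isinstance(x, bool):
            return str(x).lower()
        if isinstance(x, float):
            return f"{x:.8f}"
        return str(x)

    cols = [
        "species_a",
        "species_b",
        "min_bsd",
        "max_wsd_a",
        "max_wsd_b",
        "pair_max_wsd",
        "has_gap",
        "below_overall_cutoff",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            fh.write("\t".join(fmt(getattr(rec, c)) for c in cols) + "\n")
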