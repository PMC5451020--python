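"""Gap/cutoff statistics, checked against exhaustive brute-force oracles."""

import math
from itertools import combinations

import numpy as np
import pytest

from barcodegap.distance import k2p_matrix
from barcodegap.gapstats import (
    cutoff_table,
    gap_summary,
    gap_table,
    identical_species_groups,
    overall_max_wsd,
    pair_counts_from_species_sizes,
    pair_min_bsd,
    species_max_wsd,
)
from barcodegap.refcounts import species_sizes
from barcodegap.synthetic import SimulationConfig, simulate

from conftest import make_alignment, matrix_from_dict


# ---------------------------------------------------------------------------
# brute-force oracles, written from the definitions, independent of the package
# ---------------------------------------------------------------------------

def oracle_max_wsd(matrix, labels, species):
    members = [i for i in matrix.ids if labels[i] == species]
    dists = [
        matrix.get(a, b)
        for a, b in combinations(members, 2)
        if not math.isnan(matrix.get(a, b))
    ]
    return max(dists) if dists else None


def oracle_min_bsd(matrix, labels, a, b):
    dists = [
        matrix.get(x, y)
        for x in matrix.ids
        if labels[x] == a
        for y in matrix.ids
        if labels[y] == b
        if not math.isnan(matrix.get(x, y))
    ]
    return min(dists)


def oracle_gap_table(matrix, labels):
    species = sorted(set(labels.values()))
    out = {}
    for a, b in combinations(species, 2):
        wa, wb = oracle_max_wsd(matrix, labels, a), oracle_max_wsd(matrix, labels, b)
        if wa is None or wb is None:
            continue
        out[(a, b)] = oracle_min_bsd(matrix, labels, a, b) > max(wa, wb)
    return out


def oracle_cutoff_flags(matrix, labels, cutoff):
    species = sorted(set(labels.values()))
    return {
        (a, b): oracle_min_bsd(matrix, labels, a, b) < cutoff
        for a, b in combinations(species, 2)
    }


def oracle_identical_groups(alignment):
    seqs = list(alignment)
    species = sorted({s.species for s in seqs})
    adjacency = {sp: set() for sp in species}
    for x in seqs:
        for y in seqs:
            if x.species == y.species:
                continue
            pairs = [
                (p, q)
                for p, q in zip(x.residues, y.residues)
                if p in "ACGT" and q in "ACGT"
            ]
            if pairs and all(p == q for p, q in pairs):
                adjacency[x.species].add(y.species)
                adjacency[y.species].add(x.species)
    seen, groups = set(), []
    for sp in species:
        if sp in seen:
            continue
        stack, comp = [sp], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adjacency[cur])
        seen |= comp
        if len(comp) >= 2:
            groups.append(sorted(comp))
    return sorted(groups)


def random_dataset(seed):
    rng = np.random.default_rng(seed)
    n_species = int(rng.integers(2, 9))
    sizes = rng.integers(1, 6, size=n_species).tolist()
    while sum(1 for s in sizes if s >= 2) < 2:  # gap analysis needs 2 eligible
        sizes = rng.integers(1, 6, size=n_species).tolist()
    config = SimulationConfig(
        n_species=n_species,
        seqs_per_species=sizes,
        seq_length=120,
        inter_divergence=float(rng.uniform(0.02, 0.3)),
        intra_divergence=float(rng.uniform(0.0, 0.05)),
        seed=int(rng.integers(0, 2**31)),
    )
    return simulate(config).alignment


class TestSpeciesMaxWsd:
    def test_max_of_set(self):
        m = matrix_from_dict(
            ["a1", "a2", "a3"],
            {("a1", "a2"): 0.0, ("a1", "a3"): 0.02, ("a2", "a3"): 0.03},
        )
        labels = {i: "A" for i in m.ids}
        assert species_max_wsd(m, labels, "A") == 0.03

    def test_singleton_absent(self):
        m = matrix_from_dict(["a1", "b1"], {("a1", "b1"): 0.1})
        assert species_max_wsd(m, {"a1": "A", "b1": "B"}, "A") is None

    def test_all_undefined_absent_with_warning(self, caplog):
        m = matrix_from_dict(["a1", "a2"], {("a1", "a2"): float("nan")})
        with caplog.at_level("WARNING"):
            assert species_max_wsd(m, {"a1": "A", "a2": "A"}, "A") is None
        assert "UNDEFINED" in caplog.text

    def test_unknown_species_errors(self):
        m = matrix_from_dict(["a1", "a2"], {("a1", "a2"): 0.0})
        with pytest.raises(KeyError):
            species_max_wsd(m, {"a1": "A", "a2": "A"}, "Z")


class TestPairMinBsd:
    def test_min_of_cross_distances(self):
        m = matrix_from_dict(
            ["a1", "a2", "b1"],
            {("a1", "b1"): 0.05, ("a2", "b1"): 0.02, ("a1", "a2"): 0.09},
        )
        labels = {"a1": "A", "a2": "A", "b1": "B"}
        assert pair_min_bsd(m, labels, "A", "B") == 0.02

    def test_shared_identical_sequence_gives_zero(self):
        aln = make_alignment([("a1", "A", "ACGT"), ("b1", "B", "ACGT")])
        m = k2p_matrix(aln)
        assert pair_min_bsd(m, aln.species_map(), "A", "B") == 0.0


class TestGapTable:
    def test_clear_gap(self):
        m = matrix_from_dict(
            ["a1", "a2", "b1", "b2"],
            {
                ("a1", "a2"): 0.01,
                ("b1", "b2"): 0.01,
                ("a1", "b1"): 0.10,
                ("a1", "b2"): 0.12,
                ("a2", "b1"): 0.11,
                ("a2", "b2"): 0.13,
            },
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        records = gap_table(m, labels)
        assert len(records) == 1
        assert records[0].has_gap is True
        assert records[0].pair_max_wsd == 0.01

    def test_overlapping_species_lack_gap(self):
        # one species' within-distance (0.09) exceeds the pair Min-BSD (0.04)
        m = matrix_from_dict(
            ["a1", "a2", "b1", "b2"],
            {
                ("a1", "a2"): 0.09,
                ("b1", "b2"): 0.01,
                ("a1", "b1"): 0.04,
                ("a1", "b2"): 0.20,
                ("a2", "b1"): 0.21,
                ("a2", "b2"): 0.22,
            },
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert gap_table(m, labels)[0].has_gap is False

    def test_tie_counts_as_no_gap(self):
        m = matrix_from_dict(
            ["a1", "a2", "b1", "b2"],
            {
                ("a1", "a2"): 0.05,
                ("b1", "b2"): 0.01,
                ("a1", "b1"): 0.05,
                ("a1", "b2"): 0.2,
                ("a2", "b1"): 0.2,
                ("a2", "b2"): 0.2,
            },
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert gap_table(m, labels)[0].has_gap is False

    def test_singletons_excluded(self):
        m = matrix_from_dict(
            ["a1", "a2", "b1", "b2", "c1"],
            {
                ("a1", "a2"): 0.01,
                ("b1", "b2"): 0.01,
                ("a1", "b1"): 0.1,
                ("a1", "b2"): 0.1,
                ("a2", "b1"): 0.1,
                ("a2", "b2"): 0.1,
                ("a1", "c1"): 0.1,
                ("a2", "c1"): 0.1,
                ("b1", "c1"): 0.1,
                ("b2", "c1"): 0.1,
            },
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        records = gap_table(m, labels)
        assert {(r.species_a, r.species_b) for r in records} == {("A", "B")}


class TestOverallMaxWsdAndCutoff:
    def test_max_of_maxima(self):
        ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
        m = matrix_from_dict(
            ids,
            {
                ("a1", "a2"): 0.02,
                ("b1", "b2"): 0.17,
                ("c1", "c2"): 0.05,
                **{
                    (x, y): 0.3
                    for x, y in combinations(ids, 2)
                    if x[0] != y[0]
                },
            },
        )
        labels = {i: i[0].upper() for i in ids}
        assert overall_max_wsd(m, labels) == 0.17

    def test_all_singletons_error(self):
        m = matrix_from_dict(["a1", "b1"], {("a1", "b1"): 0.2})
        with pytest.raises(ValueError):
            overall_max_wsd(m, {"a1": "A", "b1": "B"})

    def test_cutoff_zero_flags_nothing(self):
        m = matrix_from_dict(["a1", "b1"], {("a1", "b1"): 0.1})
        records = cutoff_table(m, {"a1": "A", "b1": "B"}, 0.0)
        assert not any(r.below_overall_cutoff for r in records)

    def test_constructed_min_bsds(self):
        # species D distant from everyone; A-B close, A-C/B-C moderate
        m = matrix_from_dict(
            ["a1", "b1", "c1"],
            {("a1", "b1"): 0.01, ("a1", "c1"): 0.20, ("b1", "c1"): 0.30},
        )
        records = cutoff_table(m, {"a1": "A", "b1": "B", "c1": "C"}, 0.17)
        flagged = [(r.species_a, r.species_b) for r in records if r.below_overall_cutoff]
        assert flagged == [("A", "B")]

    def test_singletons_included_in_cutoff_analysis(self):
        m = matrix_from_dict(
            ["a1", "a2", "b1"],
            {("a1", "a2"): 0.01, ("a1", "b1"): 0.05, ("a2", "b1"): 0.06},
        )
        records = cutoff_table(m, {"a1": "A", "a2": "A", "b1": "B"}, 0.1)
        assert len(records) == 1  # pair (A, B) present despite B singleton
        assert records[0].below_overall_cutoff is True
        assert records[0].max_wsd_b is None


class TestIdenticalSpeciesGroups:
    def test_shared_haplotype(self):
        aln = make_alignment(
            [("a1", "A", "ACGTACGT"), ("b1", "B", "ACGTACGT"), ("c1", "C", "ACGAACGA")]
        )
        assert identical_species_groups(aln) == [["A", "B"]]

    def test_two_haplotype_groups(self):
        # five species share one haplotype, two share another
        h1, h2 = "ACGT" * 5, "TGCA" * 5
        rows = [(f"s{i}", f"sp{i}", h1) for i in range(5)]
        rows += [(f"t{i}", f"tp{i}", h2) for i in range(2)]
        rows += [("u1", "up1", "AAAA" * 5)]
        groups = identical_species_groups(make_alignment(rows))
        assert groups == [
            [f"sp{i}" for i in range(5)],
            [f"tp{i}" for i in range(2)],
        ]

    def test_all_distinct_empty(self):
        aln = make_alignment([("a1", "A", "ACGT"), ("b1", "B", "ACGA")])
        assert identical_species_groups(aln) == []

    def test_identity_ignores_gap_and_n_columns(self):
        # fragment matches full-length sequence on its covered region
        aln = make_alignment(
            [("a1", "A", "ACGTACGT"), ("b1", "B", "--GTACGT"), ("c1", "C", "NNNNNNNN")]
        )
        groups = identical_species_groups(aln)
        assert ["A", "B"] in groups
        assert all("C" not in g for g in groups)  # no comparable sites -> no edge


class TestGapSummary:
    def test_denominators_with_singleton(self):
        data = simulate(
            SimulationConfig(
                n_species=4,
                seqs_per_species=[3, 3, 3, 1],
                seq_length=400,
                inter_divergence=0.2,
                intra_divergence=0.01,
                seed=9,
            )
        )
        m = k2p_matrix(data.alignment)
        labels = data.alignment.species_map()
        summary = gap_summary(m, labels)
        assert summary.n_pairs_gap_analysis == 3  # C(3,2)
        assert summary.n_pairs_cutoff_analysis == 6  # C(4,2)

    def test_well_separated_species_have_no_failures(self):
        data = simulate(
            SimulationConfig(
                n_species=5,
                seqs_per_species=3,
                seq_length=2000,
                inter_divergence=0.3,
                intra_divergence=0.005,
                seed=21,
            )
        )
        m = k2p_matrix(data.alignment)
        summary = gap_summary(m, data.alignment.species_map())
        assert summary.pct_no_gap == 0.0
        assert summary.pct_below_cutoff == 0.0


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracles(self, seed):
        aln = random_dataset(seed)
        m = k2p_matrix(aln)
        labels = aln.species_map()

        records = gap_table(m, labels)
        expected = oracle_gap_table(m, labels)
        assert {(r.species_a, r.species_b): r.has_gap for r in records} == expected

        species = sorted(set(labels.values()))
        maxima = [w for sp in species if (w := oracle_max_wsd(m, labels, sp)) is not None]
        if maxima:
            cutoff = max(maxima)
            assert overall_max_wsd(m, labels) == cutoff
            flags = {
                (r.species_a, r.species_b): r.below_overall_cutoff
                for r in cutoff_table(m, labels, cutoff)
            }
            assert flags == oracle_cutoff_flags(m, labels, cutoff)

        assert identical_species_groups(aln) == oracle_identical_groups(aln)


class TestMonotonicity:
    def test_raising_cutoff_never_decreases_flags(self):
        aln = random_dataset(101)
        m = k2p_matrix(aln)
        labels = aln.species_map()
        counts = [
            sum(r.below_overall_cutoff for r in cutoff_table(m, labels, c))
            for c in (0.0, 0.05, 0.1, 0.2, 0.4, 1.0)
        ]
        assert counts == sorted(counts)


class TestPairCounts:
    def test_denominator_law(self):
        sizes = {"A": 5, "B": 1, "C": 2, "D": 3, "E": 1}
        gap_pairs, cutoff_pairs = pair_counts_from_species_sizes(sizes)
        assert gap_pairs == 3  # C(3,2): A, C, D
        assert cutoff_pairs == 10  # C(5,2)

    @pytest.mark.parametrize(
        "gene, group, expected_gap_pairs",
        [
            ("COI", "nonAphidiinae", 91),
            ("16S", "nonAphidiinae", 120),
            ("COI", "Aphidiinae", 210),
            ("16S", "Aphidiinae", 190),
            ("18S", "nonAphidiinae", 105),
        ],
    )
    def test_reference_library_pair_counts(self, gene, group, expected_gap_pairs):
        """The published per-species sequence counts reproduce the reported
        numbers of species pairs entering the gap analysis."""
        gap_pairs, _ = pair_counts_from_species_sizes(species_sizes(gene, group))
        assert gap_pairs == expected_gap_pairs

    def test_16s_nonaphidiinae_cutoff_denominator(self):
        # 21 species carry 16S data -> C(21,2) = 210 pairs in the cutoff analysis
        _, cutoff_pairs = pair_counts_from_species_sizes(
            species_sizes("16S", "nonAphidiinae")
        )
        assert cutoff_pairs == 210
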