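"""Kimura two-parameter (K2P) pairwise distances and distance summaries.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the observed proportions of transition- and
transversion-differing sites among the n compared sites, the distance in
expected substitutions per site is

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Sites where either sequence carries a gap, N or an ambiguity code are
excluded pair by pair (pairwise deletion, the default) or globally
(complete deletion).  When the logarithm argument is non-positive
(substitution saturation) or no sites remain, the distance is UNDEFINED and
propagates as such — saturation is diagnostic information, never clamped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for distances the K2P formula cannot produce (saturation or no
#: overlapping sites).  NaN so it propagates through numpy matrices; test
#: with :func:`is_undefined`.
UNDEFINED = math.nan

# uint8 codes: A=0, C=1, G=2, T=3 (purines even, pyrimidines odd), missing=255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_MISSING = np.uint8(255)


def is_undefined(value: float) -> bool:
    """True when a distance is the UNDEFINED sentinel."""
    return isinstance(value, float) and math.isnan(value)


def _residues(seq) -> str:
    return getattr(seq, "residues", seq)


def encode(seq) -> np.ndarray:
    """Encode residues as uint8 (A=0, C=1, G=2, T=3; everything else missing)."""
    raw = np.frombuffer(_residues(seq).encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def count_site_patterns(a, b) -> tuple[int, float, float]:
    """Count compared sites and transition/transversion proportions.

    Returns ``(n, P, Q)`` where n is the number of sites at which both
    sequences carry an unambiguous base, P the proportion of those sites
    differing by a transition and Q by a transversion.  ``n == 0`` yields
    ``(0, 0.0, 0.0)`` — the downstream distance is then UNDEFINED.
    """
    ea, eb = encode(a), encode(b)
    if ea.shape != eb.shape:
        raise ValueError("sequences must be aligned to equal length")
    return _patterns_encoded(ea, eb)


def _patterns_encoded(ea: np.ndarray, eb: np.ndarray) -> tuple[int, float, float]:
    valid = (ea != _MISSING) & (eb != _MISSING)
    n = int(valid.sum())
    if n == 0:
        return 0, 0.0, 0.0
    diff = valid & (ea != eb)
    # same parity = both purines or both pyrimidines = transition
    transitions = int((diff & ((ea & 1) == (eb & 1))).sum())
    transversions = int(diff.sum()) - transitions
    return n, transitions / n, transversions / n


def k2p_from_proportions(P: float, Q: float) -> float:
    """K2P distance from transition/transversion proportions.

    UNDEFINED when ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return UNDEFINED
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p(a, b) -> float:
    """K2P distance between two aligned sequences (UNDEFINED on saturation)."""
    n, P, Q = count_site_patterns(a, b)
    if n == 0:
        return UNDEFINED
    return k2p_from_proportions(P, Q)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix keyed by specimen ID.

    ``values[i, j]`` is in expected substitutions/site; UNDEFINED entries are
    NaN.  ``site_counts[i, j]`` is the number of sites compared for the pair.
    """

    ids: list[str]
    values: np.ndarray
    site_counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n) or self.site_counts.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids")
        self._index = {name: i for i, name in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def sites(self, a: str, b: str) -> int:
        return int(self.site_counts[self._index[a], self._index[b]])

    def n_undefined(self) -> int:
        """Number of UNDEFINED unordered pairs."""
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def pair_distances(self, ids_a: Iterable[str], ids_b: Iterable[str]) -> np.ndarray:
        """All distances between two id sets (cross pairs, defined or not)."""
        ia = [self._index[x] for x in ids_a]
        ib = [self._index[x] for x in ids_b]
        return self.values[np.ix_(ia, ib)].ravel()

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        keep = [self._index[x] for x in ids]
        return DistanceMatrix(
            [self.ids[i] for i in keep],
            self.values[np.ix_(keep, keep)].copy(),
            self.site_counts[np.ix_(keep, keep)].copy(),
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        """Square TSV with ids as header row and column; UNDEFINED as 'NA'."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                cells = [
                    "NA" if math.isnan(v) else f"{v:.8f}" for v in self.values[i]
                ]
                fh.write(name + "\t" + "\t".join(cells) + "\n")

    def write_phylip(self, path: str | Path) -> None:
        """PHYLIP square format (names truncated/padded to 10 characters)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                cells = [
                    "NA" if math.isnan(v) else f"{v:.6f}" for v in self.values[i]
                ]
                fh.write(f"{name[:10]:<10}" + "  ".join(cells) + "\n")


def k2p_matrix(alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs K2P distance matrix for an alignment.

    Parameters
    ----------
    alignment:
        A :class:`barcodegap.seqio.GeneAlignment` (or any iterable of
        objects with ``specimen_id`` and ``residues``).
    deletion:
        ``"pairwise"`` drops gap/N/ambiguity sites per pair;
        ``"complete"`` drops every column containing any such character in
        any sequence before computing distances.
    """
    seqs = list(alignment)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    ids = [s.specimen_id for s in seqs]
    enc = np.stack([encode(s) for s in seqs])
    if deletion == "complete":
        enc = enc[:, (enc != _MISSING).all(axis=0)]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    m = len(seqs)
    values = np.zeros((m, m))
    counts = np.zeros((m, m), dtype=int)
    np.fill_diagonal(counts, enc.shape[1])
    for i in range(m):
        counts[i, i] = int((enc[i] != _MISSING).sum())
        for j in range(i + 1, m):
            n, P, Q = _patterns_encoded(enc[i], enc[j])
            d = UNDEFINED if n == 0 else k2p_from_proportions(P, Q)
            values[i, j] = values[j, i] = d
            counts[i, j] = counts[j, i] = n
    return DistanceMatrix(ids, values, counts)


@dataclass(frozen=True)
class DistanceSummary:
    """Range, mean and standard error of a set of pairwise distances."""

    scope: str  # "within_species" | "between_species"
    min: float
    max: float
    mean: float
    se: float
    n_pairs: int
    n_undefined: int = 0
    gene: str = ""
    group: str = ""


def _scope_pairs(
    matrix: DistanceMatrix, labels: Mapping[str, str], scope: str
) -> tuple[list[float], int]:
    want_same = {"within_species": True, "between_species": False}[scope]
    dists: list[float] = []
    n_undef = 0
    ids = matrix.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if (labels[ids[i]] == labels[ids[j]]) != want_same:
                continue
            d = matrix.values[i, j]
            if math.isnan(d):
                n_undef += 1
            else:
                dists.append(float(d))
    return dists, n_undef


def summarize_distances(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    scope: str,
    gene: str = "",
    group: str = "",
) -> DistanceSummary:
    """Summarize conspecific or heterospecific pairwise distances.

    ``se`` is the standard error of the mean over the pairwise distances
    (sample SD / sqrt(n)); pairwise distances are not independent, so this
    is descriptive rather than inferential.  UNDEFINED pairs are excluded
    and counted.
    """
    missing = [i for i in matrix.ids if i not in labels]
    if missing:
        raise KeyError(f"labels missing for ids: {missing[:5]}")
    dists, n_undef = _scope_pairs(matrix, labels, scope)
    if n_undef:
        logger.warning("%d UNDEFINED pairs excluded from %s summary", n_undef, scope)
    if not dists:
        raise ValueError(f"empty scope: no defined {scope} pairs")
    arr = np.asarray(dists)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return DistanceSummary(
        scope=scope,
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        se=se,
        n_pairs=len(arr),
        n_undefined=n_undef,
        gene=gene,
        group=group,
    )
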