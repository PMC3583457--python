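"""Single-linkage homologous protein families.

A family is a connected component of the pairwise homology graph under a
named threshold regime: any protein homologous to at least one member joins
the family (transitive expansion).  Two regimes come from the survey design:
``synteny`` (40% similarity) for neighborhood analysis and ``content``
(50% similarity) for the whole-genome screen, both with <20% length
difference.

Family ids are deterministic: the lexicographically smallest member id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .align import AlignParams, DEFAULT_PARAMS, align_sequences, global_score
from .homology import HomologyEdge, length_diff_fraction, pair_chance_pvalue
from .records import ProteinRecord


@dataclass(frozen=True)
class ThresholdRegime:
    """Named (similarity %, length-difference fraction) threshold pair."""

    name: str
    sim_threshold: float
    len_threshold: float
    statistic: str = "similarity"

    def __post_init__(self) -> None:
        if self.sim_threshold <= 0 or self.len_threshold <= 0:
            raise ValueError("thresholds must be positive")


SYNTENY_REGIME = ThresholdRegime("synteny", 40.0, 0.20)
CONTENT_REGIME = ThresholdRegime("content", 50.0, 0.20)


@dataclass(frozen=True)
class ProteinFamily:
    family_id: str
    members: frozenset
    regime: ThresholdRegime

    def __len__(self) -> int:
        return len(self.members)


class _UnionFind:
    """Union-find with path compression over a fixed key set."""

    def __init__(self, keys: Sequence[str]):
        self.parent: Dict[str, str] = {k: k for k in keys}

    def find(self, k: str) -> str:
        root = k
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[k] != root:
            self.parent[k], k = root, self.parent[k]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


#: pairwise table: (id_a, id_b) sorted ->
#: (pct_similarity, pct_identity, len_frac, chance_pvalue)
SimilarityTable = Dict[Tuple[str, str], Tuple[float, float, float, float]]


def compute_similarity_table(
    proteins: Sequence[ProteinRecord],
    max_len_threshold: float = 0.20,
    params: AlignParams = DEFAULT_PARAMS,
    gate_sim_floor: float = 40.0,
    gate_shuffles: int = 25,
) -> SimilarityTable:
    """All-vs-all alignment statistics for pairs that could pass a regime.

    Pairs whose length difference is >= ``max_len_threshold`` are skipped
    without aligning — the predicate rejects them under any regime with
    ``len_threshold <= max_len_threshold``, so the skip is result-identical.
    The chance-gate p-value (see :func:`~rebscan.homology.pair_chance_pvalue`)
    is computed only for pairs whose similarity reaches ``gate_sim_floor``
    (others get the sentinel 1.0 — they cannot become edges under regimes
    with ``sim_threshold >= gate_sim_floor``).  The table can be shared
    across such regimes; thresholds are applied later.
    """
    ordered = sorted(proteins, key=lambda r: r.protein_id)
    # sort by length so the length prefilter scans a narrow band
    by_length = sorted(ordered, key=lambda r: (len(r), r.protein_id))
    table: SimilarityTable = {}
    n = len(by_length)
    for i in range(n):
        a = by_length[i]
        for j in range(i + 1, n):
            b = by_length[j]
            ldf = length_diff_fraction(len(a), len(b))
            if not ldf < max_len_threshold:
                break  # all later proteins are even longer
            key = (min(a.protein_id, b.protein_id), max(a.protein_id, b.protein_id))
            # score <= 0: no evidence of homology (mirrors is_homologous);
            # score-only is several-fold cheaper than a traceback alignment
            if global_score(a.sequence, b.sequence, params) <= 0:
                table[key] = (0.0, 0.0, ldf, 1.0)
                continue
            result = align_sequences(
                a.sequence, b.sequence, params=params,
                ids=(a.protein_id, b.protein_id),
            )
            chance_p = 1.0
            if result.percent_similarity >= gate_sim_floor:
                chance_p = pair_chance_pvalue(
                    a.sequence, b.sequence, result.raw_score,
                    params=params, n_shuffles=gate_shuffles,
                )
            table[key] = (
                result.percent_similarity,
                result.percent_identity,
                ldf,
                chance_p,
            )
    return table


def edges_under_regime(
    table: SimilarityTable,
    regime: ThresholdRegime,
    gate_pvalue: Optional[float] = 1e-3,
) -> List[HomologyEdge]:
    """Homology edges a similarity table supports under a regime."""
    edges = []
    for (ida, idb), (sim, ident, ldf, chance_p) in sorted(table.items()):
        value = sim if regime.statistic == "similarity" else ident
        if value >= regime.sim_threshold and ldf < regime.len_threshold:
            if gate_pvalue is not None and chance_p > gate_pvalue:
                continue
            edges.append(
                HomologyEdge(
                    pair=(ida, idb),
                    percent_similarity=sim,
                    percent_identity=ident,
                    length_diff_fraction=ldf,
                )
            )
    return edges


def build_families(
    proteins: Sequence[ProteinRecord],
    regime: ThresholdRegime,
    params: AlignParams = DEFAULT_PARAMS,
    table: Optional[SimilarityTable] = None,
    gate_pvalue: Optional[float] = 1e-3,
) -> List[ProteinFamily]:
    """Connected components of the homology graph under ``regime``.

    A precomputed :func:`compute_similarity_table` may be passed to share the
    O(n^2) alignment cost across regimes; it must have been computed with
    ``max_len_threshold >= regime.len_threshold`` and a gate floor at or
    below ``regime.sim_threshold``.
    Singletons are families of size 1.  Output is sorted by family id.
    """
    if not proteins:
        raise ValueError("protein set is empty")
    if table is None:
        table = compute_similarity_table(
            proteins, max_len_threshold=regime.len_threshold, params=params,
            gate_sim_floor=min(40.0, regime.sim_threshold),
        )
    ids = sorted(r.protein_id for r in proteins)
    uf = _UnionFind(ids)
    for edge in edges_under_regime(table, regime, gate_pvalue=gate_pvalue):
        uf.union(*edge.pair)
    groups: Dict[str, List[str]] = {}
    for pid in ids:
        groups.setdefault(uf.find(pid), []).append(pid)
    families = [
        ProteinFamily(family_id=min(members), members=frozenset(members),
                      regime=regime)
        for members in groups.values()
    ]
    return sorted(families, key=lambda f: f.family_id)


def family_of(protein_id: str, families: Sequence[ProteinFamily]) -> str:
    """Family id containing a protein; KeyError if unknown."""
    for family in families:
        if protein_id in family.members:
            return family.family_id
    raise KeyError(f"protein {protein_id!r} not found in any family")


def membership_map(families: Sequence[ProteinFamily]) -> Dict[str, str]:
    """protein_id -> family_id over a family list."""
    out: Dict[str, str] = {}
    for family in families:
        for pid in family.members:
            out[pid] = family.family_id
    return out


def families_table(
    families: Sequence[ProteinFamily], taxon_of: Mapping[str, str]
) -> pd.DataFrame:
    """Flat TSV-ready table: family_id, protein_id, taxon_id, regime."""
    rows = [
        {
            "family_id": fam.family_id,
            "protein_id": pid,
            "taxon_id": taxon_of.get(pid, ""),
            "regime": fam.regime.name,
        }
        for fam in families
        for pid in sorted(fam.members)
    ]
    return pd.DataFrame(rows, columns=["family_id", "protein_id", "taxon_id", "regime"])
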