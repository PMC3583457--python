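"""*reb* locus calling, ±k-ORF windows, and conserved neighborhood patterns.

*reb* genes cluster on the genome, usually side-by-side or separated by a few
intervening genes; a locus is a maximal run of reb genes on one replicon with
at most ``max_gap`` intervening non-reb genes.  Around each locus the k ORFs
immediately upstream and downstream (ordinal gene index, not nucleotide
distance; strand recorded but ignored) form its synteny window.  Conserved
patterns are groups of homologous families that (1) recur in windows of at
least ``min_taxa`` distinct taxa, (2) are genome-wide exclusive to
Reb-harboring taxa, and (3) co-occur with each other in enough shared taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import networkx as nx

from .families import ProteinFamily, membership_map
from .records import ProteinRecord, Proteome


@dataclass(frozen=True)
class RebLocus:
    """A maximal run of reb genes on one replicon."""

    taxon_id: str
    replicon_id: str
    member_reb_ids: Tuple[str, ...]   # ordered by ordinal index
    index_span: Tuple[int, int]       # (min index, max index), inclusive

    def __len__(self) -> int:
        return len(self.member_reb_ids)


@dataclass(frozen=True)
class SyntenyWindow:
    """The ordered ±k-ORF neighborhood around one reb locus.

    ``upstream`` lists the k nearest non-reb genes with indices below the
    locus span in ascending index order; ``downstream`` the k nearest above,
    ascending.  ``truncated`` marks windows cut short by a replicon end.
    """

    locus: RebLocus
    upstream: Tuple[str, ...]
    downstream: Tuple[str, ...]
    truncated: bool = False


@dataclass(frozen=True)
class SyntenyPattern:
    """A co-occurring set of window families exclusive to Reb-harboring taxa."""

    pattern_id: str
    family_ids: frozenset
    supporting_taxa: frozenset
    adjacency_profile: Mapping[str, Tuple[str, ...]]  # taxon -> ordered labels


def call_reb_loci(
    proteome: Proteome, reb_ids: Set[str], max_gap: int = 3
) -> List[RebLocus]:
    """Group a proteome's reb genes into loci.

    Per replicon, reb genes whose ordinal indices are separated by at most
    ``max_gap`` intervening genes belong to one locus.  Empty ``reb_ids``
    yields an empty list.  Loci are sorted by (replicon, index).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    unknown = {rid for rid in reb_ids if rid in proteome}
    loci: List[RebLocus] = []
    for replicon in proteome.replicons:
        rebs = [r for r in proteome.replicon_records(replicon)
                if r.protein_id in reb_ids]
        if not rebs:
            continue
        run: List[ProteinRecord] = [rebs[0]]
        for rec in rebs[1:]:
            if rec.index - run[-1].index - 1 <= max_gap:
                run.append(rec)
            else:
                loci.append(_locus_from_run(proteome.taxon_id, replicon, run))
                run = [rec]
        loci.append(_locus_from_run(proteome.taxon_id, replicon, run))
    return sorted(loci, key=lambda l: (l.replicon_id, l.index_span[0]))


def _locus_from_run(taxon_id: str, replicon: str,
                    run: Sequence[ProteinRecord]) -> RebLocus:
    return RebLocus(
        taxon_id=taxon_id,
        replicon_id=replicon,
        member_reb_ids=tuple(r.protein_id for r in run),
        index_span=(run[0].index, run[-1].index),
    )


def extract_window(
    locus: RebLocus,
    proteome: Proteome,
    k: int = 5,
    reb_ids: Set[str] = frozenset(),
) -> SyntenyWindow:
    """The k nearest non-reb genes on each side of a locus.

    Counting starts immediately outside the locus span; reb genes from other
    loci falling inside the window range are passed over without being
    counted (windows never contain reb genes).  Truncation at replicon ends
    is recorded, not an error.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    records = proteome.replicon_records(locus.replicon_id)
    lo, hi = locus.index_span
    below = [r for r in records if r.index < lo and r.protein_id not in reb_ids]
    above = [r for r in records if r.index > hi and r.protein_id not in reb_ids]
    upstream = below[-k:] if k else []
    downstream = above[:k] if k else []
    truncated = len(upstream) < k or len(downstream) < k
    return SyntenyWindow(
        locus=locus,
        upstream=tuple(r.protein_id for r in upstream),
        downstream=tuple(r.protein_id for r in downstream),
        truncated=truncated,
    )


def detect_patterns(
    windows: Sequence[SyntenyWindow],
    families: Sequence[ProteinFamily],
    reb_taxa: Set[str],
    all_taxa: Set[str],
    taxon_of: Mapping[str, str],
    min_taxa: int = 3,
) -> List[SyntenyPattern]:
    """Conserved cross-taxon neighborhood patterns around reb loci.

    1. every window gene is mapped to its (synteny-regime) family;
    2. candidate families are those seen in windows of >= ``min_taxa``
       distinct taxa;
    3. candidates with any member in a non-Reb-harboring taxon — checked
       genome-wide via the full family membership, not just windows — are
       dropped;
    4. retained families are grouped into patterns: two families join one
       pattern iff their windows share >= ``min_taxa`` taxa (connected
       components of that co-occurrence graph).

    Patterns report their supporting taxa and, per taxon, the ordered family
    labels of its window (upstream, ``REB``, downstream).
    """
    if min_taxa < 2:
        raise ValueError("min_taxa must be >= 2 (a pattern needs recurrence)")
    fam_of = membership_map(families)
    taxa_in_windows: Dict[str, Set[str]] = {}
    for window in windows:
        taxon = window.locus.taxon_id
        for pid in window.upstream + window.downstream:
            fam = fam_of.get(pid)
            if fam is not None:
                taxa_in_windows.setdefault(fam, set()).add(taxon)
    candidates = {
        fam for fam, taxa in taxa_in_windows.items() if len(taxa) >= min_taxa
    }
    nonreb = all_taxa - reb_taxa
    retained = set()
    fam_members: Dict[str, Set[str]] = {f.family_id: set(f.members)
                                        for f in families}
    for fam in candidates:
        member_taxa = {taxon_of[pid] for pid in fam_members[fam]
                       if pid in taxon_of}
        if not member_taxa & nonreb:
            retained.add(fam)
    graph = nx.Graph()
    graph.add_nodes_from(retained)
    retained_sorted = sorted(retained)
    for i, fa in enumerate(retained_sorted):
        for fb in retained_sorted[i + 1:]:
            shared = taxa_in_windows[fa] & taxa_in_windows[fb]
            if len(shared) >= min_taxa:
                graph.add_edge(fa, fb)
    patterns: List[SyntenyPattern] = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    for component in components:
        supporting = set()
        for fam in component:
            supporting |= taxa_in_windows[fam]
        profile: Dict[str, Tuple[str, ...]] = {}
        for window in windows:
            taxon = window.locus.taxon_id
            if taxon not in supporting:
                continue
            labels = (
                tuple(fam_of.get(pid, pid) for pid in window.upstream)
                + ("REB",) * len(window.locus.member_reb_ids)
                + tuple(fam_of.get(pid, pid) for pid in window.downstream)
            )
            # one profile row per taxon; multiple loci concatenate in order
            profile[taxon] = profile.get(taxon, ()) + labels
        patterns.append(
            SyntenyPattern(
                pattern_id="",  # assigned below once ordering is known
                family_ids=frozenset(component),
                supporting_taxa=frozenset(supporting),
                adjacency_profile=profile,
            )
        )
    patterns.sort(key=lambda p: (-len(p.supporting_taxa), min(p.family_ids)))
    return [
        SyntenyPattern(
            pattern_id=f"P{i + 1}",
            family_ids=p.family_ids,
            supporting_taxa=p.supporting_taxa,
            adjacency_profile=p.adjacency_profile,
        )
        for i, p in enumerate(patterns)
    ]
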