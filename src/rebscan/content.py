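"""Whole-genome phyletic profiles and the Reb-exclusivity screen.

The presence/absence matrix records, for every homologous family (content
regime) and every taxon, whether at least one family member is annotated in
that taxon.  A family is *exclusive* when it is present in at least
``min_reb_taxa`` Reb-harboring taxa and in zero others; families with one or
two non-Reb presences are reported as near-misses (distant homologs falling
just outside the exclusive subfamilies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .families import ProteinFamily
from .records import ProteinRecord


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Families x taxa boolean phyletic profile.

    ``data`` is a pandas DataFrame indexed by family_id with one boolean
    column per taxon; Reb-harboring taxa come first, each block sorted.
    """

    data: pd.DataFrame
    reb_taxa: Tuple[str, ...]
    nonreb_taxa: Tuple[str, ...]

    @property
    def families(self) -> List[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> List[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class ExclusivityReport:
    """Outcome of the exclusivity screen.

    ``exclusive_families``: (family_id, n_reb_taxa_present, member_count)
    ``near_miss_families``: (family_id, n_reb_taxa_present, n_nonreb_present)
    """

    exclusive_families: Tuple[Tuple[str, int, int], ...]
    near_miss_families: Tuple[Tuple[str, int, int], ...]
    min_reb_taxa: int

    @property
    def exclusive_ids(self) -> Set[str]:
        return {fid for fid, _, _ in self.exclusive_families}


def build_matrix(
    families: Sequence[ProteinFamily],
    reb_taxa: Iterable[str],
    nonreb_taxa: Iterable[str],
    taxon_of: Mapping[str, str],
) -> PresenceAbsenceMatrix:
    """Boolean families x taxa matrix from content-regime family membership."""
    reb = tuple(sorted(set(reb_taxa)))
    nonreb = tuple(sorted(set(nonreb_taxa)))
    overlap = set(reb) & set(nonreb)
    if overlap:
        raise ValueError(f"taxa in both partitions: {sorted(overlap)}")
    taxa = list(reb) + list(nonreb)
    family_ids = sorted(f.family_id for f in families)
    if len(family_ids) != len(set(family_ids)):
        raise ValueError("duplicate family ids")
    data = pd.DataFrame(False, index=family_ids, columns=taxa)
    for family in families:
        for pid in family.members:
            taxon = taxon_of.get(pid)
            if taxon in data.columns:
                data.loc[family.family_id, taxon] = True
    return PresenceAbsenceMatrix(data=data, reb_taxa=reb, nonreb_taxa=nonreb)


def screen_exclusive(
    matrix: PresenceAbsenceMatrix,
    families: Sequence[ProteinFamily],
    min_reb_taxa: int = 2,
) -> ExclusivityReport:
    """Families present only in Reb-harboring taxa (plus near-misses)."""
    if min_reb_taxa < 1:
        raise ValueError("min_reb_taxa must be >= 1")
    sizes = {f.family_id: len(f.members) for f in families}
    reb_block = matrix.data[list(matrix.reb_taxa)] if matrix.reb_taxa else None
    nonreb_block = (
        matrix.data[list(matrix.nonreb_taxa)] if matrix.nonreb_taxa else None
    )
    exclusive: List[Tuple[str, int, int]] = []
    near_miss: List[Tuple[str, int, int]] = []
    for family_id in matrix.families:
        n_reb = int(reb_block.loc[family_id].sum()) if reb_block is not None else 0
        n_non = (
            int(nonreb_block.loc[family_id].sum())
            if nonreb_block is not None
            else 0
        )
        if n_reb >= min_reb_taxa and n_non == 0:
            exclusive.append((family_id, n_reb, sizes.get(family_id, 0)))
        elif n_reb >= min_reb_taxa and 1 <= n_non <= 2:
            near_miss.append((family_id, n_reb, n_non))
    return ExclusivityReport(
        exclusive_families=tuple(exclusive),
        near_miss_families=tuple(near_miss),
        min_reb_taxa=min_reb_taxa,
    )


def summarize_distribution(
    reb_ids_by_taxon: Mapping[str, Set[str]],
    records_by_id: Mapping[str, ProteinRecord],
    all_taxa: Iterable[str],
) -> pd.DataFrame:
    """Per-taxon reb copy-number table (presence/absence tabulation).

    One row per taxon: number of reb homologs, their ids, and which copies
    sit on plasmid replicons.  Taxa with zero hits are listed with n_reb=0
    (the non-Reb side of the tabulation).
    """
    rows = []
    for taxon in sorted(set(all_taxa)):
        ids = sorted(reb_ids_by_taxon.get(taxon, set()))
        plasmid_flags = [
            records_by_id[pid].is_plasmid for pid in ids if pid in records_by_id
        ]
        rows.append(
            {
                "taxon_id": taxon,
                "n_reb": len(ids),
                "reb_ids": ",".join(ids),
                "plasmid_flags": ",".join(
                    str(flag).lower() for flag in plasmid_flags
                ),
                "any_plasmid": any(plasmid_flags),
            }
        )
    return pd.DataFrame(
        rows, columns=["taxon_id", "n_reb", "reb_ids", "plasmid_flags", "any_plasmid"]
    )


def copy_number_stats(distribution: pd.DataFrame) -> Dict[str, float]:
    """min/max/mean reb copy number across Reb-harboring taxa."""
    harboring = distribution[distribution["n_reb"] > 0]
    if harboring.empty:
        return {"n_reb_taxa": 0, "min": 0, "max": 0, "mean": 0.0}
    return {
        "n_reb_taxa": int(len(harboring)),
        "min": int(harboring["n_reb"].min()),
        "max": int(harboring["n_reb"].max()),
        "mean": float(harboring["n_reb"].mean()),
    }


def plot_matrix(matrix: PresenceAbsenceMatrix, path) -> None:
    """Basic presence/absence heatmap (families x taxa)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * len(matrix.taxa)),
                 max(4, 0.05 * len(matrix.families)))
    )
    ax.imshow(matrix.data.values, aspect="auto", cmap="Greys",
              interpolation="nearest")
    ax.set_xticks(range(len(matrix.taxa)))
    ax.set_xticklabels(matrix.taxa, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_xlabel("taxa (Reb-harboring first)")
    ax.set_ylabel(f"{len(matrix.families)} families")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
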