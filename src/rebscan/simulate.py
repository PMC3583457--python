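"""Synthetic multi-taxon proteomes with planted reb loci and ground truth.

The generator emulates the world the survey operates on, at desk scale:

* Reb-harboring taxa carry a contiguous *reb* locus of 1–9 copies of a common
  Reb ancestor (~95 aa), adjacent copies optionally separated by a few
  intervening genes; an optional extra copy can be planted far from the locus
  (the multi-locus case) and a configurable fraction of loci sit on plasmid
  replicons.
* Each reb taxon carries one of two mutually exclusive neighborhood patterns
  (or none): Group 1 — four partner families of ~360, ~110–120, ~170 and
  ~60–80 aa planted immediately downstream in a fixed order (plus an optional
  fifth); Group 2 — two ~205–220 aa partner families downstream plus a
  sigma-factor-like and a regulator-like family upstream.  Partner families
  occur *only* in Reb-harboring taxa (the property the exclusivity screen
  must recover).
* Decoy families are planted across taxa regardless of Reb status; every
  decoy touches at least one non-Reb taxon when one exists, and decoy 0 is
  present in all taxa (the promiscuous decoy).
* All remaining genes are i.i.d. background proteins (singleton families).

Homologs are per-site substitutions of the family ancestor: a site mutates
with probability ``divergence`` and its replacement (never the original
residue) is drawn with probability proportional to background frequency
times exp(λ·BLOSUM62 score), so percent similarity degrades smoothly and
more slowly than percent identity.  Expected identity to the ancestor is
therefore exactly ``1 − divergence`` per site.  No indels are introduced;
lengths are family properties.

Identical configs yield byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .align import substitution_matrix
from .composition import BACKGROUND
from .records import AMINO_ACIDS, ProteinRecord, Proteome, write_fasta, write_gff3

#: BLOSUM62 natural scale parameter (nats per half-bit score unit).
_BLOSUM62_LAMBDA = 0.3176

PATTERN_KINDS = ("group1", "group2", "none")

GROUP1_FAMILIES = ("HP1.1", "HP1.2", "HP1.3", "HP1.4")
GROUP2_FAMILIES = ("HP2.1", "HP2.2", "HP2.3", "HP2.4")


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of one synthetic dataset.  See module docstring."""

    seed: int = 0
    n_reb_taxa: int = 10
    n_nonreb_taxa: int = 10
    reb_copies_range: Tuple[int, int] = (1, 9)
    reb_mean_length: int = 95
    pattern_kinds: Optional[Tuple[str, ...]] = None   # per reb taxon
    divergence: float = 0.2
    background_genes_per_replicon: int = 30
    decoy_family_count: int = 20
    plasmid_fraction: float = 0.15
    locus_max_gap: int = 1            # max intervening genes inside a locus
    n_distal_reb_taxa: int = 0        # taxa with one extra far-away reb copy
    plant_hp15: bool = False          # optional fifth Group 1 family
    min_expected_identity: float = 0.30

    def __post_init__(self) -> None:
        lo, hi = self.reb_copies_range
        if not (1 <= lo <= hi):
            raise ValueError(f"reb_copies_range must satisfy 1 <= lo <= hi, got {self.reb_copies_range}")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError(f"divergence must be in [0, 1), got {self.divergence}")
        for name in ("n_reb_taxa", "n_nonreb_taxa", "background_genes_per_replicon",
                     "decoy_family_count", "locus_max_gap", "n_distal_reb_taxa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_reb_taxa + self.n_nonreb_taxa == 0:
            raise ValueError("zero taxa requested")
        if not (0.0 <= self.plasmid_fraction <= 1.0):
            raise ValueError("plasmid_fraction must be in [0, 1]")
        if self.n_distal_reb_taxa > self.n_reb_taxa:
            raise ValueError("n_distal_reb_taxa exceeds n_reb_taxa")
        if 1.0 - self.divergence < self.min_expected_identity:
            raise ValueError(
                f"divergence {self.divergence} drives expected identity to the "
                f"ancestor ({1.0 - self.divergence:.2f}) below the generator's "
                f"identity floor ({self.min_expected_identity}); planted "
                "homologs would not be recognisable as a family"
            )
        if self.pattern_kinds is not None:
            if len(self.pattern_kinds) != self.n_reb_taxa:
                raise ValueError(
                    f"pattern_kinds has {len(self.pattern_kinds)} entries for "
                    f"{self.n_reb_taxa} reb taxa"
                )
            bad = set(self.pattern_kinds) - set(PATTERN_KINDS)
            if bad:
                raise ValueError(f"unknown pattern kinds: {sorted(bad)}")

    def resolved_pattern_kinds(self) -> Tuple[str, ...]:
        """Per-reb-taxon pattern kinds (default: alternating group1/group2)."""
        if self.pattern_kinds is not None:
            return tuple(self.pattern_kinds)
        return tuple(
            "group1" if i % 2 == 0 else "group2" for i in range(self.n_reb_taxa)
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        data = json.loads(text)
        if data.get("reb_copies_range") is not None:
            data["reb_copies_range"] = tuple(data["reb_copies_range"])
        if data.get("pattern_kinds") is not None:
            data["pattern_kinds"] = tuple(data["pattern_kinds"])
        return cls(**data)


@dataclass
class GroundTruth:
    """What the generator planted, keyed for downstream assertions."""

    reb_protein_ids: Set[str] = field(default_factory=set)
    partner_family_map: Dict[str, Set[str]] = field(default_factory=dict)
    decoy_family_map: Dict[str, Set[str]] = field(default_factory=dict)
    pattern_by_taxon: Dict[str, str] = field(default_factory=dict)
    locus_positions: Dict[str, List[Tuple[str, Tuple[int, int]]]] = field(
        default_factory=dict
    )
    reb_taxa: Set[str] = field(default_factory=set)
    nonreb_taxa: Set[str] = field(default_factory=set)

    def family_label_of(self, protein_id: str) -> str:
        """Ground-truth family label; background proteins map to ''. """
        if protein_id in self.reb_protein_ids:
            return "reb"
        for label, members in self.partner_family_map.items():
            if protein_id in members:
                return label
        for label, members in self.decoy_family_map.items():
            if protein_id in members:
                return label
        return ""

    def planted_families(self) -> Dict[str, Set[str]]:
        """label -> protein ids for all multi-member planted families."""
        out: Dict[str, Set[str]] = {"reb": set(self.reb_protein_ids)}
        out.update({k: set(v) for k, v in self.partner_family_map.items()})
        out.update({k: set(v) for k, v in self.decoy_family_map.items()})
        return out


@dataclass
class SyntheticDataset:
    """Generated proteomes, their ground truth, and seed stand-ins."""

    proteomes: List[Proteome]
    truth: GroundTruth
    seeds: List[ProteinRecord]
    config: GeneratorConfig

    def proteome(self, taxon_id: str) -> Proteome:
        for p in self.proteomes:
            if p.taxon_id == taxon_id:
                return p
        raise KeyError(taxon_id)


# ---------------------------------------------------------------------------
# Sequence model
# ---------------------------------------------------------------------------

def _substitution_kernel() -> np.ndarray:
    """20x20 replacement kernel: K[a, b] = P(b | a mutates), K[a, a] = 0."""
    scores = substitution_matrix("BLOSUM62")[:20, :20]
    kernel = BACKGROUND[None, :] * np.exp(_BLOSUM62_LAMBDA * scores)
    np.fill_diagonal(kernel, 0.0)
    kernel /= kernel.sum(axis=1, keepdims=True)
    return kernel


_KERNEL = _substitution_kernel()
_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
_AA_TO_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def random_protein(length: int, rng: np.random.Generator) -> str:
    """An i.i.d. background protein of the given length."""
    codes = rng.choice(20, size=length, p=BACKGROUND)
    return b"".join(_AA[codes]).decode()


def mutate_sequence(sequence: str, divergence: float,
                    rng: np.random.Generator) -> str:
    """Per-site substitution of a sequence at the given divergence.

    Each site mutates independently with probability ``divergence``; the
    replacement (never the original residue) is drawn from the
    BLOSUM62-biased kernel.  Expected identity to the input is exactly
    ``1 − divergence``.
    """
    codes = np.array([_AA_TO_CODE[a] for a in sequence], dtype=np.int64)
    mask = rng.random(len(codes)) < divergence
    for pos in np.flatnonzero(mask):
        codes[pos] = rng.choice(20, p=_KERNEL[codes[pos]])
    return b"".join(_AA[codes]).decode()


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

_PARTNER_LENGTHS_FIXED = {"HP1.1": 360, "HP1.3": 170, "HP1.5": 175,
                          "HP2.3": 190, "HP2.4": 240}


def _draw_partner_lengths(rng: np.random.Generator) -> Dict[str, int]:
    lengths = dict(_PARTNER_LENGTHS_FIXED)
    lengths["HP1.2"] = int(rng.integers(110, 121))
    lengths["HP1.4"] = int(rng.integers(60, 81))
    lengths["HP2.1"] = int(rng.integers(205, 221))
    lengths["HP2.2"] = int(rng.integers(205, 221))
    return lengths


def _decoy_subsets(
    rng: np.random.Generator,
    n_decoys: int,
    reb_taxa: Sequence[str],
    nonreb_taxa: Sequence[str],
) -> List[Set[str]]:
    """Taxon subsets per decoy; decoy 0 is in all taxa, all decoys touch a
    non-reb taxon when one exists (decoys emulate widely shared families)."""
    all_taxa = list(reb_taxa) + list(nonreb_taxa)
    subsets: List[Set[str]] = []
    for d in range(n_decoys):
        if d == 0:
            subsets.append(set(all_taxa))
            continue
        size = int(rng.integers(2, len(all_taxa) + 1))
        chosen = set(rng.choice(all_taxa, size=size, replace=False).tolist())
        if nonreb_taxa and not (chosen & set(nonreb_taxa)):
            chosen.add(str(rng.choice(list(nonreb_taxa))))
        subsets.append(chosen)
    return subsets


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the proteomes, ground truth and seed stand-ins of a world."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    reb_taxa = [f"R{i + 1:02d}" for i in range(config.n_reb_taxa)]
    nonreb_taxa = [f"N{i + 1:02d}" for i in range(config.n_nonreb_taxa)]
    truth.reb_taxa = set(reb_taxa)
    truth.nonreb_taxa = set(nonreb_taxa)
    patterns = config.resolved_pattern_kinds()

    # --- ancestors ---------------------------------------------------------
    reb_ancestor = random_protein(config.reb_mean_length, rng)
    partner_lengths = _draw_partner_lengths(rng)
    partner_labels = list(GROUP1_FAMILIES) + (["HP1.5"] if config.plant_hp15 else [])
    partner_labels += list(GROUP2_FAMILIES)
    partner_ancestors = {
        label: random_protein(partner_lengths[label], rng)
        for label in partner_labels
    }
    decoy_labels = [f"decoy{d + 1:02d}" for d in range(config.decoy_family_count)]
    decoy_ancestors = {
        label: random_protein(int(rng.integers(120, 401)), rng)
        for label in decoy_labels
    }
    decoy_subsets = dict(
        zip(decoy_labels,
            _decoy_subsets(rng, config.decoy_family_count, reb_taxa, nonreb_taxa))
    )
    for label in partner_labels:
        truth.partner_family_map[label] = set()
    for label in decoy_labels:
        truth.decoy_family_map[label] = set()

    # --- seed stand-ins (pKAP298 RebA/B/D analogues + a RebC-like orphan) --
    seed_records: List[ProteinRecord] = []
    for i, name in enumerate(("RebA", "RebB", "RebD")):
        seq = mutate_sequence(reb_ancestor, 0.05, rng)
        seed_records.append(
            ProteinRecord(
                protein_id=f"seed_{name}", taxon_id="SEED",
                replicon_id="pKAP298", index=i,
                start=1 + i * 400, end=(1 + i * 400) + 3 * len(seq) - 1,
                strand="+", is_plasmid=True, sequence=seq,
            )
        )
    rebc_seq = random_protein(116, rng)
    seed_records.append(
        ProteinRecord(
            protein_id="seed_RebC", taxon_id="SEED", replicon_id="pKAP298",
            index=3, start=1201, end=1201 + 3 * len(rebc_seq) - 1,
            strand="+", is_plasmid=True, sequence=rebc_seq,
        )
    )

    # --- per-taxon assembly -------------------------------------------------
    proteomes: List[Proteome] = []
    for t_idx, taxon in enumerate(reb_taxa + nonreb_taxa):
        is_reb_taxon = t_idx < len(reb_taxa)
        pattern = patterns[t_idx] if is_reb_taxon else "none"
        if is_reb_taxon:
            truth.pattern_by_taxon[taxon] = pattern

        # background genes, then decoys inserted among them
        chromosome: List[Tuple[str, str]] = [
            ("", random_protein(int(rng.integers(80, 401)), rng))
            for _ in range(config.background_genes_per_replicon)
        ]
        for label in decoy_labels:
            if taxon in decoy_subsets[label]:
                pos = int(rng.integers(0, len(chromosome) + 1))
                chromosome.insert(
                    pos, (label, mutate_sequence(decoy_ancestors[label],
                                                 config.divergence, rng))
                )

        plasmid: List[Tuple[str, str]] = []
        if is_reb_taxon:
            gets_distal = t_idx < config.n_distal_reb_taxa
            block = _locus_block(config, pattern, reb_ancestor,
                                 partner_ancestors, rng,
                                 reserve_one_copy=gets_distal)
            on_plasmid = bool(rng.random() < config.plasmid_fraction)
            if on_plasmid:
                flank = [
                    ("", random_protein(int(rng.integers(80, 401)), rng))
                    for _ in range(12)
                ]
                plasmid = flank[:6] + block + flank[6:]
            else:
                lo = min(6, len(chromosome))
                insert_at = int(rng.integers(lo, len(chromosome) + 1)) \
                    if len(chromosome) > lo else len(chromosome)
                chromosome = (
                    chromosome[:insert_at] + block + chromosome[insert_at:]
                )
            if gets_distal:
                # extra far-away copy on the chromosome (multi-locus case)
                distal = ("reb", mutate_sequence(reb_ancestor,
                                                 config.divergence, rng))
                chromosome.insert(0, distal)

        records: List[ProteinRecord] = []
        for replicon_id, payload, plasmid_flag in (
            ("chr", chromosome, False),
            ("p1", plasmid, True),
        ):
            cursor = 1
            for idx, (label, seq) in enumerate(payload):
                pid = f"{taxon}_{replicon_id}_{idx:04d}"
                start = cursor
                end = start + 3 * len(seq) - 1
                cursor = end + 201  # fixed intergenic spacing
                records.append(
                    ProteinRecord(
                        protein_id=pid, taxon_id=taxon,
                        replicon_id=replicon_id, index=idx,
                        start=start, end=end,
                        strand="+" if rng.random() < 0.5 else "-",
                        is_plasmid=plasmid_flag, sequence=seq,
                    )
                )
                if label == "reb":
                    truth.reb_protein_ids.add(pid)
                elif label in truth.partner_family_map:
                    truth.partner_family_map[label].add(pid)
                elif label in truth.decoy_family_map:
                    truth.decoy_family_map[label].add(pid)
        proteome = Proteome(taxon_id=taxon, records=records)
        proteomes.append(proteome)

        if is_reb_taxon:
            truth.locus_positions[taxon] = _reb_runs(
                proteome, truth, config.locus_max_gap
            )
    return SyntheticDataset(
        proteomes=proteomes, truth=truth, seeds=seed_records, config=config
    )


def _locus_block(
    config: GeneratorConfig,
    pattern: str,
    reb_ancestor: str,
    partner_ancestors: Dict[str, str],
    rng: np.random.Generator,
    reserve_one_copy: bool = False,
) -> List[Tuple[str, str]]:
    """The contiguous planted block: upstream partners, reb run, downstream.

    ``reserve_one_copy`` shrinks the draw by one so a distal extra copy
    keeps the taxon's total inside ``reb_copies_range``.
    """
    def partner(label: str) -> Tuple[str, str]:
        return (label, mutate_sequence(partner_ancestors[label],
                                       config.divergence, rng))

    lo, hi = config.reb_copies_range
    if reserve_one_copy:
        hi = max(lo, hi - 1)
    n_copies = int(rng.integers(lo, hi + 1))
    run: List[Tuple[str, str]] = []
    for c in range(n_copies):
        if c > 0 and config.locus_max_gap > 0:
            for _ in range(int(rng.integers(0, config.locus_max_gap + 1))):
                run.append(("", random_protein(int(rng.integers(80, 401)), rng)))
        run.append(("reb", mutate_sequence(reb_ancestor, config.divergence, rng)))
    if pattern == "group1":
        down = [partner(l) for l in GROUP1_FAMILIES]
        if config.plant_hp15:
            down.append(partner("HP1.5"))
        return run + down
    if pattern == "group2":
        up = [partner("HP2.3"), partner("HP2.4")]
        down = [partner("HP2.1"), partner("HP2.2")]
        return up + run + down
    return run


def _reb_runs(proteome: Proteome, truth: GroundTruth, max_gap: int
              ) -> List[Tuple[str, Tuple[int, int]]]:
    """Ground-truth locus spans: maximal reb runs per replicon, merged at the
    generator's own intervening-gene allowance (planted blocks are contiguous
    runs with gaps <= max_gap, the distal copy is planted much farther)."""
    spans: List[Tuple[str, Tuple[int, int]]] = []
    for replicon in proteome.replicons:
        indices = [r.index for r in proteome.replicon_records(replicon)
                   if r.protein_id in truth.reb_protein_ids]
        if not indices:
            continue
        run_start = prev = indices[0]
        for idx in indices[1:]:
            if idx - prev - 1 <= max_gap:
                prev = idx
            else:
                spans.append((replicon, (run_start, prev)))
                run_start = prev = idx
        spans.append((replicon, (run_start, prev)))
    return spans


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: Path) -> Dict[str, List[str]]:
    """Write per-taxon FASTA + GFF3, seeds, truth sidecars, and a manifest."""
    if not dataset.proteomes:
        raise ValueError("no proteomes to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, List[str]] = {"fasta": [], "gff3": [], "truth": [],
                                      "seeds": []}
    for proteome in sorted(dataset.proteomes, key=lambda p: p.taxon_id):
        fasta = outdir / f"{proteome.taxon_id}.faa"
        gff = outdir / f"{proteome.taxon_id}.gff3"
        write_fasta(proteome, fasta)
        write_gff3(proteome, gff)
        manifest["fasta"].append(fasta.name)
        manifest["gff3"].append(gff.name)

    seeds_path = outdir / "seeds.faa"
    write_fasta(Proteome(taxon_id="SEED", records=dataset.seeds), seeds_path)
    manifest["seeds"].append(seeds_path.name)

    truth = dataset.truth
    rows = ["protein_id\ttaxon\tfamily_label\tis_reb"]
    for proteome in sorted(dataset.proteomes, key=lambda p: p.taxon_id):
        for rec in proteome:
            label = truth.family_label_of(rec.protein_id)
            rows.append(
                f"{rec.protein_id}\t{rec.taxon_id}\t{label}"
                f"\t{str(rec.protein_id in truth.reb_protein_ids).lower()}"
            )
    truth_tsv = outdir / "truth.tsv"
    truth_tsv.write_text("\n".join(rows) + "\n")
    manifest["truth"].append(truth_tsv.name)

    sidecar = {
        "config": json.loads(dataset.config.to_json()),
        "pattern_by_taxon": truth.pattern_by_taxon,
        "locus_positions": {
            taxon: [[replicon, list(span)] for replicon, span in loci]
            for taxon, loci in truth.locus_positions.items()
        },
        "reb_taxa": sorted(truth.reb_taxa),
        "nonreb_taxa": sorted(truth.nonreb_taxa),
    }
    truth_json = outdir / "truth.json"
    truth_json.write_text(json.dumps(sidecar, sort_keys=True, indent=2) + "\n")
    manifest["truth"].append(truth_json.name)

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
    return manifest
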