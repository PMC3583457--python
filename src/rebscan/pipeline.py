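"""End-to-end survey orchestration: search → families → synteny → content → features.

One config drives the whole survey.  Inputs are either a generator config
(synthetic world) or a dataset directory of per-taxon FASTA/GFF3 pairs plus a
seed FASTA (the layout :func:`rebscan.simulate.write_dataset` produces).
Every stage writes its intermediate as TSV/JSON under the output directory,
and a final ``report.json`` carries stage counts, parameters and RNG seeds.
Identical config + inputs give identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .align import AlignParams, DEFAULT_PARAMS, align_sequences
from .content import (
    build_matrix,
    copy_number_stats,
    screen_exclusive,
    summarize_distribution,
)
from .families import (
    CONTENT_REGIME,
    SYNTENY_REGIME,
    ThresholdRegime,
    build_families,
    compute_similarity_table,
    edges_under_regime,
    families_table,
    membership_map,
)
from .features import conservation_profile, moment_table
from .homology import SearchHit, iterate_profile_search, search_with_seeds
from .records import (
    ProteinRecord,
    Proteome,
    pool_records,
    read_fasta_sequences,
    read_proteome,
    taxon_of_map,
    validate_sequence,
)
from .simulate import GeneratorConfig, generate_dataset, write_dataset
from .synteny import call_reb_loci, detect_patterns, extract_window

logger = logging.getLogger("rebscan")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Survey parameters.  Defaults are the survey's published settings:
    e-value cutoff 1e-3; synteny regime 40% similarity, <20% length
    difference; content regime 50% similarity, <20% length difference;
    windows of k=5 ORFs up/downstream."""

    input_dir: Optional[str] = None           # dataset dir (FASTA+GFF3+seeds)
    generator: Optional[GeneratorConfig] = None
    outdir: str = "rebscan_out"
    e_cutoff: float = 1e-3
    synteny_regime: ThresholdRegime = field(default_factory=lambda: SYNTENY_REGIME)
    content_regime: ThresholdRegime = field(default_factory=lambda: CONTENT_REGIME)
    k: int = 5
    max_gap: int = 3
    min_taxa: int = 3
    min_reb_taxa: int = 2
    n_shuffles: int = 30
    profile_iters: int = 1
    rng_seed: int = 0
    align_params: AlignParams = field(default_factory=lambda: DEFAULT_PARAMS)

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_dir / generator must be given"
            )


@dataclass
class ValidationReport:
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def discover_manifest(input_dir: Path) -> Dict[str, Dict[str, Path]]:
    """Map taxon -> {fasta, gff3} from a dataset directory.

    Taxa are the ``*.faa``/``*.gff3`` basename pairs; ``seeds.faa`` is
    reserved for the seed set.
    """
    input_dir = Path(input_dir)
    taxa: Dict[str, Dict[str, Path]] = {}
    for fasta in sorted(input_dir.glob("*.faa")):
        if fasta.stem == "seeds":
            continue
        taxa[fasta.stem] = {"fasta": fasta, "gff3": input_dir / f"{fasta.stem}.gff3"}
    return taxa


def validate_inputs(manifest: Mapping[str, Mapping[str, Path]]) -> ValidationReport:
    """Cross-check FASTA/GFF3 pairs without building full proteomes.

    Errors: missing/unreadable files, CDS without sequence and vice versa,
    duplicate ids, alphabet violations.  Short replicons (too few genes to
    fill a ±5 window) are warnings — they behave like contig fragments and
    yield truncated windows downstream.
    """
    from .records import read_gff3_table  # local to keep module surface tidy

    report = ValidationReport()
    for taxon in sorted(manifest):
        paths = manifest[taxon]
        fasta, gff = Path(paths["fasta"]), Path(paths["gff3"])
        for path in (fasta, gff):
            if not path.is_file():
                raise FileNotFoundError(f"{taxon}: unreadable input {path}")
        try:
            seqs = read_fasta_sequences(fasta)
        except Exception as exc:
            report.errors.append(f"{taxon}: FASTA parse failure: {exc}")
            continue
        try:
            table = read_gff3_table(gff)
        except Exception as exc:
            report.errors.append(f"{taxon}: GFF3 parse failure: {exc}")
            continue
        gff_ids = list(table["protein_id"])
        if len(gff_ids) != len(set(gff_ids)):
            dupes = sorted({i for i in gff_ids if gff_ids.count(i) > 1})
            report.errors.append(f"{taxon}: duplicate CDS ids {dupes}")
        missing_seq = sorted(set(gff_ids) - set(seqs))
        if missing_seq:
            report.errors.append(
                f"{taxon}: CDS without FASTA sequence: {missing_seq}"
            )
        missing_cds = sorted(set(seqs) - set(gff_ids))
        if missing_cds:
            report.errors.append(
                f"{taxon}: FASTA record without CDS: {missing_cds}"
            )
        for pid, seq in sorted(seqs.items()):
            try:
                validate_sequence(seq, f"{taxon}:{pid}")
            except ValueError as exc:
                report.errors.append(str(exc))
        if (table["start"] > table["end"]).any():
            report.errors.append(f"{taxon}: GFF3 feature with start > end")
        for replicon, group in table.groupby("replicon_id"):
            if len(group) < 11:
                report.warnings.append(
                    f"{taxon}/{replicon}: only {len(group)} genes — contig "
                    "fragment? windows will be truncated"
                )
    return report


def _load_seed_records(path: Path) -> List[ProteinRecord]:
    seqs = read_fasta_sequences(path)
    return [
        ProteinRecord(
            protein_id=pid, taxon_id="SEED", replicon_id="seeds", index=i,
            start=1, end=3 * len(seq), strand="+", is_plasmid=False,
            sequence=seq,
        )
        for i, (pid, seq) in enumerate(sorted(seqs.items()))
    ]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run all survey stages; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "version": "0.1.0",
        "python": platform.python_version(),
        "parameters": {
            "e_cutoff": config.e_cutoff,
            "synteny_regime": asdict(config.synteny_regime),
            "content_regime": asdict(config.content_regime),
            "k": config.k,
            "max_gap": config.max_gap,
            "min_taxa": config.min_taxa,
            "min_reb_taxa": config.min_reb_taxa,
            "n_shuffles": config.n_shuffles,
            "profile_iters": config.profile_iters,
            "rng_seed": config.rng_seed,
        },
        "stages": {},
    }
    stage = "inputs"
    try:
        proteomes, seeds = _stage_inputs(config, outdir, report)
        all_records = pool_records(proteomes)
        by_id = {r.protein_id: r for r in all_records}
        taxon_of = taxon_of_map(proteomes)
        all_taxa = {p.taxon_id for p in proteomes}

        stage = "search"
        hits = _stage_search(config, seeds, all_records, outdir, report)
        reb_ids = {h.subject_id for h in hits}
        reb_taxa = {taxon_of[pid] for pid in reb_ids}

        stage = "synteny_windows"
        windows = []
        for proteome in sorted(proteomes, key=lambda p: p.taxon_id):
            if proteome.taxon_id not in reb_taxa:
                continue
            for locus in call_reb_loci(proteome, reb_ids, config.max_gap):
                windows.append(
                    extract_window(locus, proteome, k=config.k, reb_ids=reb_ids)
                )
        report["stages"]["synteny_windows"] = {
            "n_loci": len(windows),
            "n_truncated": sum(w.truncated for w in windows),
        }

        stage = "families"
        table = compute_similarity_table(
            all_records,
            max_len_threshold=max(
                config.synteny_regime.len_threshold,
                config.content_regime.len_threshold,
            ),
            params=config.align_params,
        )
        synteny_families = build_families(
            all_records, config.synteny_regime, table=table
        )
        content_families = build_families(
            all_records, config.content_regime, table=table
        )
        _write_tsv(families_table(synteny_families, taxon_of),
                   outdir / "families_synteny.tsv")
        _write_tsv(families_table(content_families, taxon_of),
                   outdir / "families_content.tsv")
        edge_rows = [
            {
                "id_a": e.pair[0], "id_b": e.pair[1],
                "pct_similarity": round(e.percent_similarity, 2),
                "pct_identity": round(e.percent_identity, 2),
                "length_diff_fraction": round(e.length_diff_fraction, 4),
            }
            for e in edges_under_regime(table, config.synteny_regime)
        ]
        _write_tsv(
            pd.DataFrame(edge_rows, columns=["id_a", "id_b", "pct_similarity",
                                             "pct_identity",
                                             "length_diff_fraction"]),
            outdir / "edges_synteny.tsv",
        )
        report["stages"]["families"] = {
            "n_proteins": len(all_records),
            "n_synteny_families": len(synteny_families),
            "n_content_families": len(content_families),
        }

        stage = "patterns"
        patterns = detect_patterns(
            windows, synteny_families, reb_taxa, all_taxa, taxon_of,
            min_taxa=config.min_taxa,
        ) if len(reb_taxa) >= 2 else []
        _write_windows_tsv(windows, membership_map(synteny_families),
                           outdir / "windows.tsv")
        (outdir / "patterns.json").write_text(
            json.dumps(
                [
                    {
                        "pattern_id": p.pattern_id,
                        "families": sorted(p.family_ids),
                        "supporting_taxa": sorted(p.supporting_taxa),
                        "contexts": {
                            t: list(labels)
                            for t, labels in sorted(p.adjacency_profile.items())
                        },
                    }
                    for p in patterns
                ],
                indent=2, sort_keys=True,
            ) + "\n"
        )
        report["stages"]["patterns"] = {
            "n_patterns": len(patterns),
            "patterns": [
                {"pattern_id": p.pattern_id,
                 "n_families": len(p.family_ids),
                 "n_taxa": len(p.supporting_taxa)}
                for p in patterns
            ],
        }

        stage = "content"
        matrix = build_matrix(
            content_families, reb_taxa, all_taxa - reb_taxa, taxon_of
        )
        matrix.data.to_csv(outdir / "matrix.tsv", sep="\t")
        _write_sparse_matrix(matrix, outdir / "matrix_triplets.tsv")
        exclusivity = screen_exclusive(
            matrix, content_families, min_reb_taxa=config.min_reb_taxa
        )
        (outdir / "exclusivity.json").write_text(
            json.dumps(
                {
                    "min_reb_taxa": exclusivity.min_reb_taxa,
                    "exclusive": [
                        {"family_id": fid, "n_reb_taxa": n, "n_members": m}
                        for fid, n, m in exclusivity.exclusive_families
                    ],
                    "near_miss": [
                        {"family_id": fid, "n_reb_taxa": n, "n_nonreb_taxa": m}
                        for fid, n, m in exclusivity.near_miss_families
                    ],
                },
                indent=2, sort_keys=True,
            ) + "\n"
        )
        reb_by_taxon: Dict[str, Set[str]] = {}
        for pid in reb_ids:
            reb_by_taxon.setdefault(taxon_of[pid], set()).add(pid)
        distribution = summarize_distribution(reb_by_taxon, by_id, all_taxa)
        _write_tsv(distribution, outdir / "distribution.tsv")
        report["stages"]["content"] = {
            "n_families": len(matrix.families),
            "n_exclusive": len(exclusivity.exclusive_families),
            "exclusive_families": sorted(exclusivity.exclusive_ids),
            "n_near_miss": len(exclusivity.near_miss_families),
            "copy_number": copy_number_stats(distribution),
        }

        stage = "features"
        report["stages"]["features"] = _stage_features(
            config, hits, by_id, outdir
        )
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        report["failed_stage"] = stage
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        raise PipelineError(stage, exc) from exc

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def _stage_inputs(config: PipelineConfig, outdir: Path, report: Dict
                  ) -> Tuple[List[Proteome], List[ProteinRecord]]:
    if config.generator is not None:
        dataset = generate_dataset(config.generator)
        write_dataset(dataset, outdir / "dataset")
        proteomes, seeds = dataset.proteomes, dataset.seeds
        report["stages"]["inputs"] = {
            "source": "generator",
            "generator_seed": config.generator.seed,
            "n_taxa": len(proteomes),
        }
    else:
        input_dir = Path(config.input_dir)
        manifest = discover_manifest(input_dir)
        if not manifest:
            raise FileNotFoundError(f"no FASTA/GFF3 pairs under {input_dir}")
        validation = validate_inputs(manifest)
        for warning in validation.warnings:
            logger.warning(warning)
        if not validation.ok:
            raise ValueError(
                "input validation failed: " + "; ".join(validation.errors)
            )
        proteomes = [
            read_proteome(taxon, paths["fasta"], paths["gff3"])
            for taxon, paths in sorted(manifest.items())
        ]
        seeds_path = input_dir / "seeds.faa"
        if not seeds_path.is_file():
            raise FileNotFoundError(f"seed FASTA not found: {seeds_path}")
        seeds = _load_seed_records(seeds_path)
        report["stages"]["inputs"] = {
            "source": str(input_dir),
            "n_taxa": len(proteomes),
            "n_warnings": len(validation.warnings),
        }
    return proteomes, seeds


def _stage_search(config: PipelineConfig, seeds: Sequence[ProteinRecord],
                  all_records: Sequence[ProteinRecord], outdir: Path,
                  report: Dict) -> List[SearchHit]:
    hits = search_with_seeds(
        seeds, all_records,
        e_cutoff=config.e_cutoff,
        n_shuffles=config.n_shuffles,
        rng_seed=config.rng_seed,
        params=config.align_params,
    )
    n_direct = len(hits)
    if hits and config.profile_iters > 0:
        hits, _profile = iterate_profile_search(
            hits, all_records,
            max_iters=config.profile_iters,
            inclusion_e=config.e_cutoff,
            n_shuffles=config.n_shuffles,
            rng_seed=config.rng_seed + 1,
            params=config.align_params,
        )
    by_id = {r.protein_id: r for r in all_records}
    seed_by_id = {s.protein_id: s for s in seeds}
    rows = []
    for hit in sorted(hits, key=lambda h: h.subject_id):
        subject = by_id[hit.subject_id]
        seed = seed_by_id.get(hit.query_seed_id)
        if seed is not None:
            result = align_sequences(
                seed.sequence, subject.sequence, params=config.align_params,
                ids=(seed.protein_id, subject.protein_id),
            )
            pct_id, pct_sim = result.percent_identity, result.percent_similarity
        else:  # profile-recovered hit: no single seed to align against
            pct_id = pct_sim = float("nan")
        rows.append(
            {
                "seed_id": hit.query_seed_id,
                "subject_id": hit.subject_id,
                "raw_score": hit.raw_score,
                "pct_identity": round(pct_id, 2),
                "pct_similarity": round(pct_sim, 2),
                "empirical_p": hit.empirical_p,
                "empirical_e": hit.evalue,
            }
        )
    _write_tsv(
        pd.DataFrame(rows, columns=["seed_id", "subject_id", "raw_score",
                                    "pct_identity", "pct_similarity",
                                    "empirical_p", "empirical_e"]),
        outdir / "hits.tsv",
    )
    report["stages"]["search"] = {
        "n_seeds": len(seeds),
        "n_direct_hits": n_direct,
        "n_hits": len(hits),
    }
    return hits


def _stage_features(config: PipelineConfig, hits: Sequence[SearchHit],
                    by_id: Mapping[str, ProteinRecord], outdir: Path) -> Dict:
    reb_seqs = {
        h.subject_id: by_id[h.subject_id].sequence
        for h in hits if h.subject_id in by_id
    }
    out: Dict = {"n_reb_proteins": len(reb_seqs)}
    if len(reb_seqs) >= 2:
        master_id = max(
            (h for h in hits if h.subject_id in by_id),
            key=lambda h: (h.raw_score, [-ord(c) for c in h.subject_id]),
        ).subject_id
        aligned = master_projection(
            reb_seqs[master_id],
            {k: v for k, v in sorted(reb_seqs.items())},
            params=config.align_params,
        )
        profile = conservation_profile(list(aligned.values()))
        _write_tsv(profile.to_frame(), outdir / "conservation.tsv")
        out["alignment_length"] = profile.alignment_length
        out["max_information_bits"] = round(float(profile.information.max()), 3)
    window_len = 18
    moments = moment_table(
        {k: v for k, v in reb_seqs.items() if len(v) >= window_len},
        window_len=window_len,
    )
    _write_tsv(moments, outdir / "moments.tsv")
    if not moments.empty:
        out["max_muH"] = float(moments["muH"].max())
    return out


def master_projection(master_seq: str, sequences: Mapping[str, str],
                      params: AlignParams = DEFAULT_PARAMS) -> Dict[str, str]:
    """Project sequences onto master coordinates (master–slave alignment).

    Each sequence is globally aligned to the master; the output rows have
    exactly ``len(master_seq)`` columns with '-' where the member aligns a
    gap.  Insertions relative to the master are dropped, which is the
    behaviour of profile/HMM master-coordinate alignments.
    """
    from .align import _make_aligner

    aligner = _make_aligner(params, "global")
    out: Dict[str, str] = {}
    for seq_id in sorted(sequences):
        seq = sequences[seq_id]
        row = ["-"] * len(master_seq)
        alignment = aligner.align(master_seq, seq)[0]
        blocks_m, blocks_s = alignment.aligned
        for (ms, me), (ss, _se) in zip(blocks_m, blocks_s):
            for offset in range(me - ms):
                row[ms + offset] = seq[ss + offset]
        out[seq_id] = "".join(row)
    return out


def _write_windows_tsv(windows, fam_of: Mapping[str, str], path: Path) -> None:
    rows = []
    for window in windows:
        locus = window.locus
        span = f"{locus.index_span[0]}-{locus.index_span[1]}"
        for side, ids in (("upstream", window.upstream),
                          ("downstream", window.downstream)):
            for rank, pid in enumerate(ids):
                rows.append(
                    {
                        "taxon": locus.taxon_id,
                        "replicon": locus.replicon_id,
                        "locus_span": span,
                        "side": side,
                        "rank": rank,
                        "protein_id": pid,
                        "family_id": fam_of.get(pid, ""),
                        "truncated": window.truncated,
                    }
                )
    _write_tsv(
        pd.DataFrame(rows, columns=["taxon", "replicon", "locus_span", "side",
                                    "rank", "protein_id", "family_id",
                                    "truncated"]),
        path,
    )


def _write_sparse_matrix(matrix, path: Path) -> None:
    rows = [
        {"family_id": fam, "taxon_id": taxon}
        for fam in matrix.families
        for taxon in matrix.taxa
        if bool(matrix.data.loc[fam, taxon])
    ]
    _write_tsv(pd.DataFrame(rows, columns=["family_id", "taxon_id"]), path)
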