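# Methods

`rebscan` re-implements, as a tested pipeline on synthetic data, a
comparative-genomics survey of R-body (Reb) protein homologs: which genomes
carry *reb* genes, how the copies cluster into loci, which gene families
recur in the loci's neighborhoods, and which families are present *only* in
Reb-harboring taxa.

## Pairwise alignment and "percent similarity"

All pairwise statements rest on deterministic alignments with BLOSUM62 and
affine gaps (open −11, extend −1, the BLASTP convention; configurable via
`AlignParams`). The homology predicate uses **global** (end-to-end)
alignments because it also constrains whole-protein length; search scoring
uses **local** (Smith–Waterman) alignments. `X` scores 0 against everything.

*Percent similarity* is BLAST's "Positives": the percentage of alignment
columns — gap columns included in the denominator, exactly as BLAST prints
it — whose residue pair has a positive BLOSUM62 score. Percent identity is
reported alongside and is always ≤ similarity. The denominator matters: with
"aligned columns only" as denominator, the affine DP's cheap gap extension
lets it cherry-pick positive columns, and ~30–40 % of *unrelated*
length-matched protein pairs exceed 40 % "similarity", which would collapse
single-linkage clustering. Over the full alignment length, unrelated pairs
average ~29–30 %.

Reported fields are symmetric by construction: the pair is canonically
ordered before the DP runs, so co-optimal-alignment ambiguity cannot make
statistics depend on argument order.

## The homology predicate and the chance gate

Two proteins are called homologous under a named threshold regime when

1. their length difference, `|la − lb| / max(la, lb)`, is **strictly** below
   the regime's length threshold (0.20 in both shipped regimes);
2. percent similarity (or identity — the statistic is configurable) reaches
   the regime's similarity threshold — 40 % for the `synteny` regime, 50 %
   for the `content` regime; and
3. the alignment beats chance: its global score is positive and exceeds the
   Gumbel tail fitted to scores of the same protein against residue-shuffled
   copies of its partner (25 shuffles, RNG seeded deterministically from the
   sequence pair), at p ≤ 1e-3. Identical sequences bypass the gate, where
   composition-preserving shuffles are degenerate.

Condition 3 restores what a BLAST-first workflow has implicitly: thresholds
were only ever applied to pairs that produced a significant hit. Without it
the predicate accepts a small but fatal fraction of unrelated pairs (single
linkage amplifies every false edge into a merged family).

Families are connected components of the resulting homology graph
(union-find with path compression, deterministic iteration over sorted
protein ids; family id = lexicographically smallest member). A
length-difference prefilter and a score-only pre-pass skip most alignments;
both are provably result-identical to the naive double loop. The 50 % regime
is a refinement of the 40 % regime on any protein set, since its edge set is
a subset.

## Seed search and empirical significance

A seed set is searched against a database by Smith–Waterman; each subject's
statistic is its best score over all seeds. Significance is empirical: the
same statistic is recomputed on `n_shuffles` residue-shuffled copies of the
subject (seeded RNG). The reported `empirical_p` is the plain fraction of
decoy scores ≥ the observed score. Because retention at e ≤ 1e-3 needs
p-resolution far beyond 1/n_shuffles, the *working* p-value extrapolates the
right tail of the same decoy distribution with a Gumbel fit (method of
moments: scale = σ·√6/π, loc = μ − γ·scale) whenever the count is zero —
the PRSS/FASTA approach. The e-value is p × database size; hits are retained
at e ≤ 1e-3 (the survey's published cutoff). A subject hit by several seeds
is reported once, ties broken toward the lexicographically smallest seed id.

Iterative profile search mirrors PSI-BLAST/HMMER: all hits so far are
master–slave aligned onto the best-scoring hit, columns with < 50 %
occupancy are masked, frequencies get background pseudocounts (weight 5,
Robinson–Robinson composition), and the log-odds profile rescans the
database with a hand-written (numba) profile Smith–Waterman under the same
shuffled-null machinery. The hit set is monotone; iteration stops at a
fixpoint or `max_iters`.

## Loci, windows, patterns

Neighborhoods are measured in ordinal gene ranks (ORF counts), not
nucleotides; strand is recorded but ignored. A *reb* locus is a maximal run
of reb genes on one replicon separated by at most `max_gap` (default 3)
intervening genes; multiple loci per genome are supported. The window around
a locus is the k (default 5) nearest non-reb genes on each side, counted
from just outside the locus span, truncated (and flagged) at replicon ends.

Pattern detection: map window genes to synteny-regime families; keep
families seen in windows of ≥ `min_taxa` (default 3 — the source work names
no number) distinct taxa; drop any family with a member in a
non-Reb-harboring taxon (checked genome-wide, not just in windows); group
survivors into patterns via connected components of the co-occurrence graph
(two families joined when their windows share ≥ `min_taxa` taxa). Patterns
report supporting taxa and per-taxon ordered context strings.

## Phyletic profiles and exclusivity

The presence/absence matrix marks a content-regime family present in a taxon
when ≥ 1 member is annotated there. A family is *exclusive* when present in
≥ `min_reb_taxa` (default 2 — one genome carries no co-occurrence signal;
set 1 for the strictest reading) Reb-harboring taxa and zero others;
families with 1–2 non-Reb presences are listed separately as near-misses
(distant homologs falling outside the exclusive subfamilies). Exclusivity is
monotone in `min_reb_taxa`.

## Sequence features

The conservation profile computes per-column residue frequencies over
non-gap characters (gap fraction reported separately; > 50 % gap columns
flagged) and information content log2(20) − H bits, no small-sample
correction (synthetic alignments are large). The helical hydrophobic moment
uses the Eisenberg consensus scale (pluggable) at δ = 100°/residue:
µH = ‖Σ h·(cos nδ, sin nδ)‖ / N per sliding window; an 18-mer homopolymer
cancels exactly (5 full turns).

## The synthetic world

The generator states the world the survey is tested against:

- Reb-harboring taxa carry 1–9 copies (uniform draw) of a common 95-aa Reb
  ancestor in a contiguous locus, adjacent copies separated by up to
  `locus_max_gap` (default 1) intervening genes; optionally one extra copy
  far from the locus (the multi-locus case; the in-locus draw is then capped
  so the total stays ≤ 9); a configurable fraction (default 0.15) of loci
  sit on plasmid replicons.
- Group 1 neighborhoods plant four partner families (~360, ~110–120, ~170,
  ~60–80 aa, lengths drawn once per dataset) immediately downstream in fixed
  order, optionally a fifth; Group 2 plants two ~205–220 aa families
  downstream and sigma-factor-like (190 aa) + regulator-like (240 aa)
  families upstream. Partners exist only in Reb taxa; Group 1 and 2 never
  co-occur in one taxon; taxa may also get no pattern.
- 20 decoy families (default) are planted across taxa regardless of Reb
  status; decoy 1 is in every taxon, and every decoy touches ≥ 1 non-Reb
  taxon when one exists — decoys emulate widely shared families, which is
  precisely what the exclusivity screen must reject.
- All other genes are i.i.d. background proteins (Robinson–Robinson
  composition, lengths uniform 80–400 aa), 30 per chromosome by default — a
  desk-scale stand-in for full proteomes chosen so the O(n²) family build
  stays within minutes on one CPU.

Homologs are per-site substitutions of the family ancestor at rate
`divergence` (default 0.2; the source work reports only "good conservation",
so this is a free parameter): the replacement is never the original residue
and is drawn ∝ background × exp(λ·BLOSUM62), so similarity degrades more
slowly than identity. Expected identity to the ancestor is exactly
1 − divergence; configs implying < 30 % identity are rejected with a
diagnostic. No indels are introduced — lengths are family properties — so
the < 20 % length test is exercised by family length draws, not per-copy
jitter. Identical configs give byte-identical files.

What a green test does **not** establish: real proteomes have domain
architectures, indels, low-complexity regions, compositional bias and shared
vertical descent, none of which the i.i.d. background models; the synthetic
world measures whether the *pipeline logic* recovers planted structure, not
BLAST-grade sensitivity on real sequences.

## Numerical choices and edge cases

- Score ties in searches resolve toward the lexicographically smallest id;
  all iteration orders are sorted, so runs are reproducible bit-for-bit.
- Gumbel fits use method of moments (no optimizer, deterministic); a
  zero-variance null degenerates to a step function at its mean.
- Windows at replicon edges truncate silently but are flagged; empty reb
  sets yield empty locus lists, not errors; a zero-Reb-taxa survey completes
  with empty patterns and an empty exclusivity report.
- Profile columns with zero occupancy cannot occur for the master itself;
  profiles with zero kept columns raise.

## Known limitations

- The chance gate makes the predicate slightly conservative for genuinely
  homologous pairs near the detection floor (~25 % identity over < 60
  residues).
- Empirical-null searches cost |db| × n_shuffles alignments per seed set;
  defaults (n_shuffles = 30) balance resolution against runtime and rely on
  the Gumbel tail beyond the sampled range.
- The conservation profile is master-anchored; insertions relative to the
  master are dropped, as in profile/HMM coordinate systems.
- min_taxa and min_reb_taxa have no published values; defaults are package
  choices, exposed as parameters.
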