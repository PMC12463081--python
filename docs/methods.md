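# Methods

This note documents the models and procedures implemented in `pcgloop`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and digestion model

All coordinates are 0-based half-open (`[start, end)`, the BED
convention) internally; GFF3 input is shifted by −1 on the start at read
time. A single arithmetic convention keeps every overlap and length
computation uniform, and BED dominates the package's I/O.

In-silico digestion scans each chromosome for exact occurrences of the
recognition sequence (DpnII, `GATC`, by default) and places a blunt cut
immediately 5′ of each occurrence. The enzyme's biological 5′ overhang
does not affect fragment bookkeeping, and the blunt model matches the
fragment maps produced by common Hi-C digestion utilities. Fragments tile
each chromosome exactly (gap-free, non-overlapping, concatenation
reconstructs `[0, length)`); zero-length fragments from a site at
position 0 are dropped. IUPAC ambiguity codes never match the site, so an
`N`-containing region is simply never cut inside the unknown stretch.

Overlap is ≥ 1 shared bp with no reciprocal-fraction requirement
(`min_overlap` is exposed where a stricter threshold is wanted), and all
overlap queries are strand-blind; strand matters only for promoter
construction (the 1,000 bp — configurable — immediately upstream of the
strand-aware gene start).

## Probe placement

Probe count per peak is a step function of peak length `L`:
`L < 300 → 1` probe at the center; `300 ≤ L ≤ 500 → 2` at ⌊L/3⌋ and
⌊2L/3⌋; `L > 500 → 3` at ⌊L/4⌋, ⌊L/2⌋, ⌊3L/4⌋. The boundary reading is
the only one under which the three clauses partition all lengths.
Fractional positions are floored for determinism; a probe interval is
`[center − ⌊p/2⌋, center + ⌈p/2⌉)` for probe length `p` (default 100 bp),
giving exactly `p` bases when unclipped. Probes overhanging a short
region are clipped to the region and flagged rather than discarded, so
sub-100-bp peaks still receive their probe. Bait chemistry
(biotinylation, complementarity) is metadata; the analysis consumes
coordinates and, optionally, extracted sequence.

## Loop classification and the PcG hub

Bait fragments are typed `only_H2Aub` or `H2Aub_H3K27me3` by H3K27me3
peak overlap. Loops with two bait anchors are Bait-Bait, with exactly one
Bait-Nonbait; zero-bait loops cannot be captured by the probe design and
are dropped with a logged count. The three-way class follows from
bait-anchor composition: *Both* (one only-H2Aub bait + one co-marked
bait), *only-H2Aub* (all bait anchors only-H2Aub), *H2Aub/H3K27me3*
(≥ 1 co-marked bait anchor, no only-H2Aub bait anchor).

Hub membership uses **one-step anchor sharing**: the seed set is every
anchor of a Both-loop, and a loop is a hub member iff it shares ≥ 1
anchor fragment (bait or not) with that seed set. This is the literal
reading of a hub "started" by Both-loop anchors; `transitive=True`
computes full connected components of the anchor-sharing graph for
comparison, and `bait_anchors_only=True` restricts the sharing test to
bait anchors. Both-loops are hub members by definition, so the five final
classes (hub Both / hub only-H2Aub / hub H2Aub-H3K27me3 / Pure
only-H2Aub / Pure H2Aub-H3K27me3) partition every classified loop set —
asserted on every run.

An opt-in refinement (`nonbait_k27`) classes a Bait-Nonbait loop whose
non-bait anchor overlaps an H3K27me3 peak as H2Aub/H3K27me3 — "at least
one anchor is an H3K27me3-enriched region" — with a transparency flag.
It is off by default so the bait-anchor-only three-way partition holds
exactly.

Loop length is the distance between anchor-fragment midpoints: symmetric,
robust to fragment-size differences, and never zero since anchors differ.
Trans-chromosomal pairs are flagged (NaN) and excluded from length
statistics. The per-gene loop span takes the loops anchored on a gene,
splits the *other* anchors by genomic side, and reports the maximum
pairwise distance among each side's midpoints (a single anchor gives span
0; fewer than two loops give no record); a `from_gene` option measures
the maximum distance from the gene edge instead, since the span wording
admits both readings. Anchor feature annotation uses precedence
exon > intron > promoter > intergenic on ≥ 1 bp overlap; a precedence
order is required because a fragment-sized anchor routinely overlaps
several features.

## Mutant comparison

Loop identity is the unordered canonical anchor-fragment pair, so
WT/mutant matching is exact set algebra: disappeared ∪ maintained = WT
loops and maintained ∪ new = mutant loops, disjoint by construction.

A fragment's histone-modification change is the mutant/WT ratio of
length-weighted mean occupancy, called *decreased* when
`log2(ratio) < −0.2` — the absolute-log2-fold-change-above-0.2 convention
of differential-binding callers, with the decreasing sign. A supplied
differential-region BED can override computed calls. A loop is `Hl` when
≥ 1 of its bait anchors is decreased for a relevant mark: only-H2Aub
loops consult H2Aub only; H3K27me3-involved loops consult either mark.
Whether one or both anchors must be affected, and whether non-bait
anchors count, are genuinely open readings; the defaults (≥ 1 bait
anchor) are exposed as `both_anchors` / `include_nonbait` switches.
Anchors without change records count as maintained, with a warning.

The 2×2 loop-fate × HM-fate association uses Pearson chi-squared without
continuity correction by default (Yates is configurable; at the table
sizes of interest the correction is immaterial), plus an odds ratio with
a Haldane–Anscombe 0.5 correction when any cell is zero. A zero marginal
leaves the test undefined and flagged rather than silently 1.0.

## Occupancy enrichment

Per-region occupancy is `Σ(value × overlap_bp) / region_length`:
uncovered bases count as 0. The `covered` mode (divide by covered bases
only, the `bedmap --wmean` dialect) is implemented as an alternative;
full-length is the default because it is the conservative choice when
coverage is sparse and the upstream tool's exact dialect cannot be
assumed. Random regions are count- and length-matched to the targets and
placed uniformly over the allowed genome space (an interval is chosen
with probability proportional to its feasible start positions); matching
on GC or chromosome is not attempted. One random draw per invocation is
the default null, with `n_permutations` for an empirical null. The score
is `log2((target_mean + ε)/(random_mean + ε))` with
ε = 10⁻³ × the track's genome-wide mean, keeping scores finite when a
small random set lands entirely off-signal. Significance is a two-sided
Mann–Whitney U on per-region occupancies, corrected across the marks of
one invocation by Bonferroni–Holm; `ns` iff adjusted p > 0.05, otherwise
the sign of the score decides enriched/depleted.

## Expression linkage

Bait regions fall into six disjoint groups: loop status (PcG hub if the
fragment anchors ≥ 1 hub loop, else Pure if it anchors any loop, else
Nonloop) crossed with bait class. Genes attach to a group on ≥ 1 bp
gene-body overlap with the fragment; a gene touching several groups is
assigned by precedence hub > Pure > Nonloop (co-marked before only-marked
within a status) to keep the group gene sets disjoint. Expression bins
default to a zero bin plus quartiles of the nonzero values, since no
canonical binning exists for such proportion plots; the edges are
configurable. Differential-expression labels are always inputs — the
upstream thresholds (adjusted p < 0.05, |log2FC| ≥ 1) travel as metadata
— and the per-fate-cell fraction of up-regulated genes is reported with
its gene counts, `NaN` for empty cells.

## Synthetic data: what is emulated, what is not

The generator plants, per seed, exactly the structure the pipeline
claims to recover:

- **Genome** — 2 chromosomes × 400 kb by default, with GATC gaps drawn
  geometric with mean 260 bp (the genome-average DpnII spacing scale),
  filler sequence guaranteed free of spurious sites, so the digest
  reproduces the planted fragment boundaries exactly (~3,000 fragments).
- **Peaks** — 400 H2Aub peaks, each strictly inside one fragment of
  ≥ 150 bp so the bait set equals the planted fragment set; 40% co-marked
  with H3K27me3; 100 H3K27me3-only peaks on separate fragments.
- **Loops** — 150 Both-loops seed the hub, 320 hub-attached loops share a
  seed anchor (partner class matched to the seed so no accidental
  Both-loop arises), 30 + 20 Pure loops drawn from anchor pools kept
  disjoint from the hub pools, giving a hub fraction a little above 90%
  with under 10% Pure. Anchor distances are log-normal with median 25 kb.
  The Bait-Nonbait coin (0.32 per eligible loop; Both-loops are Bait-Bait
  by definition) is drawn once per loop and the placement retried within
  type, so the realized fraction stays binomial even when one pair type
  rejects duplicate pairs more often.
- **Mutant** — HM loss is planned per bait fragment (probability 0.5,
  planted log2 change −1 on the signal tracks), loop-level `Hl` derived
  from the planted fragment plan so hub-shared anchors stay
  self-consistent, and loop loss drawn with P(loss|Hl) = 0.8 vs
  P(loss|Hm) = 0.2; 100 new loops recombine bait anchors or recruit
  fresh non-bait fragments.
- **Expression** — log-normal baseline (ln-mean 2, ln-sd 1, RPKM-like),
  multiplied by 0.5 at H3K27me3-marked fragments and 0.6 at loop-anchor
  fragments; up-label probabilities 0.5 / 0.3 / 0.3 / 0.1 across the
  Ll/Hl, Ll/Hm, Lm/Hl, Lm/Hm cells against a 0.05 background.

Truth tables (planted class per loop, fate per loop, change per fragment,
group and label per gene) are first-class outputs; tests compare against
them and never re-derive truth from the generated files. Identical
config + seed yields byte-identical files (emitted headers carry the tool
version but no timestamp).

The generator does **not** emulate raw reads, ligation junctions, capture
hybridization efficiency, interaction-distance decay within the caller,
peak-boundary noise, partially overlapping peaks and fragments, or
mappability structure. Passing tests therefore demonstrate the
correctness of the downstream logic under clean planted structure, not
robustness to upstream calling noise in real data. The default dataset
(520 WT loops on a 0.8 Mb genome) is sized so stable proportions emerge
while the full suite runs in seconds on one CPU; the association and
enrichment studies use 1,000 loops × 100 seeds and 500 target regions
respectively, matching the scales at which their guarantees are stated.

## Numerical conventions and edge cases

- Determinism everywhere: every stochastic routine takes an explicit
  seed or `numpy.random.Generator`; the pipeline manifest records config
  hash and input checksums, never wall-clock-derived seeds.
- Degenerate inputs: empty chromosomes digest to nothing (warning);
  regions on chromosomes absent from a signal track score 0 occupancy
  (warning); absent from a fragment map they raise, naming the
  chromosome, since that indicates a genome mismatch.
- Ties and ordering: anchor pairs are stored lower-fragment-id first;
  probe centers are floored; quantile bin edges are deduplicated when
  expression values tie.
- The upstream interaction caller's weight parameters are carried as an
  inert configuration block for provenance; they are never used in
  computation here.

## Known limitations

- The hub definition is one-step sharing from Both-loop anchors; the
  transitive variant can only enlarge the hub, and both are exposed
  because the narrative definition does not fix the closure.
- Gene-to-region assignment ignores promoter overlap (gene body only);
  promoters matter only for anchor feature annotation and probes-per-gene.
- Enrichment random sampling is length-matched but not GC- or
  chromosome-matched.
- BigWig and .hic/.cool binary formats are out of scope; signal comes in
  as bedGraph.
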