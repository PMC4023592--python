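# Methods

This note documents the models and procedures implemented in `cslmine`,
their assumptions, the parameters that matter, and the places where a
design was genuinely open and a choice had to be made.

## Pipeline model

The package codifies a homology-first mining strategy for the CesA/Csl
superfamily in short-read data. Its central assumptions are:

* family membership is decided **phylogenetically**, by placement relative
  to a pre-classified reference panel, not by best-hit labels alone;
* sequencing errors — in particular frameshift-inducing indels typical of
  pyrosequencing reads — are handled at the **alignment/translation**
  stage, not the assembly stage;
* all thresholds that matter downstream are the conventional ones:
  best-hit E < 1e-10, domain E < 1e-2, peptide length > 150 aa (100 and
  200 as documented alternates), overlap > 60 nt at > 97% identity,
  support ≥ 0.70.

## Frameshift-tolerant translated alignment (`fsalign`)

A Smith–Waterman-style local DP over (nt consumed, aa consumed). Moves
consuming one subject residue:

| move | nt | emitted | score |
| --- | --- | --- | --- |
| codon | 3 | amino acid or `*` | BLOSUM62, or `stop_score` (−5) for stops |
| +1 frameshift | 4 | `/` then the amino acid | best delete-one triplet + `frameshift_penalty` (−15) |
| −1 frameshift | 2 | `\` then the amino acid | best dinucleotide-compatible residue + `frameshift_penalty` |

plus affine gaps on either side (first column −11, then −1 per column;
a gap column on the query side consumes one subject residue, on the
subject side three nucleotides). Both strands are searched; minus-strand
coordinates refer to the reverse-complemented query. Alignment identity
is the match fraction over columns where both sides are amino acids.

**Error-tolerant frameshift codons.** The contiguous triplet around a
1-nt indel does not contain the original codon, so a fixed reading would
corrupt exactly one residue at every mid-codon indel. Instead, a 4-nt
window is scored as the best of its four delete-one triplets and a 2-nt
window as the best amino acid whose codon contains the observed
dinucleotide in order. Because BLOSUM62 diagonal entries strictly
dominate their rows, aligning an indel-bearing read against the protein
it came from recovers the original residue exactly; this is what makes
the healing round-trip exact. A frameshift closer to a read end than the
penalty can recoup (~5 codons) is indistinguishable from alignment
truncation for any local aligner, so the round-trip fixture plants
indels at least 18 nt from either end.

**E-values.** `E = K·(m/3)·n·exp(−λS)` with K = 0.1 and λ = 0.27 per
score unit (roughly the gapped BLOSUM62 −11/−1 regime). Only the
threshold crossings at 1e-10 / 1e-2 / the pre-screen cap are consumed,
and the model is strictly monotone in score, so the exact constants only
shift the effective score cutoffs. The pre-screen cap for reads defaults
to 1e-3; contig re-search uses a permissive cap of 1.0 and leaves
rejection to the qualification filters.

**Implementation.** The production DP is row-vectorized over a
sentinel-separated concatenation of the panel (score-only pass), with a
full traceback pass run only for each query's best subject. The
test-suite holds the DP to exact score equality with an independently
written top-down recursion on hundreds of random instances, and
validates the recursion itself against exhaustive path enumeration on
micro instances; emitted alignments are re-scored column by column.

## Greedy overlap assembly (`asm`)

Reads are merged best-overlap-first: an overlap is an **ungapped**
suffix–prefix match (both orientations) of length strictly greater than
`min_overlap` (60) at identity strictly above `min_overlap_identity`
(0.97); merge order is fully determined by (identity, length, unit-id
pair), making the result invariant to input order. Consensus is
per-column majority with ties resolved by the earliest-offset member.

Keeping overlaps ungapped is a deliberate simplification: a read whose
indel falls inside the mutual overlap will not merge there, so indel-rich
read sets under-assemble into several contigs per transcript, and the
single-covered stretches of a contig retain their reads' indels. Both
effects are accepted because the downstream frameshift-healing stage is
the component assigned to error tolerance, and the pipeline's
conclusions are qualitative (which families are present), not
quantitative. Assembly is per species; the caller groups reads.

## Healing, profiles and filters (`extract_filter`)

Healed translation deletes `/`, `\`, `*`, `-` from the aligned query
string of the best hit — nothing else. Filters, all strict inequalities:

1. best-hit E-value < 1e-10;
2. both domain profiles matched at E < 1e-2 (an either-domain mode is a
   config switch; both-required is the default);
3. length > 150 aa (alternates 100/200), with an explicit allowlist as
   the only rescue path for shorter peptides.

Domain profiles are per-column log-odds matrices over the 20 amino acids
(pseudocount 1.0, uniform background 1/20, scores floored at −10;
columns more than half gapped are dropped). A peptide is scored by the
best ungapped placement, profile overhang allowed down to 10 overlapping
columns; X scores 0. Significance is calibrated per peptide against
≥ 1000 of its own residue shuffles: the reported E is the expected count
of null scores at or above the observed one, extrapolated beyond the
sample with an exponential (mean-excess) tail fitted to the top decile.
This reproduces the one thing the filter consumes — a significance
threshold — without re-implementing profile-HMM statistics.

## Phylogenetics (`phylo`)

* **MSA** is delegated to MAFFT; L-INS-i (`--localpair --maxiterate
  1000`) is the default, G-INS-i available (it places terminal gaps
  optimally on very short fragments). The module verifies that every row
  degaps back to its input.
* **Distances**: p-distance over shared non-gap columns, Poisson
  corrected (−ln(1−p), p capped at 0.95). A pair with no shared columns
  is an error by default; the pipeline and the bootstrap use a capped
  mode instead, since column resampling and fragmentary peptides can
  produce such pairs legitimately.
* **Neighbor joining**, hand-written with an explicitly deterministic
  tie rule (smallest index pair under the current ordering) and negative
  branch lengths clamped to zero with the deficit moved to the sibling
  edge. NJ recovers additive matrices exactly; the suite checks this
  against randomly generated trees and cross-checks topologies against
  scikit-bio's implementation on noisy matrices.
* **Supports** are column-bootstrap proportions: the fraction of
  resampled-column NJ trees containing each bipartition of the original
  tree (default 1000 resamples, seeded). This replaces approximate-ML
  trees with resampled local support tests; only the 0.70 display/
  decision threshold is consumed downstream, and the replacement is
  documented rather than claimed equivalent.
* **Newick** serialization keeps branch lengths and supports (as
  internal labels) at full precision and round-trips losslessly through
  the package's own parser; labels with metacharacters are quoted.

## Classification (`classify`)

All decisions are made on bipartitions of the unrooted tree, so they are
invariant to rooting and leaf order. A family's **core clade** is the
smallest supported edge side containing all of the family's reference
leaves and none of any other family's (on an unrooted tree a *maximal*
pure side is degenerate — the complement of any other family's clade is
pure — so maximality cannot define the clade). Verdicts, in order:

1. **member** — the leaf lies inside exactly one family core;
2. **novel_cluster** — the leaf belongs to a supported clade of at least
   `min_novel_cluster_size` (default 3) query-only leaves; checked
   before the joining rule so a well-supported query-only cluster beside
   a family is reported as novel rather than absorbed;
3. **member by joining** — a supported edge groups the leaf with exactly
   one complete family and nothing from any other family (the smallest
   such side decides; several equally near families yield a basal set);
4. **basal** — the nearest supported reference-containing side holds one
   or more complete families;
5. **unclassified** otherwise.

The occurrence matrix marks `+` for any member verdict and `?` for
basal-only evidence, `+` overriding `?`. The minimum novel-cluster size
of 3 is a package default, not an inherited rule.

## Synthetic data (`simdata`)

The generator emulates a multi-species short-read mining study at desk
scale. Default study conditions: 6 families × 4 reference and 4 sampled
species, 300-aa proteins, within-family identity 0.80 and between-family
identity 0.35, 400-nt reads at 10× coverage, substitution rate 0.01/nt,
indel rate 0.005/nt (lengths 1–2 nt, every one frameshift-inducing),
1,000 decoy reads (half uniform-random, half shuffled transcript
windows). All generators are bit-reproducible from `(config, seed)`.

Design details worth knowing:

* **Identity targets.** A common ancestor is mutated into family
  ancestors and then species copies. Retentions are solved from
  r² + (1−r)²/19 = target, and the ancestor→family retention is deflated
  by the within-family retention so that *species-level* cross-family
  pairs hit the between-family target; recovered identities land within
  ±5 points of targets at 300 aa.
* **Catalytic motif.** The six D,D,D,QXXRW anchor residues are pinned in
  every homologous protein (as they are conserved in real CesA/Csl
  enzymes), so motif scanning behaves realistically; decoys lack it.
* **Domain regions.** The two domain alignments are column slices of the
  panel mirroring real CesA architecture, where the Glycos_transf_2 core
  falls inside the long central Cellulose_synt span: Cellulose_synt from
  0.30·L (up to 100 columns) and Glycos_transf_2 nested from 0.40·L (up
  to 60 columns). Central nesting means any sufficiently long fragment
  of the catalytic core can satisfy the two-domain filter, as with the
  real profiles.
* **Back-translation** uses one fixed codon per residue; codon usage is
  irrelevant to every stage except frame bookkeeping. Reads are tiled at
  evenly spaced starts (count ≈ coverage·T/L), strands drawn at random,
  qualities constant.

What the generator does **not** emulate: homopolymer-specific error
profiles, expression-level bias between genes, transcript length
variation and alternative isoforms, domain gain/loss, and compositional
biases of real genomes. Passing tests therefore demonstrate that the
machinery is correct under its stated statistical structure — not that
real archives would yield the same recovery rates.

## Numerical and reproducibility choices

* One seed drives every stochastic stage; per-read and per-peptide RNG
  streams are derived via CRC32 of the record id so outputs do not
  depend on processing order. Repeated runs are byte-identical.
* All intermediate files are plain text with sorted, deterministic
  ordering; floats are printed at fixed or full (`repr`) precision.
* Exact float equality is used inside the DP traceback (values are
  recomputed identically) and the NJ Q-matrix is formed symmetrically
  (r_i + r_j before subtraction) so that argmin tie-breaking is
  well-defined.
* Problem sizes used in the packaged checks: 200 random oracle
  instances (≤ 40 nt × ≤ 14 aa), 500 healing round-trips, 100 additive
  NJ matrices (≤ 12 taxa), the default study for end-to-end scoring,
  and a 3 × 2-family reduced study for the byte-determinism check —
  sizes chosen to keep a full verification run in the minutes range on
  one core.

## Known limitations

* The assembler's ungapped overlaps under-assemble indel-rich data by
  design; contig counts are not biologically meaningful.
* Profile E-values are calibrated per peptide against shuffles of that
  peptide; they are comparable across peptides only in the threshold
  sense the filters use.
* The E-value model's constants are fixed, not fitted per search; the
  model is monotone in score, so recalibration would only shift the
  effective score thresholds.
* Classification requires the reference panel to be present on the tree;
  families whose references are paraphyletic there are reported
  unresolved rather than guessed.
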