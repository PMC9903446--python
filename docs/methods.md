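# Methods

This note documents the models, conventions and design choices behind
`cmschimera`, in the order the pipeline runs.

## Survey model and synthetic data

The package targets surveys of a chimeric mitochondrial CMS locus whose
architecture is B-*atp6* (619 bp) + DS (52 bp) + VS (176 bp) + GSV ORF
(~214–240 bp). The synthetic generator (`cmschimera.synthetic`) builds a
reference chimera honouring the locus landmarks:

- B-*atp6* starts with the junction motif `GGGCGGGGG` and ends `TGAGTAA`;
- DS starts `TTTCATAA` and ends with the mirror motif `GGGGGCGGG`
  followed by `ACAAA`, closing a 671 bp conserved block;
- the GSV begins with `ATG`, its first 34 bases form the COXII prefix,
  and its codons are drawn stop-free so the ORF translates cleanly;
- all other positions are uniform random bases from a single seeded
  stream. The fill is redrawn (deterministically) if a spurious copy of
  either junction motif arises, so the mirror pair occurs exactly once
  each — this makes motif-recovery checks exact.

The default GSV length is 214 bp rather than the full 240 bp ORF because
the surveyed amplicons did not cover the last 26 bases; which end is
trimmed is exposed as a choice rather than hard-coded (the generator
plants the prefix-anchored convention: the COXII prefix and ATG are
always present). Full-length 240 is available via `gsv_length`.

The default survey design mirrors the study: 17 populations, of which
PS and GZ carry haplotype H1 (15 sequenced individuals each), TL and HK
carry H2 (15 each), YJ carries H3 (5), and 12 populations are
assay-negative and emit atp6-only records — absence of the chimera is
data, not an error. Haplotypes are the reference plus planted edits:
across haplotypes the VS carries 5 indel events (two in H1, three in H3)
and 32 SNP sites (16 in H1, 16 in H3, disjoint, none under an indel
footprint), matching the reported "five indels, >30 SNPs" character of
the spacer; the GSV carries a small synonymous/nonsynonymous SNP mix so
nucleotide and protein haplotype counts differ in a known way. Edit
positions refer to the *unedited* reference and are applied
right-to-left, so a deletion never shifts a later SNP.

What the generator does **not** emulate: PCR/sequencing error, chimeric
reads, within-population polymorphism, recombination, or realistic base
composition. Passing round-trip tests therefore demonstrates pipeline
correctness on clean data with known truth, not robustness to noisy
field data.

## Haplotypes, identity, variable sites

Haplotype equality is exact string match after upper-casing (optionally
after trimming leading/trailing missing states); near-duplicate
clustering is deliberately out of scope because the survey collapses
identical amplicons. Labels rank by descending member count with ties
broken lexicographically by representative sequence — a pure function of
the input multiset. Note the rank convention means the planted "H1" and
the recovered "H1" may swap between the two equally sized 30-member
classes; tests compare count structures, not label identity.

Percent identity uses Needleman–Wunsch global alignment with match +1,
mismatch −1, linear gap −2 and *penalised* end gaps. Among co-optimal
alignments the traceback is "high-road" (diagonal, then up, then left),
making the reported alignment deterministic. The identity denominator is
the full alignment length including gap columns (the common "global
alignment identity" convention, which reproduces whole-number published
identities); dividing by the shorter sequence length is available via
`denominator="shorter"`. Identical columns of missing states do not
count as matches, so 100% identity occurs iff the sequences are
identical.

Variable-site matrices report 1-based columns with ≥ 2 distinct
non-missing states; "." = same as the designated reference row, "?" =
unknown. "N" and "?" are both missing; gaps are ordinary states there
(an indel column is variable).

## Structure annotation

Anchor segments (B-*atp6*, DS, optionally a GSV reference or the COXII
prefix) are located by semi-global (infix) alignment using edlib's
edit-distance aligner with an identity threshold (default 0.95,
implemented as an edit-distance cap ⌊(1−0.95)·|ref|⌋); exact substring
hits short-circuit the aligner. Edit distance slightly differs from the
±1/−2 scoring used for percent identity, but at the ≥95% identity
regime the located interval is the same and the infix search is linear
in practice. A query legitimately lacking a segment (a non-carrier
individual) yields a "missing" annotation, never an exception, so one
annotator serves carriers and non-carriers. The VS is derived as the
interval between the DS end and the GSV start; when only the COXII
prefix is given, the GSV start is the first ATG at or after the prefix
match. B-*atp6* length is fixed at 619 bp throughout.

Mirror-motif scanning reports exact occurrences of a motif and of its
character reversal (a *mirror* repeat, not a reverse complement),
overlapping hits included; motifs shorter than 5 bases are rejected as
uninformative, and self-mirror motifs are deduplicated.

The VS variation catalog counts an **indel event** as a distinct maximal
gap-column interval pooled across rows (two rows sharing the same gap
pattern contribute one event) and a **SNP site** as a gap-free column
with ≥ 2 distinct non-missing states. Because "five indels" could also
be read as gap columns, the catalog reports `n_gap_columns` alongside
`n_indel_events`. Exact event counting presumes the alignment preserves
the planted gap intervals; the pipeline uses the generator's exact
alignment when available and a center-star progressive alignment (a
convenience wrapper around pairwise NW, not a fidelity target)
otherwise.

## Translation

Standard genetic code (table 1 by default, switchable): plant
mitochondria use the standard code for these codons and no C→U RNA
editing is modelled. Internal stops render `*` and translation
continues; codons containing missing states or gaps render `X`; a
trailing partial codon is dropped. Protein haplotypes group nucleotide
labels by identical translation, sorted by group size then smallest
member label.

## AMOVA

Two-level analysis of molecular variance for haploid data. Sums of
squares come from pair sums of squared distances; degrees of freedom are
(G−1, P−G, N−P); variance components use the standard weighted
sample-size coefficients

    n′  = (N − Σ_g Σ_{p∈g} n_p²/n_g) / (P − G)
    n″  = (Σ_g Σ_{p∈g} n_p²/n_g − Σ_p n_p²/N) / (G − 1)
    n‴  = (N − Σ_g n_g²/N) / (G − 1)

with Vc = SS_WP/(N−P), Vb = (MS_AP − Vc)/n′, Va = (MS_AG − Vc − n″Vb)/n‴.
Degenerate designs are handled explicitly: one group ⇒ single-level
analysis (Φ_CT undefined, Φ_ST = Φ_SC); one population per group ⇒ the
among-populations-within-groups level vanishes (Vb = 0); zero total
variance ⇒ Φ statistics undefined and p-values skipped.

The default distance is **haplotype-binary** (d² = 1 between distinct
haplotypes, 0 otherwise). This choice reproduces the published survey
table exactly (SS 3.462/15/0 with N = 65); squared
nucleotide-difference distances (`mode="nt_differences"`) rescale the
components and are available as the alternative.

Permutation p-values are inclusive, (k+1)/(n+1), counting permuted
statistics ≥ the observed one (within 1e-12), so a statistic exceeded by
no permutation reports p = 1/(n+1), never 0. The three schemes are the
standard ones: individuals among populations (Φ_ST), individuals among
populations within groups (Φ_SC), whole populations among groups (Φ_CT).
Records are canonicalised by sorted id before permuting, so p-values are
reproducible under a fixed seed and invariant to input order.

**A design limit worth knowing:** with P populations split into groups
of sizes (1, P−1), the population-permutation null for Φ_CT has only P
distinct arrangements and reproduces the observed grouping with
probability 1/P. The inclusive p-value therefore has a floor near 1/P
(≈ 0.2 for the five-carrier survey design) regardless of effect size —
a well-known property of few-population two-level designs, not an
implementation artifact. Φ_SC and Φ_ST are unaffected.

## Phylogeny

HKY85 with stationary frequencies π and transition/transversion rate
ratio κ; the rate matrix is scaled so the mean substitution rate is 1
(branch lengths in expected substitutions per site). Transition
probabilities come from the symmetrised eigendecomposition
P(t) = D^(−1/2) U e^(Λt) Uᵀ D^(1/2) (exact for any reversible model;
matches the JC69 closed form to < 1e-10 at κ = 1, equal π). Likelihoods
use Felsenstein pruning over unique site patterns; gaps, `N` and `?` are
missing states marginalised over all four bases. Trees are unrooted,
stored with an arbitrary trifurcating root; the likelihood is invariant
to that choice.

The search starts from a neighbor-joining tree (scikit-bio's NJ on
Jukes–Cantor distances; labels sorted for deterministic ties; negative
branch lengths clamped to 0) and alternates: per-edge branch-length
optimization by bounded Brent (tolerance 1e-6, bounds [1e-9, 20]), κ
optimization likewise (bounds [0.05, 100]), and evaluation of all NNI
rearrangements with the best improving move accepted. It stops when a
full round gains ≤ 1e-8 log-likelihood; the log-likelihood never
decreases. Base frequencies are empirical counts (missing excluded,
floored at 1e-8); κ initialises at 4. Bootstrap supports resample sites
with replacement, rebuild each replicate by NJ plus branch-length-only
polish, and report the fraction of replicates containing each internal
bipartition of the point tree.

Fidelity surface: the module is validated against an exhaustive
ancestral-state-summation oracle on small instances, closed forms, and
simulation recovery (the 6-taxon, 1000-site recovery check used in the
test suite); reproducing any particular published tree topology or
support values is not a goal — those depend on alignment and search
minutiae of other software. Gamma rate heterogeneity, other substitution
models and SPR/TBR moves are out of scope.

## Problem sizes and numerical choices

Tests and the acceptance script run the survey at its published size
(65 chimera records, 17 populations, 1000 permutations), likelihood
oracles at 3–4 taxa × ≤ 5 sites, and topology-recovery simulations at 6
taxa × 1000 sites × 20 replicates — sizes chosen so the full suite
completes in about a minute while exercising every code path. SS
additivity is maintained to 1e-9; identity and AMOVA comparisons in
tests use the precision the published values are printed at.
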