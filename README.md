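# cmschimera

Analysis toolkit for surveys of the chimeric mitochondrial cytoplasmic male
sterility (CMS) locus **B-*atp6*-*orfH79*** in wild rice (*Oryza
rufipogon*). Gametophytic CMS in rice is caused by a family of
mitochondrial open reading frames (*orf79*, *orfH79*, *L-orf79* and the
W-series variants, collectively "GSV") that sit at the 3′ end of a chimeric
region: a duplicated *atp6* copy (B-*atp6*, 619 bp) plus a conserved 52 bp
downstream segment (DS) — a 671 bp conserved block — followed by a 176 bp
indel- and SNP-rich variable spacer (VS) and then the GSV ORF itself, whose
first 34 bases match cytochrome oxidase subunit II (COXII). The junction of
the conserved block is flanked by a *mirror* repeat (GGGCGGGGG … GGGGGCGGG
— character reversal, not reverse complement), the putative signature of
independent chimera formation.

The package is written for population geneticists who survey such loci: it
collapses sequenced individuals into haplotypes, annotates the chimeric
architecture, translates the ORF, partitions molecular variance
hierarchically, and infers a maximum-likelihood phylogeny — and it ships a
synthetic-data generator that reproduces the survey design (17 populations,
5 carriers, 65 sequenced chimera-positive individuals) so the entire
pipeline runs and is testable offline.

## Methods at a glance

**Hierarchical AMOVA.** Squared pairwise distances d²ᵢⱼ (by default 0/1 for
same/different haplotype) are partitioned into variance components via
pair-sum sums of squares, SS(S) = (1/|S|) Σ_{i<j∈S} d²ᵢⱼ, at three levels:
among groups (Va), among populations within groups (Vb) and within
populations (Vc), using the standard weighted sample-size coefficients
n′, n″, n‴. Fixation indices follow as

    Φ_CT = Va/(Va+Vb+Vc),  Φ_SC = Vb/(Vb+Vc),  Φ_ST = (Va+Vb)/(Va+Vb+Vc)

with significance from non-parametric permutation (1000 permutations by
default; p = (k+1)/(n+1), counting permuted statistics ≥ observed). Each
index has its own permutation scheme: individuals among populations
(Φ_ST), individuals among populations within groups (Φ_SC), whole
populations among groups (Φ_CT).

**Phylogeny.** HKY85 substitution model (transition/transversion ratio κ,
unequal base frequencies π, rate matrix scaled to one expected substitution
per site), Felsenstein pruning over site patterns, neighbor-joining start,
then alternating branch-length optimization (bounded Brent), κ
optimization and nearest-neighbor-interchange moves; optional site-resampled
bootstrap supports.

**Sequence layer.** Exact-match haplotype collapsing; variable-site
matrices in dot notation ("." = same as reference, "?" = unknown);
Needleman–Wunsch global-alignment percent identity (match +1, mismatch −1,
gap −2, identity = identical columns / alignment length); semi-global
anchor location for segment annotation; mirror-repeat motif scanning;
standard-code ORF translation with internal stops kept as `*`.

## Worked example

```python
from cmschimera import (make_reference, published_design, simulate_survey,
                        collapse, distance_matrix, amova)

ref = make_reference(seed=1)                      # 1061 bp reference chimera
survey = simulate_survey(published_design(ref, seed=1), ref)
hapset = collapse(survey.bundle.records)
print(hapset.counts.loc[:, ["PS", "GZ", "TL", "HK", "YJ"]])

d = distance_matrix(survey.bundle.records, assignments=hapset.assignments())
res = amova(d, {r.id: r.population for r in survey.bundle.records},
            survey.bundle.group_map, n_perm=1000, seed=1)
print(res.to_frame().round(5).to_string(index=False))
```

prints

```
    PS  GZ  TL  HK  YJ
H1   0   0  15  15   0
H2  15  15   0   0   0
H3   0   0   0   0   5
            Source of variation  d.f.  Sum of squares  Variance components  Percentage of variation  Fixation index       P
                   Among groups     1         3.46154              0.16667                 33.33333         0.33333 0.21279
Among populations within groups     3        15.00000              0.33333                 66.66667         1.00000 0.00100
             Within populations    60         0.00000              0.00000                  0.00000         1.00000 0.00100
                          Total    64        18.46154              0.50000                100.00000             NaN     NaN
```

The census shows the survey design: three haplotypes, two shared by two
populations each (15 sequenced individuals per population) and one private
to YJ (5 individuals); labels rank by total count, so the two 30-member
haplotypes are H1/H2 and the private one is H3. The AMOVA table partitions
all variance between populations — none within (Vc = 0, hence Φ_ST = Φ_SC
= 1 with p = 1/1001) — and a third of it among the two groups
(Φ_CT = 0.33333). The Φ_CT permutation p-value (≈ 0.21) reflects a design
limit, not a computation artifact: with five populations split 1|4 there
are only five distinct group reassignments, so the population-permutation
null can never push p below ~0.2 (see `docs/methods.md`).

The same stages are available from the shell:

```bash
cmschimera simulate --seed 1 --out run/
cmschimera amova run/chimera.fasta --group-map run/groups.tsv --seed 1
cmschimera run-all --seed 1 --out run/
```

## Layout

| module | contents |
| --- | --- |
| `cmschimera.io` | FASTA / TSV map / Newick reading and writing |
| `cmschimera.synthetic` | reference chimera, planted haplotype edits, survey simulation, HKY85 sequence simulation on trees |
| `cmschimera.haplotypes` | collapsing, variable-site matrices, NW identity, progressive alignment helper |
| `cmschimera.structure` | segment annotation, mirror-motif scan, VS variation catalog, COXII prefix |
| `cmschimera.orfs` | translation and protein-haplotype grouping |
| `cmschimera.amova` | distance matrices, variance components, Φ statistics, permutation tests |
| `cmschimera.phylo` | HKY85 likelihood, NJ, NNI search, bootstrap |
| `cmschimera.pipeline` / `cmschimera.cli` | orchestration and the `cmschimera` command |
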