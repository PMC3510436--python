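# Methods

## Overview

`trnapanel` assesses how well a human mt-tRNA position is conserved across
a fixed panel of species and converts that into a 0/1/2-point score used as
the conservation component of mt-tRNA pathogenicity scoring. The package
also computes the intra-species statistics that justify representing each
species by a single reference sequence, and the exact test comparing
observed stem/loop variation to a proportional expectation.

## Coordinates, strands and variant projection

All genomic coordinates are 1-based inclusive, matching the rCRS "m."
numbering used in variant notation. Gene sequences are always handled on
the sense (tRNA-coding) strand. A variant `m.<pos><ref>><alt>` states its
alleles on the mtDNA heavy strand; when the target gene is encoded on the
light strand, the position is mirrored (`offset = end − pos + 1`) and both
alleles complemented before any comparison. `U` is normalised to `T` on
input, so all comparisons run in the DNA alphabet even when sources use RNA
letters. The reference base of the variant is checked against the actual
reference gene sequence and a mismatch is a hard error — this catches
off-by-one coordinate mistakes before they silently corrupt a score.

## The consensus panel

The bundled panel (`data/panel.yaml`) lists ten species — four primates
(including *Homo sapiens* as the mandatory reference), three other mammals,
chicken, Atlantic cod and fruit fly — each with the GenBank accession of its
reference mitochondrial genome. The source table prints the same accession
(NC_002081) for both *Hylobates lar* and *Gadus morhua*; this is almost
certainly a typographic duplication, and the bundled file preserves it with
a warning comment rather than silently substituting a "corrected" accession
the source never printed. Configuration loading enforces: unique species,
exactly one reference, and the presence of *Homo sapiens*.

## Alignment

Panel gene sequences (~65–75 nt homologues) are aligned with a center-star
construction over Needleman–Wunsch global pairwise alignments (linear gap
penalty; defaults match +1, mismatch −1, gap −2; merging under "once a gap,
always a gap"). Traceback tie-breaking is fixed (diagonal, then gap in the
second sequence, then gap in the first) so outputs are bit-reproducible.
These defaults are adequate for short homologous tRNA genes; they are not a
general-purpose aligner (no affine gaps, no guide tree), and any
pre-computed alignment (aligned FASTA or Clustal) is accepted everywhere an
alignment is, so published alignments can be reproduced exactly.

## Structure annotations

Cloverleaf structure (domain per position, pairing partner per stem
position) is an *input*, not an inference: no folding is attempted.
Annotations are validated for partner symmetry, stem/partner consistency
and contiguity. The package ships curated tables for the three human genes
the worked examples use (MT-TL1, MT-TI, MT-TK), built from canonical
mammalian mt-tRNA cloverleaf geometry at the documented rCRS gene
coordinates; they are marked approximate at single-position resolution in
their headers. Annotations for other genes are supplied by the user or
generated by the synthetic module. Base pairs are classified Watson–Crick
(A:T, G:C), wobble (G·T, the DNA representation of G·U) or other; wobble is
*not* a retained pair by default, with a `wobble_counts_as_paired` switch
because reasonable practice differs.

## Change counts and gap policy

For a variant column, `n_changes` counts non-reference panel species whose
residue differs from the human reference allele. The human row never counts
toward its own change total. Under the default policy a gap in a
non-reference row counts as a change (an indel at the position is evidence
of non-conservation); `gap_is_change=False` ignores gapped rows instead.
The choice is exposed because neither convention is canonical. A gap in the
reference row flags the profile rather than erroring, since a reference
indel means column homology itself is questionable.

## The flowchart and its thresholds

Outside a stem the score depends only on `n_changes`; inside a stem the
position is considered first and then the base pairing of the changed
species. The published description of the flowchart fixes its *shape*
(region first, then count, then pairing; green/yellow/red terminal boxes)
but not the numeric cutoffs, so the defaults here — 0 changes → 2 points;
non-stem 1 change → 1 point, ≥2 → 0; stem changes all compensatory
(paired state retained in every changed species) → 1 point, else 0 — are a
design decision anchored to the three published worked-example scores
(m.3243A>G → 2, m.4269A>G → 2, m.8344A>G → 0), which they reproduce. All
cutoffs are configurable, every report embeds the thresholds used, and each
score carries its full decision path. Whether a natively non-Watson–Crick
reference pair should be treated specially is not recoverable from the
published material; the implementation asks only whether *changed* species
retain a paired state.

## Intra-species metrics

Within one species' sequence set for one gene: `pct_conserved_columns` is
the percentage of alignment columns that are monomorphic, with gaps as a
fifth state; `largest_identical_group` is the share of sequences in the
largest set of exactly identical sequences; `reference_is_major` is true
iff the reference residue is modal at every polymorphic column (ties count
as modal). Sets larger than the sampling cap are reduced to the reference
plus a seeded uniform sample of 34 — the cap under which the original
intra-species survey was performed — and the seed is a required, logged
parameter. The 95% (base conservation) and 80% (largest identical group)
reporting thresholds appear as boolean columns in the summary table.

## Stems-versus-loops test

Observed variation is tallied per domain class: a position is *varying* if
its alignment column is polymorphic (gaps count as a state); each varying
position increments exactly one of stems/loops. The expected tally is
proportional: `e_stem = total × n_stem/(n_stem + n_loop)`, reported
unrounded and rounded. Observed and rounded-expected counts form a 2×2
table tested with a two-sided Fisher's exact test, defined by probability
mass: the sum of hypergeometric probabilities (margins fixed) of all tables
no more probable than the observed one, with a 1e-12 relative tolerance so
exact ties are included despite floating point. Probabilities come from
scipy's hypergeometric distribution; the summation rule is implemented
explicitly so the tie tolerance is under package control, and the test
suite cross-checks against both an exact-rational enumeration oracle (all
tables with total ≤ 40) and `scipy.stats.fisher_exact`. Note the published
observed (78 + 131 = 209) and expected (139 + 68 = 207) counts do not share
a total; the proportional definition here conserves the observed total by
construction, and the two-row-counts reading of the test is the natural but
not uniquely determined construction.

## Synthetic data

The generator emulates the data regime the method operates on, not
mitochondrial mutation processes:

- **Structured tRNAs**: cloverleaf segment layout (acceptor 7 bp, D stem
  3–4 bp, anticodon and T stems 5 bp, loops 5–9 nt, variable region
  4–6 nt, ~65–80 nt total), random loop bases, stems Watson–Crick
  complementary at generation.
- **Species panels**: a star phylogeny — each species independently
  substituted from the root at a per-species rate. Default rates (great
  apes 3%, gibbon 6%, other mammals 15%, chicken 25%, cod 30%, fly 40%)
  mirror the divergence gradient of the real panel. Stem substitutions are
  accompanied by a partner co-substitution restoring Watson–Crick pairing
  with probability 0.9 (compensatory evolution dominates in real stems).
  No indels by default (a flag exists to exercise gap policies), and
  substitutions are uniform over the three alternative bases. Truth logs
  record every changed position, so change counts and tallies are
  recoverable exactly, not statistically.
- **Populations**: individuals mutated from a reference at a per-base
  per-individual rate of 4×10⁻⁴ by default, which makes ~1.4% of positions
  polymorphic in a 35-sequence set — the low-variation regime observed in
  real mt-tRNA sequence sets (~1.3% of bases varying). An optional planted
  haplogroup split gives `round(f·n)` individuals one group-defining
  allele, reproducing the two-identical-groups pattern that
  haplogroup-defining SNPs create (e.g. a 68/32 split at f = 0.32,
  n = 100).

All generators are pure functions of (parameters, seed).

### The worked-example stand-in

`synthetic_worked_example_panel` builds synthetic 10-species panels for
MT-TL1, MT-TI and MT-TK at their genuine rCRS coordinates, conforming to
the curated structure tables, with the three variant contexts planted to
match what the real panel shows: the m.3243 D-loop column and m.4269
acceptor-stem pair fully conserved, the m.8344 T-loop column variable in
most species (the T loop is the most variable region in real cross-species
data). Branch divergence is moderated (capped at 10%) so that column
homology is alignment-robust, as it is for real mt-tRNA genes, and the
construction retries its evolution draw until the star alignment is
gap-free — the generator emits no indels, so position-wise homology is true
by construction and a gapped alignment would be an artefact. These
sequences are **not** GenBank records: the stand-in demonstrates and tests
the full pipeline offline, while `fetch-panel` + `score` perform real
assessments. Consequently, passing worked-example checks shows the pipeline
computes the right score from the right conservation pattern; it does not
re-measure conservation in real genomes.

## What the tests do and do not show

Truth-log recovery, oracle agreement and calibration tests establish that
the implementation counts, aligns, scores and tests exactly as specified
under controlled conditions. The original survey's corpus-wide proportions
(e.g. 250/264 tRNAs with <5% variation, 90% reference-major) depended on an
unrecorded random draw of 2011-era GenBank sequences and cannot be
recomputed; the package instead verifies that the same qualitative pattern
emerges under the generator's default low-variation regime.

## Numerical and design choices

- Deterministic everywhere: fixed alignment tie-breaks, seeded sampling,
  pure-function generators; reports embed a config fingerprint.
- Fisher p-values are clamped to ≤ 1 after summation; zero-total tables are
  errors, not NaNs.
- Degenerate inputs fail loudly: empty FASTA, ragged alignment rows,
  all-gap columns, asymmetric structure pairings, variants outside their
  gene, and reference-allele mismatches all raise with the offending
  values named.
- Problem sizes in the shipped checks (200 aligner oracle pairs, all 2×2
  tables with total ≤ 40, 50 truth-log panels, 200 calibration
  populations, 60 low-variation sets) were chosen to give exhaustive or
  tight-tolerance coverage at interactive runtimes.

## Limitations

- The numeric flowchart cutoffs are anchored to three published example
  scores, not to a published table of cutoffs; other historical panels'
  score *changes* are therefore out of scope.
- The curated structure tables cover the three worked-example genes;
  other genes need user-supplied structure tables.
- The aligner is intentionally minimal; for distant homologues with real
  indels, supply an external alignment.
- No post-transcriptional modification, tertiary interaction or
  thermodynamic information is used anywhere.
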