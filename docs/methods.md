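# Methods

## Scope and model

The package treats a bacterial genome as its protein complement and a
marker panel as a set of COG families. Three layers sit on top of that:

1. **set comparison** — exact set algebra over COG identifier lists;
2. **copy detection** — a per-family position-specific scoring model
   searched locally against every protein, with an E-value threshold and a
   two-tier (strict + rescue) acceptance scheme;
3. **pair similarity** — percent identity of globally aligned marker
   copies, pooled over the panel, summarised as separability at a fixed
   PID threshold.

## Marker sets and fixtures

Marker-set files are plain text, one `COGnnnn` id per line. The seven
bundled literature panels are **synthetic stand-ins**: the original
supplementary membership lists are not redistributed here, so the fixtures
were constructed to satisfy every published summary of them — sizes
31/31/40/40/36/73/120, Ciccarelli ∩ Wu&Eisen = 14, Creevey ∩ Wu = 28,
Creevey ⊇ Ciccarelli, and category J modal in every set. The Creevey-style
panel uses the well-known 40 fetchMG/mOTU marker COGs; identifiers unique
to other panels are plausible translation-apparatus COGs plus clearly
synthetic ids. Conclusions that depend on *which* specific COG is shared
between two panels should not be drawn from these fixtures; all counts
above are faithful. The COG definition table ships in the same
`cog-20.def.tab` dialect (id, category letters, description, gene symbol,
trailing columns ignored) and is likewise synthetic.

Category composition attributes a multi-letter annotation (e.g. `JK`) to
its first letter only, so each gene lands in exactly one bucket and the
J/L/H/O/F/other percentages sum to 100. Overlap percentages are reported
relative to the first-named set.

## Profiles and detection

A profile is built from a seed alignment of family members: columns with
more than 50% gaps are discarded; each remaining match column scores
residue *r* as

    score(r) = log2((f_r + α·bg_r) / ((1 + α)·bg_r))

with observed column frequency *f*, pseudocount weight α (default 1) and
the Robinson–Robinson background *bg*. Scores are floored at −8 so
zero-frequency residues at small α stay finite; `X` and any non-standard
residue scores 0 against every column.

Search is Smith–Waterman over profile columns × protein positions with
affine gaps (open 11, extend 1) and a deterministic traceback (diagonal >
gap-in-protein > gap-in-profile; a new local alignment starts only when
continuing would score negatively; the best cell is the first
strictly-better one in row-major order). Significance uses the ungapped
Karlin–Altschul form `E = K·m·n·exp(−λS)` with the conventional
BLOSUM62-scale constants λ = 0.267, K = 0.041 and *n* = the genome's total
residue count. These constants are not recalibrated to the profile score
scale; genuine marker copies score hundreds of bits above the ~64 needed
at E = 1e-15 while background matches score tens, so the E-value acts as a
thresholding scale with an enormous safety margin, not as a calibrated
significance.

Detection runs in two passes per genome:

* **primary** — proteins are shortlisted by exact 4-mer seeding against
  the profile consensus (≥ 8 shared 4-mers, a BLAST-like heuristic that
  skips decoys cheaply); shortlisted proteins are fully aligned and
  accepted at E ≤ 1e-15 with ≥ 70% profile-column coverage;
* **rescue** — only for genome × marker cells with no primary hit, every
  not-yet-assigned protein is aligned exhaustively (no seeding, no
  coverage floor) at the same E cutoff.

Each protein is assigned to at most one COG — lowest E-value, ties broken
by lexicographic COG id — and a protein assigned by the primary pass is
never reassigned by rescue, which guarantees union counts dominate
primary-only counts cell-wise. Markers lacking a seed alignment are
flagged unsearchable and excluded from summary denominators.

## Occurrence statistics

Universalism of a marker = % of genomes with ≥ 1 copy; uniqueness = % with
exactly 1 copy, both over **all** genomes by default (the
present-genomes-only uniqueness denominator is available as a flag).
Set summaries report mean / population SD / min / median (midpoint on even
counts) / max of the per-marker percentages, separately for primary-only
and union counts.

## Alignment and PID

Pairwise alignment is global Needleman–Wunsch under BLOSUM62 with affine
gaps (a length-*k* gap costs open + *k*·extend, open 11, extend 1) and the
deterministic tie order diagonal > up > left. PID is computed after
deleting indel-versus-indel columns only; remaining indel positions stay
in the denominator. Comparison is case-insensitive and `X` matches `X`.
A zero-length alignment yields a missing datum rather than a number.

Aggregate pair PID defaults to the concatenated-column definition
(Σ matches / Σ aligned positions over the panel — the aligned-length-
weighted mean of per-marker PIDs); an unweighted mean is a flag. When a
genome carries several copies of a marker, the copy pair maximising PID is
used, making the pair statistic an upper bound of the similarity. Both
all-genome-pairs and one-representative-per-species pair enumeration modes
exist; all-pairs is the default. The separability fraction uses strict
`>` at the threshold (default 99.5%).

`min_varied_positions(L, t)` returns the smallest integer *d* with
`(L − d)/L ≤ t`, computed as `L − floor(L·t)` with a 1e-9 guard against
float representation of thresholds like 0.995. It is length-unit-agnostic,
so it applies directly to a nucleotide panel length such as 33,852.

## Synthetic communities

The generator emulates a survey corpus: `n_genera × species_per_genus ×
strains_per_species` genomes, each carrying one (by default) copy of each
of `n_markers` families (default 40, lengths uniform in 200–330 aa, total
panel ≈ 10,600 aa) plus `n_decoys` (default 10) background-frequency
random proteins. Ten decoys per genome keep runtimes desk-scale while
exercising the seeding/rejection path; they are far fewer than a real
genome's thousands of non-marker proteins, so passing tests demonstrate
specificity against random background, not against paralog-rich real
proteomes.

Evolution is per-site substitution with replacements drawn from a
BLOSUM62-conditional kernel (weights ∝ bg_b·2^(S(a,b)/2), identity
excluded) — substituted sites therefore look like plausible exchanges
rather than uniform noise, which keeps profile scoring and decoy rejection
realistic. Divergence parameters are **pairwise** targets: two siblings at
level ℓ should differ at a fraction *t_ℓ* of sites (genus 0.30, species
0.10, strain 0.002 by default, the last two matching the ~90% / ~99.8%
PID regimes). Each branch uses the substitution probability *b* solving

    2b(1 − b) + b²·(1 − p_coincide) = t

where `p_coincide` is the background-averaged chance that two independent
replacements of the same residue coincide. Cross-species genome pairs
additionally carry two strain branches, so their realised divergence is
*t_species* + ~*t_strain* (≈ 0.102 at the defaults, mean PID ≈ 89.8) —
within every tolerance used.

Indels are off by default (divergence targets are defined on
substitutions); when enabled, insertion and deletion events each occur at
`indel_rate/2` per site with geometric (mean 2) lengths. Duplication adds
a second, slightly diverged copy with probability `dup_rate` per genome ×
marker; loss removes the gene with probability `loss_rate` (loss is drawn
first). Seed alignments for profile building are made from the **genus
ancestors only**, never from emitted genomes, so detection tests are not
circular; with indels enabled the ancestors are anchored to the root
sequence's columns via global alignment (insertions relative to the root
are dropped). All outputs are byte-reproducible from the seed.

What the generator does **not** model: codon structure, rate heterogeneity
across sites or lineages, selection, horizontal transfer, paralogous
families related to the markers, and genome misannotation. Synthetic
results therefore validate the pipeline's statistics and thresholds, not
corpus-scale biological values.

## Problem sizes used in tests and the acceptance script

Parameter-recovery runs use the default community (3 genera × 3 species ×
2 strains = 18 genomes, 36 species pairs, 9 strain pairs, panel ≥ 10,000
aa). Detection fidelity additionally uses 25 genera × 5 species × 4
strains = 500 genomes × 40 markers with 1% loss, chosen so the expected
39.6 present markers per genome is estimated with standard error ≈ 0.03.
Statistical assertions use 3-standard-error (or wider) bands around the
planted expectations.

## Numerical choices and degenerate inputs

* Dynamic programs run in compiled (numba) kernels; both are
  cross-checked against exhaustive brute-force enumerators on small
  instances in the test suite, and the global aligner's scores against an
  independent implementation.
* Empty marker-set files, ragged alignments, empty sequences, duplicate
  FASTA ids and zero-genome matrices raise immediately with the offending
  name; ambiguous gene-symbol→COG mappings are reported, never resolved
  silently.
* A pair of genomes sharing zero markers produces a missing aggregate PID
  (reported, not dropped); separability is computed over non-missing
  values.
* All file outputs use 0-based half-open coordinates and tab-separated
  text.

## Known limitations

* The E-value scale is nominal (see above); absolute E-values should not
  be compared with BLAST output.
* The two-pass detector is a functional analogue of an HMM-extractor +
  PSI-BLAST workflow, not a reconstruction of either tool's internals;
  per-source statistics (primary vs rescue) are reported both ways where
  the published row semantics are ambiguous.
* Aggregation of per-marker PIDs into a pair PID and the choice of genome
  pairs per species are both exposed as flags because the canonical choice
  is not fixed in the literature; defaults are concatenated-column PID and
  all genome pairs.
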