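# Methods

## The inference model

For one codon, the evidence is the multiset of profile-HMM consensus
columns that aligned over its genomic occurrences; column i contributes
its match-emission distribution π_i over the 20 amino acids. Twenty-one
hypotheses compete:

* **M_a** (a = one of 20 amino acids): the codon is specifically
  translated as a. Each column contributes likelihood π_i(a).
* **M_0** (non-specific translation): the alignments do not reflect one
  specific residue — pseudogenes, misaligned repeats, composition
  artifacts. Each column contributes Σ_a f(a)·π_i(a), the probability of
  the column emitting a residue drawn from the background composition f.

Columns are treated as conditionally independent given the model, so
log L(M) sums over observations. Posteriors are the softmax of
log-prior + log-likelihood, computed in log space (max subtracted before
exponentiation; −∞ log likelihoods from exact-zero emissions are
legal and simply zero out a model). The decision rule: report the argmax
amino acid iff its posterior ≥ τ, else `?`. M_0 can never be "decided",
and `*` is never emitted — the method does not predict termination
codons, and a sense codon that became a stop leaves no aligned columns
to judge, so sense-to-stop reassignments are invisible by construction.

Two deliberate simplifications: observations are unweighted (no
per-column alignment-confidence factor), and the prior over the 21
models is uniform. With τ = 0.9999 the threshold, not the prior,
dominates behaviour; a caller can supply a non-uniform prior or a custom
background f through `InferenceConfig` (the pipeline default for f is
the mean background of the profile database, which lets a user counter
compositional mismatch between input and profiles by supplying their
own profiles or config).

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| τ (posterior threshold, `-r`) | 0.9999 | confidence required to assign a letter; lower values trade confidence for coverage |
| background f | profile-database mean | composition used by the non-specific model |
| emission floor | 1e-9 | probabilities are floored and renormalised on profile read, so one aberrant column can never be infinitely decisive |
| internal aligner cutoff | 10 bits | minimum log2-odds score for keeping an internal alignment |
| external E-value cutoff | 1e-6 | domain E-value cutoff for `hmmscan` output |

Closed forms used as test anchors: a single point-mass column on amino
acid a gives posterior(M_a) = 1/(1 + f(a)) under a uniform prior;
N point-mass columns give 1/(1 + f(a)^N), which for f(a) = 0.05 first
exceeds 0.9999 at N = 4; uniform columns give 1/21 for every model; an
empty observation set returns the prior.

## Alignment

### Internal Viterbi aligner

A standard profile state machine — match/insert/delete per consensus
column — aligned locally: entry and exit are uniform over the K columns
(cost log2(1/K) each), flanking residues are free, insert states emit
the background (log-odds 0). The score is the log2-odds of the path's
match emissions against the background plus transition log
probabilities. The returned score is the bit score; no E-value
calibration is attempted, so internal filtering is by bit score.
Residues outside the 20-letter alphabet (`X` from ambiguous bases, `*`
from standard-code stops inside a frame) are barred from match states
but may sit in inserts or flanks: allowing a match state to consume a
`*` would presuppose the very decoding being inferred.

The delete chain inside the dynamic program is evaluated as a max-plus
prefix scan (a cumulative-max over column-indexed terms), which keeps
the per-residue step vectorised over columns. Correctness is certified
against exhaustive path enumeration — an independent recursive oracle
that scores every legal local path — on random instances with ≤4
columns, ≤6 residues and per-node random transitions (the random
transitions are what catch off-by-one node indexing).

The internal aligner reports the single best local alignment per
(profile, frame) pair. Multi-domain targets are the external aligner's
job; the synthetic bundles place one gene per contig so nothing is lost
at desk scale.

### External aligner

`hmmscan` is driven via subprocess with `--notextw`; per-domain
alignment blocks are parsed by walking the aligned profile/target
strings (profile `.` = insertion, target `-` = deletion; everything
else is a match correspondence). Fan-out over N workers splits the
translation FASTA into contiguous chunks of whole sequences and
concatenates results in input order, so the worker count never changes
the output. Profile files written by this package carry placeholder
STATS calibration lines — enough for HMMER to run, but the E-values it
prints for them are uncalibrated; filtering such runs by bit score is
the sensible choice.

## Observation processing

Match correspondences map back to genomic codons through frame/strand
arithmetic (coordinates are 0-based forward-strand codon starts
internally). Codons containing non-ACGT characters are skipped — the
conservative reading of ambiguous bases. Filters, in order: profile
exclusion list (the shipped template is empty; real screens exclude
families that commonly pseudogenize, such as mobile genetic elements,
and organellar families), significance threshold, then overlap
resolution: when two same-strand segments claim the same genomic codon,
the higher-scoring segment keeps it (ties: earlier segment). This
prevents one locus aligned by several profiles from being counted as
several independent observations — the paralog/pseudogene pile-up
failure mode. Opposite-strand overlaps are both kept, since overlapping
genes on opposite strands are real.

## The synthetic-data generator

A bundle is a matched triple (profile database, genome, true code),
a pure function of its spec including the seed.

* **Families.** Each consensus column picks a residue uniformly, draws
  its emission distribution from a Dirichlet with total concentration 10
  whose mean mass on that residue is the `conservation` parameter
  (default 0.5), and the largest component is then swapped onto the
  consensus residue. The swap is part of the definition of "consensus":
  in a real alignment column the consensus residue is the modal one.
  It also makes the generator's ground truth sharp — every observation
  of a codon has its true amino acid as the modal emission, so a wrong
  letter can only come from a pipeline defect, not a sampling accident.
  MSA rows are sampled column-independently from these distributions;
  profiles are built from the MSAs with pseudocount 1.
* **Genome.** Each family's consensus protein is back-translated under
  the bundle's true code, choosing among synonyms per the codon-usage
  weights (uniform by default), one gene copy per contig with random
  intergenic flanks (Poisson mean 30 nt), strand drawn per copy
  (default half reverse). Default 5 families × 120 columns × 10 copies
  gives every sense codon ≈50 expected observations under uniform usage
  (worst case: 6-fold degenerate amino acids), comfortably above the
  ~30 a confident call needs. With `pseudogene_rate`, gene copies also
  emit frameshifted (single-deletion) pseudogene contigs.

What the generator does **not** emulate: indel evolution within
families, phylogenetic correlation between sequences, GC/codon-usage
bias of real genomes, mRNA editing, and profile databases whose
composition differs from the input. Passing tests therefore demonstrate
the pipeline's correctness — coordinate arithmetic, filtering, the
decision rule, end-to-end recovery under known conditions — not its
error rate on real genomes, where misalignment and compositional
mismatch dominate.

## Numerical and design choices

* Codons are indexed lexicographically (A<C<G<T, AAA=0..TTT=63); output
  prints codon strings, so the convention is self-documenting.
* HMMER3 text scores are written as negative natural logs to 5 decimal
  places with `*` for probability zero; a write/read cycle therefore
  reproduces probabilities to ~1e-5 (quantisation plus read-side
  renormalisation), and a second cycle is exact. Emission rows are
  floored at 1e-9 and renormalised on read.
* The decision comparison is closed (≥ τ), deterministic at equality.
* Ties in the Viterbi traceback prefer match over insert over delete;
  only the score is contractual, the path choice is deterministic.
* All pipeline stages are deterministic for fixed inputs; the only
  randomness in the package lives in the fixture generator and is fully
  seed-derived.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
bundles: the sufficiency simulation uses 1000 replicates of up to 30
columns; standard-code recovery uses the default 5×120×10 bundle
(~21 kb genome); the reassignment screen runs 50 such bundles in the
suite and 20 in the acceptance script, each carrying one random
sense-to-sense reassignment among codons whose amino acid keeps at
least one other synonym; aligner certification uses 1000 (suite) / 500
(script) random tiny instances. These sizes make the whole suite run in
a few minutes on one CPU while keeping every count far from its
decision boundary.

## Known limitations

* No E-value calibration for the internal aligner; its bit-score cutoff
  is a heuristic, exposed in config.
* The per-observation weighting of the published large-scale screens
  (alignment-confidence factors) is not reproduced; observations here
  are unweighted, which is slightly anti-conservative for codons
  observed repeatedly at one locus. The same-strand overlap
  deduplication is the main guard against that.
* Termination codons are never predicted; sense-to-stop reassignments
  are undetectable in principle for this evidence model.
* The shipped exclusion list is an empty template; users screening real
  genomes should populate it for their profile database.
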