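# codonlens

Infer an organism's genetic code table — the amino-acid meaning of each
of the 64 codons — directly from nucleotide sequence, with no annotation
and no taxonomic placement.

Nearly all genomes are annotated assuming the standard genetic code, yet
dozens of clades (CUG-clade yeasts, many mitochondria, several bacterial
lineages) have reassigned codons. A wrong code table silently corrupts
every downstream protein prediction. `codonlens` detects stop-to-sense
and sense-to-sense reassignments from raw DNA or RNA of any assembly
level; it does not predict termination codons and by construction cannot
detect sense-to-stop reassignments.

## Method

The pipeline has three stages:

1. **Align.** The input is translated in all six reading frames under the
   standard code, and the translations are locally aligned to profile
   HMMs of conserved protein families — either with HMMER's `hmmscan`
   (for Pfam-scale databases) or with the built-in Viterbi aligner
   (self-contained, no external tools). Standard-code stop characters
   inside a frame are unalignable: the codons behind them must be judged
   from flanking alignment context, never forced into a match state.
2. **Process.** Each aligned profile consensus column is mapped back
   through frame/strand arithmetic to the genomic codon beneath it.
   After exclusion-list, significance and overlap filtering, the codon
   observations — each carrying its column's emission distribution
   π<sub>i</sub> over the 20 amino acids — are grouped by codon type
   into a single checkpoint file.
3. **Infer.** For each codon c with aligned columns i = 1..N, twenty-one
   models compete. Under the decoding model M<sub>a</sub> ("c is
   translated as amino acid a"),

       L(M_a) = ∏_i π_i(a)

   and under the non-specific translation model M<sub>0</sub> ("the
   alignments reflect background amino-acid usage f"),

       L(M_0) = ∏_i Σ_a f(a) · π_i(a).

   With a uniform prior, the posterior of each model is the normalised
   likelihood. The amino acid with maximum posterior is reported only if
   that posterior reaches a threshold τ (default 0.9999); otherwise the
   codon is left uninferred (`?`) — the expected outcome for stop codons
   and for codons with insufficient or conflicting evidence.

## Worked example

Simulate a genome that encodes three conserved protein families under
the yeast mitochondrial code (NCBI table 3), then re-infer its code from
sequence alone:

```sh
codonlens simulate --seed 1 --outdir bundle \
    --n-families 3 --family-length 60 --copies 6 --ncbi-table 3
codonlens run --input bundle/genome.fasta --profiles bundle/profiles.hmm \
    --out-prefix demo
```

The run prints the inferred 64-character code string (codons in
lexicographic order AAA..TTT):

```
KNKN???????SMIMIQHQHPPPP??????T?EDEDAAA?GGGGVVVV?Y?YS?SS?CWCLFLF
```

and `demo.diff.tsv` lists the differences against the standard code:

```
#codon  reference  inferred  category
ATA     I          M         sense-to-sense
CTG     L          T         sense-to-sense
ACA     T          ?         uninferred
...
TGA     *          ?         uninferred
```

Both genuine reassignments of table 3 that had enough aligned columns —
ATA read as methionine and CTG read as threonine — are recovered as
sense-to-sense calls; rarely observed codons and the three stop codons
stay `?` rather than being guessed. `demo.report.tsv` gives the
per-codon evidence:

```
#codon  n_observations  top_model  posterior  decision
AAA     17              K          1.000000   K
ACA     4               T          0.999482   ?
```

ACA's top model is correct but its posterior (0.9995) sits below
τ = 0.9999, so it is left uninferred — confidence can be traded for
coverage with `-r`, e.g. `codonlens infer -r 0.999 ...`.

The stages are also available separately (`codonlens align`, `process`,
`infer`) and resume from each other's checkpoint files; `--aligner
external --workers N` fans `hmmscan` out over N local processes.

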