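# Profile exclusion list template (pass with --exclude).
#
# One profile name or accession per line; '#' starts a comment; an empty
# list disables exclusion.  For real screens against a large profile
# database, populate this with families that commonly pseudogenize
# (mobile genetic elements: transposases, integrases, reverse
# transcriptases) and families characteristic of organellar contigs,
# whose alignments can confound nuclear genetic-code inference.
#
# Example entries (commented out):
# PF00078    # reverse transcriptase
# PF00665    # integrase core domain
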