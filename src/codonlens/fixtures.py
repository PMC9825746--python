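"""Synthetic test-data generator: matched profiles, genome and true code.

The generator emulates the situation the pipeline is built for: a set of
conserved protein families, and a genome that encodes copies of those
proteins under an arbitrary (possibly non-standard) genetic code with
configurable codon usage, interspersed with random intergenic sequence,
on both strands, optionally contaminated with frameshifted pseudogene
copies.  Everything is a pure function of the :class:`FixtureSpec` (seed
included), so bundles are byte-identical across runs.

Each family is sampled column-independently: a column picks a consensus
residue, draws its emission distribution from a Dirichlet whose mean
on-residue mass is the ``conservation`` parameter, and the largest
component is then swapped onto the consensus residue so the consensus is
always modal — which is what "consensus" means for a real alignment
column.  Sequences are then sampled per column from that distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codes import AA_ALPHABET, CODONS, GeneticCode, standard_code, write_fasta
from .errors import EncodingError
from .profiles import ProfileHMM, build_profile_from_msa, write_profile_db

#: Total Dirichlet concentration for per-column emission draws.
DIRICHLET_CONCENTRATION = 10.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic bundle.

    ``conservation`` is the mean probability mass on a column's consensus
    residue (before the modal swap); ``codon_usage`` optionally maps
    codons to relative weights among synonyms (unspecified codons weigh
    1); ``pseudogene_rate`` is the probability that a gene copy also
    emits a frameshifted (single-deletion) pseudogene contig.
    """

    seed: int = 0
    n_families: int = 5
    family_length: int = 120
    n_seqs_per_family: int = 50
    conservation: float = 0.5
    code: GeneticCode = field(default_factory=standard_code)
    codon_usage: dict | None = None
    n_copies_per_family: int = 10
    reverse_strand_fraction: float = 0.5
    intergenic_length: int = 30
    pseudogene_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.conservation <= 1):
            raise ValueError("conservation must be in (0, 1]")
        for frac in (self.reverse_strand_fraction, self.pseudogene_rate):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if min(self.n_families, self.family_length, self.n_seqs_per_family,
               self.n_copies_per_family) < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class Placement:
    """Ground truth for one encoded gene copy."""

    family: int
    copy: int
    source_id: str
    strand: str
    start: int
    end: int
    #: (forward-strand start of codon, codon string on the coding strand),
    #: one per consensus column in order.
    codons: tuple[tuple[int, str], ...]


@dataclass
class FixtureBundle:
    """Paths plus in-memory truth for one synthetic dataset."""

    spec: FixtureSpec
    profile_db_path: Path
    genome_fasta_path: Path
    placements_path: Path
    truth: GeneticCode
    placements: list[Placement]
    profiles: list[ProfileHMM]
    genome: list[tuple[str, str]]

    def observation_truth_counts(self) -> np.ndarray:
        """How often each codon appears under a consensus column (64 ints)."""
        counts = np.zeros(64, dtype=int)
        idx = {c: i for i, c in enumerate(CODONS)}
        for pl in self.placements:
            for _, codon in pl.codons:
                counts[idx[codon]] += 1
        return counts


def _family_rng(spec: FixtureSpec, family_index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1000 + family_index])


def sample_family(
    spec: FixtureSpec, family_index: int
) -> tuple[list[str], str, np.ndarray]:
    """Sample one family: (MSA rows, consensus sequence, column distributions).

    Deterministic in (spec.seed, family_index).
    """
    rng = _family_rng(spec, family_index)
    K = spec.family_length
    on = rng.integers(0, 20, size=K)
    consensus = "".join(AA_ALPHABET[i] for i in on)
    alpha_on = spec.conservation * DIRICHLET_CONCENTRATION
    alpha_off = (1.0 - spec.conservation) * DIRICHLET_CONCENTRATION / 19.0
    dists = np.empty((K, 20))
    for k in range(K):
        alpha = np.full(20, alpha_off)
        alpha[on[k]] = alpha_on
        d = rng.dirichlet(alpha)
        # make the consensus residue modal: swap the largest mass onto it
        j = int(np.argmax(d))
        d[on[k]], d[j] = d[j], d[on[k]]
        dists[k] = d
    msa = []
    for _ in range(spec.n_seqs_per_family):
        row = "".join(
            AA_ALPHABET[rng.choice(20, p=dists[k])] for k in range(K)
        )
        msa.append(row)
    return msa, consensus, dists


def _usage_weights(spec: FixtureSpec, synonyms: list[str]) -> np.ndarray:
    usage = spec.codon_usage or {}
    w = np.array([float(usage.get(c, 1.0)) for c in synonyms])
    if w.sum() <= 0:
        raise EncodingError(f"codon usage removes all of {synonyms}")
    return w / w.sum()


def _back_translate(
    spec: FixtureSpec, protein: str, rng: np.random.Generator
) -> list[str]:
    codons = []
    for aa in protein:
        syn = spec.code.synonyms(aa)
        if not syn:
            raise EncodingError(
                f"residue {aa!r} has no codon under code {spec.code.name!r}"
            )
        codons.append(syn[rng.choice(len(syn), p=_usage_weights(spec, syn))])
    return codons


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def encode_genome(
    spec: FixtureSpec, consensus_proteins: list[str]
) -> tuple[list[tuple[str, str]], list[Placement], list[str]]:
    """Back-translate each protein into gene contigs; returns pseudogene ids too.

    One gene copy per contig (flanked by random intergenic sequence), so
    a single-best-hit aligner sees one domain per target.  With
    ``pseudogene_rate``, a gene copy also emits an extra contig carrying
    a single-base deletion at a random internal position — the classic
    recent-pseudogene error source for homology-based code inference.
    """
    from .codes import reverse_complement

    rng = np.random.default_rng([spec.seed, 7])
    contigs: list[tuple[str, str]] = []
    placements: list[Placement] = []
    pseudo_ids: list[str] = []
    for fam, protein in enumerate(consensus_proteins):
        for copy in range(spec.n_copies_per_family):
            codons = _back_translate(spec, protein, rng)
            gene = "".join(codons)
            strand = "-" if rng.random() < spec.reverse_strand_fraction else "+"
            left = _random_bases(rng, int(rng.poisson(spec.intergenic_length)))
            right = _random_bases(rng, int(rng.poisson(spec.intergenic_length)))
            oriented = gene if strand == "+" else reverse_complement(gene)
            seq = left + oriented + right
            start = len(left)
            end = start + len(gene)
            name = f"contig_f{fam}c{copy}"
            contigs.append((name, seq))
            K = len(codons)
            if strand == "+":
                placed = tuple(
                    (start + 3 * k, codons[k]) for k in range(K)
                )
            else:
                placed = tuple(
                    (start + 3 * (K - 1 - k), codons[k]) for k in range(K)
                )
            placements.append(
                Placement(
                    family=fam, copy=copy, source_id=name, strand=strand,
                    start=start, end=end, codons=placed,
                )
            )
            if spec.pseudogene_rate and rng.random() < spec.pseudogene_rate:
                cut = int(rng.integers(3, len(gene) - 3))
                broken = gene[:cut] + gene[cut + 1:]
                pname = f"pseudo_f{fam}c{copy}"
                pseudo_ids.append(pname)
                pleft = _random_bases(
                    rng, int(rng.poisson(spec.intergenic_length))
                )
                pright = _random_bases(
                    rng, int(rng.poisson(spec.intergenic_length))
                )
                contigs.append((pname, pleft + broken + pright))
    return contigs, placements, pseudo_ids


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureBundle:
    """Build and write a complete bundle; idempotent under the seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = []
    consensus_proteins = []
    for fam in range(spec.n_families):
        msa, consensus, _ = sample_family(spec, fam)
        profiles.append(
            build_profile_from_msa(
                msa, name=f"fam{fam:05d}", accession=f"SYN{fam:05d}",
                pseudocount=1.0,
            )
        )
        consensus_proteins.append(consensus)
    contigs, placements, _ = encode_genome(spec, consensus_proteins)

    profile_db = out_dir / "profiles.hmm"
    genome_fasta = out_dir / "genome.fasta"
    placements_tsv = out_dir / "placements.tsv"
    write_profile_db(profiles, profile_db)
    write_fasta(contigs, genome_fasta)
    with open(placements_tsv, "w") as fh:
        fh.write("#family\tcopy\tsource_id\tstrand\tstart\tend\tcodons\n")
        for pl in placements:
            codons = ",".join(f"{s}:{c}" for s, c in pl.codons)
            fh.write(
                f"{pl.family}\t{pl.copy}\t{pl.source_id}\t{pl.strand}\t"
                f"{pl.start}\t{pl.end}\t{codons}\n"
            )
    return FixtureBundle(
        spec=spec,
        profile_db_path=profile_db,
        genome_fasta_path=genome_fasta,
        placements_path=placements_tsv,
        truth=spec.code,
        placements=placements,
        profiles=profiles,
        genome=contigs,
    )


def random_sense_to_sense_spec(
    seed: int, **overrides
) -> tuple[FixtureSpec, str, str, str]:
    """A fixture spec whose code carries one random sense-to-sense swap.

    Picks a sense codon whose amino acid has at least two synonyms (so
    the old meaning remains encodable) and moves it to a different,
    uniformly chosen amino acid.  Returns (spec, codon, old, new).
    """
    rng = np.random.default_rng([seed, 99])
    base = standard_code()
    candidates = [
        c for c, m in zip(CODONS, base.table)
        if m != "*" and len(base.synonyms(m)) >= 2
    ]
    codon = candidates[int(rng.integers(0, len(candidates)))]
    old = base[codon]
    others = [a for a in AA_ALPHABET if a != old]
    new = others[int(rng.integers(0, len(others)))]
    spec = FixtureSpec(
        seed=seed, code=base.with_codon(codon, new), **overrides
    )
    return spec, codon, old, new


# ---------------------------------------------------------------------------
# Posterior-sufficiency simulation
# ---------------------------------------------------------------------------

def posterior_sufficiency(
    seed: int,
    n_replicates: int = 1000,
    max_n: int = 40,
    conservation: float = 0.5,
    concentration: float = DIRICHLET_CONCENTRATION,
    threshold: float = 0.9999,
    success_fraction: float = 0.95,
) -> tuple[int | None, np.ndarray]:
    """How many aligned columns does a correct call need?

    Each replicate draws up to ``max_n`` synthetic consensus-column
    emission vectors for one true amino acid (same Dirichlet scheme as
    the family generator, uniform background) and records whether the
    true amino-acid model's posterior reaches ``threshold`` after the
    first n observations.  Returns the smallest N at which at least
    ``success_fraction`` of replicates have decided (or None if never),
    together with the per-N success-rate curve.
    """
    from .infer import InferenceConfig, codon_posterior

    rng = np.random.default_rng([seed, 12345])
    config = InferenceConfig(threshold=threshold)
    f = config.background
    alpha_on = conservation * concentration
    alpha_off = (1.0 - conservation) * concentration / 19.0
    success = np.zeros((n_replicates, max_n), dtype=bool)
    for r in range(n_replicates):
        a = int(rng.integers(0, 20))
        alpha = np.full(20, alpha_off)
        alpha[a] = alpha_on
        ems = rng.dirichlet(alpha, size=max_n)
        mx = np.argmax(ems, axis=1)
        for i in range(max_n):  # modal swap, as in the family generator
            j = int(mx[i])
            ems[i, a], ems[i, j] = ems[i, j], ems[i, a]
        log_em = np.log(np.maximum(ems, 1e-9))
        log_ns = np.log(ems @ f)
        ll_aa = np.cumsum(log_em, axis=0)      # (n, 20)
        ll_ns = np.cumsum(log_ns)
        for n in range(1, max_n + 1):
            ll = np.concatenate([ll_aa[n - 1], [ll_ns[n - 1]]])
            cp = codon_posterior(ll, config)
            success[r, n - 1] = cp.decision == AA_ALPHABET[a]
    rates = success.mean(axis=0)
    hits = np.nonzero(rates >= success_fraction)[0]
    min_n = int(hits[0]) + 1 if hits.size else None
    return min_n, rates
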