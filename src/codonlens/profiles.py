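"""Profile HMMs: HMMER3 text I/O, toy profile construction, exclusion lists.

A profile HMM here is the minimum needed for alignment and codon
inference: per-consensus-column match-emission distributions over the 20
amino acids, one background distribution, and per-node transition
probabilities.  Scores in HMMER3 text files are negative natural logs of
probabilities; ``*`` encodes probability zero.  On read, zero emissions
are floored at :data:`EMISSION_FLOOR` and rows renormalised so that log
likelihoods stay finite downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codes import AA_ALPHABET
from .errors import (
    InvalidDistributionError,
    NoConsensusColumnsError,
    ProfileFormatError,
)

EMISSION_FLOOR = 1e-9

#: Transition column order in HMMER3 text files (out of each node).
TRANSITION_ORDER = ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")

#: Fixed transition probabilities used for profiles built from MSAs.
DEFAULT_TRANSITIONS = {
    "m->m": 0.95, "m->i": 0.03, "m->d": 0.02,
    "i->m": 0.70, "i->i": 0.30,
    "d->m": 0.70, "d->d": 0.30,
}

_GAP_CHARS = frozenset("-.")


def _check_distribution(p: np.ndarray, what: str) -> None:
    if p.ndim != 1 or p.shape[0] != 20:
        raise InvalidDistributionError(f"{what}: need 20 probabilities")
    if np.any(p < 0) or not np.isfinite(p).all():
        raise InvalidDistributionError(f"{what}: negative or non-finite mass")
    if abs(float(p.sum()) - 1.0) > 1e-6:
        raise InvalidDistributionError(
            f"{what}: probabilities sum to {float(p.sum()):.8f}, not 1"
        )


def floor_and_normalize(p: np.ndarray, floor: float = EMISSION_FLOOR) -> np.ndarray:
    """Clip a probability vector below at ``floor`` and renormalise."""
    q = np.maximum(np.asarray(p, dtype=float), floor)
    return q / q.sum()


@dataclass
class ProfileHMM:
    """A protein-family profile: match emissions, background, transitions.

    ``match_emissions`` has shape (length, 20) in HMMER amino-acid
    alphabet order; ``transitions`` has shape (length + 1, 7) in
    :data:`TRANSITION_ORDER`, row 0 being the begin node.  Insert-state
    emissions are taken equal to ``background``.
    """

    name: str
    length: int
    match_emissions: np.ndarray
    background: np.ndarray
    transitions: np.ndarray
    accession: str | None = None
    consensus: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.length < 1 or self.match_emissions.shape != (self.length, 20):
            raise InvalidDistributionError(
                f"profile {self.name!r}: emissions shape "
                f"{self.match_emissions.shape} != ({self.length}, 20)"
            )
        for k in range(self.length):
            _check_distribution(
                self.match_emissions[k], f"profile {self.name!r} column {k + 1}"
            )
            if self.match_emissions[k].min() < EMISSION_FLOOR * (1 - 1e-6):
                raise InvalidDistributionError(
                    f"profile {self.name!r} column {k + 1}: emission below floor"
                )
        _check_distribution(self.background, f"profile {self.name!r} background")
        if self.transitions.shape != (self.length + 1, 7):
            raise InvalidDistributionError(
                f"profile {self.name!r}: transitions shape "
                f"{self.transitions.shape} != ({self.length + 1}, 7)"
            )

    def consensus_letter(self, column: int) -> str:
        """Modal residue of a 1-based consensus column."""
        return AA_ALPHABET[int(np.argmax(self.match_emissions[column - 1]))]


# ---------------------------------------------------------------------------
# HMMER3 text format
# ---------------------------------------------------------------------------

def _score(p: float) -> str:
    if p <= 0.0:
        return "*"
    return f"{-math.log(p):.5f}"


def _prob(token: str, where: str) -> float:
    if token == "*":
        return 0.0
    try:
        return math.exp(-float(token))
    except ValueError:
        raise ProfileFormatError(f"{where}: bad score token {token!r}") from None


def _fmt_row(values) -> str:
    return "  ".join(f"{v:>8}" for v in values)


def write_hmmer3_profile(profile: ProfileHMM, path_or_handle) -> None:
    """Write one profile in HMMER3/f text format.

    Scores are negative natural logs to five decimals with ``*`` for
    probability zero.  STATS calibration lines are placeholders so that
    external HMMER tools will run; E-values they produce are uncalibrated.
    """
    if hasattr(path_or_handle, "write"):
        fh = path_or_handle
        close = False
    else:
        fh = open(path_or_handle, "w")
        close = True
    try:
        p = profile
        fh.write("HMMER3/f [codonlens]\n")
        fh.write(f"NAME  {p.name}\n")
        if p.accession:
            fh.write(f"ACC   {p.accession}\n")
        fh.write(f"LENG  {p.length}\n")
        fh.write("ALPH  amino\n")
        fh.write("RF    no\nMM    no\nCONS  yes\nCS    no\nMAP   yes\n")
        fh.write("STATS LOCAL MSV       -9.00000  0.70000\n")
        fh.write("STATS LOCAL VITERBI  -10.00000  0.70000\n")
        fh.write("STATS LOCAL FORWARD   -4.00000  0.70000\n")
        fh.write("HMM      " + _fmt_row(AA_ALPHABET) + "\n")
        fh.write("         " + _fmt_row(TRANSITION_ORDER) + "\n")
        bg = [_score(v) for v in p.background]
        fh.write("  COMPO  " + _fmt_row(bg) + "\n")
        fh.write("         " + _fmt_row(bg) + "\n")
        t0 = [_score(v) for v in p.transitions[0]]
        t0[5], t0[6] = "0.00000", "*"  # begin node has no delete state
        fh.write("         " + _fmt_row(t0) + "\n")
        for k in range(1, p.length + 1):
            em = [_score(v) for v in p.match_emissions[k - 1]]
            cons = (p.consensus[k - 1] if p.consensus
                    else p.consensus_letter(k).lower())
            fh.write(f"{k:>7}  " + _fmt_row(em) + f"  {k:>6} {cons} - - -\n")
            fh.write("         " + _fmt_row(bg) + "\n")
            tk = [_score(v) for v in p.transitions[k]]
            if k == p.length:
                tk[0] = "0.00000"  # final match-to-end is certain
                tk[2], tk[6] = "*", "*"  # no delete state after the last node
            fh.write("         " + _fmt_row(tk) + "\n")
        fh.write("//\n")
    finally:
        if close:
            fh.close()


def write_profile_db(profiles, path: str | Path) -> None:
    """Concatenate profiles into one HMMER3 database file."""
    with open(path, "w") as fh:
        for p in profiles:
            write_hmmer3_profile(p, fh)


def read_hmmer3_profiles(path: str | Path) -> list[ProfileHMM]:
    """Parse a concatenated HMMER3 text file into :class:`ProfileHMM` records.

    Stored scores become probabilities via ``p = exp(-score)``; ``*``
    becomes 0 and is then floored.  Raises :class:`ProfileFormatError`
    naming the offending record on malformed input.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    profiles: list[ProfileHMM] = []
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].startswith("HMMER3"):
            if lines[i].strip():
                raise ProfileFormatError(
                    f"{path}: expected HMMER3 header at line {i + 1}, "
                    f"got {lines[i]!r}"
                )
            i += 1
            continue
        rec, i = _parse_record(lines, i + 1, str(path))
        profiles.append(rec)
    return profiles


def _parse_record(lines: list[str], i: int, path: str) -> tuple[ProfileHMM, int]:
    name = accession = None
    leng = None
    n = len(lines)
    while i < n and not lines[i].startswith("HMM "):
        key, _, val = lines[i].partition(" ")
        val = val.strip()
        if key == "NAME":
            name = val
        elif key == "ACC":
            accession = val
        elif key == "LENG":
            leng = int(val)
        elif key == "ALPH":
            if val.lower() != "amino":
                raise ProfileFormatError(
                    f"{path}: record {name!r}: alphabet {val!r} is not amino"
                )
        i += 1
    if i >= n or name is None or leng is None:
        raise ProfileFormatError(
            f"{path}: record {name!r}: missing HMM/NAME/LENG header"
        )
    alpha = lines[i].split()[1:]
    if alpha != list(AA_ALPHABET):
        raise ProfileFormatError(
            f"{path}: record {name!r}: unexpected emission alphabet {alpha!r}"
        )
    i += 2  # skip the transition-order header line
    background = None
    if i < n and lines[i].split()[:1] == ["COMPO"]:
        toks = lines[i].split()[1:]
        background = np.array(
            [_prob(t, f"{path}:{name}:COMPO") for t in toks[:20]]
        )
        i += 1
    i += 1  # node-0 insert emissions (ignored; inserts emit background)
    t0 = [_prob(t, f"{path}:{name}:node0") for t in lines[i].split()[:7]]
    i += 1
    emissions = []
    consensus = []
    transitions = [t0]
    for k in range(1, leng + 1):
        if i + 2 >= n:
            raise ProfileFormatError(
                f"{path}: record {name!r}: truncated at node {k}"
            )
        toks = lines[i].split()
        if not toks or toks[0] != str(k):
            raise ProfileFormatError(
                f"{path}: record {name!r}: node {k} missing "
                f"(LENG mismatch at line {i + 1})"
            )
        if len(toks) < 21:
            raise ProfileFormatError(
                f"{path}: record {name!r}: node {k}: short emission line"
            )
        row = np.array(
            [_prob(t, f"{path}:{name}:node{k}") for t in toks[1:21]]
        )
        emissions.append(floor_and_normalize(row))
        consensus.append(toks[22] if len(toks) > 22 else "x")
        i += 2  # skip insert emissions
        transitions.append(
            [_prob(t, f"{path}:{name}:node{k}t") for t in lines[i].split()[:7]]
        )
        i += 1
    if i >= n or lines[i].strip() != "//":
        raise ProfileFormatError(
            f"{path}: record {name!r}: missing // terminator "
            f"(LENG {leng} mismatch?)"
        )
    em = np.vstack(emissions)
    if background is None:
        background = em.mean(axis=0)
    return (
        ProfileHMM(
            name=name,
            accession=accession,
            length=leng,
            match_emissions=em,
            background=floor_and_normalize(background),
            transitions=np.array(transitions),
            consensus="".join(consensus),
        ),
        i + 1,
    )


# ---------------------------------------------------------------------------
# Profile construction from alignments
# ---------------------------------------------------------------------------

def build_profile_from_msa(
    msa: list[str],
    name: str = "msa_profile",
    pseudocount: float = 1.0,
    accession: str | None = None,
) -> ProfileHMM:
    """Build a toy profile from an aligned set of protein sequences.

    Consensus columns are those with at most 50% gap characters.  Match
    emissions are Laplace-smoothed column frequencies,
    ``(count + pseudocount) / (depth + 20 * pseudocount)`` with depth the
    number of non-gap residues in the column; the background is the mean
    of the match emissions and transitions are the fixed defaults in
    :data:`DEFAULT_TRANSITIONS`.
    """
    if len(msa) < 2:
        raise InvalidDistributionError("need at least 2 aligned sequences")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise InvalidDistributionError("aligned sequences differ in length")
    if pseudocount <= 0:
        raise InvalidDistributionError("pseudocount must be positive")
    aa_idx = {a: i for i, a in enumerate(AA_ALPHABET)}
    emissions = []
    consensus = []
    for j in range(width):
        col = [row[j] for row in msa]
        gaps = sum(c in _GAP_CHARS for c in col)
        if gaps * 2 > len(col):
            continue
        counts = np.zeros(20)
        for c in col:
            if c in _GAP_CHARS:
                continue
            try:
                counts[aa_idx[c.upper()]] += 1
            except KeyError:
                raise InvalidDistributionError(
                    f"non-amino residue {c!r} in column {j + 1}"
                ) from None
        depth = counts.sum()
        row = (counts + pseudocount) / (depth + 20.0 * pseudocount)
        emissions.append(row)
        consensus.append(AA_ALPHABET[int(np.argmax(row))])
    if not emissions:
        raise NoConsensusColumnsError(
            f"profile {name!r}: every column exceeds 50% gaps"
        )
    em = np.vstack(emissions)
    trans = np.tile(
        [DEFAULT_TRANSITIONS[k] for k in TRANSITION_ORDER], (len(emissions) + 1, 1)
    )
    return ProfileHMM(
        name=name,
        accession=accession,
        length=len(emissions),
        match_emissions=em,
        background=em.mean(axis=0),
        transitions=trans,
        consensus="".join(consensus),
    )


# ---------------------------------------------------------------------------
# Exclusion lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionList:
    """Profile names/accessions to drop before observation collection.

    Real screens exclude families that commonly pseudogenize (mobile
    genetic elements) or derive from organellar contigs; an empty list
    disables exclusion.
    """

    entries: frozenset[str] = frozenset()

    def __contains__(self, name) -> bool:
        return name in self.entries

    def excludes(self, profile: ProfileHMM) -> bool:
        return profile.name in self.entries or (
            profile.accession is not None and profile.accession in self.entries
        )


def load_exclusion_list(path: str | Path) -> ExclusionList:
    """Read one profile name or accession per line; '#' starts a comment."""
    entries = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                entries.add(entry)
    return ExclusionList(entries=frozenset(entries))
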