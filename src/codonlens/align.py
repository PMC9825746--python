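"""Local alignment of profile HMMs to translated reading frames.

Two routes produce the same :class:`AlignmentSegment` records:

* an internal Viterbi aligner over a standard profile state machine
  (match/insert/delete per column, uniform local entry and exit over
  columns, flanking residues free), suitable for self-contained runs;
* a driver for the external HMMER ``hmmscan`` program plus a parser for
  its per-domain alignment blocks, for realistic database scale.

Internal scores are log2-odds of the alignment path's match emissions
against the background, plus transition log probabilities and the entry
and exit terms; no E-value calibration is attempted, so the internal
``significance`` field simply repeats the bit score.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codes import AA_ALPHABET
from .errors import (
    InvalidSequenceError,
    MissingExecutableError,
    SearchFailedError,
    TruncatedAlignmentError,
)
from .profiles import ProfileHMM

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: Default bit-score cutoff for keeping internal alignments.
DEFAULT_MIN_SCORE_BITS = 10.0

#: Default domain E-value cutoff for keeping external alignments.
DEFAULT_MAX_EVALUE = 1e-6

_NEG = -np.inf


@dataclass
class AlignmentSegment:
    """One local alignment of a profile to one translated frame.

    ``column_map`` holds (consensus_column, residue_pos) pairs — 1-based
    profile column against 0-based position in the frame translation —
    for match-state correspondences only; inserted and deleted columns
    are absent.  Both coordinates are strictly increasing.
    """

    profile_name: str
    target_id: str
    score: float
    significance: float
    column_map: list[tuple[int, int]] = field(default_factory=list)

    def residue_positions(self) -> list[int]:
        return [pos for _, pos in self.column_map]


# ---------------------------------------------------------------------------
# Internal Viterbi aligner
# ---------------------------------------------------------------------------

def _emission_logodds(profile: ProfileHMM, protein: str) -> np.ndarray:
    """(L, K) match log2-odds; unalignable residues ('X', '*', ...) -inf."""
    K = profile.length
    S = np.full((len(protein), K), _NEG)
    log_em = np.log2(profile.match_emissions)   # (K, 20); floored, never 0
    log_bg = np.log2(profile.background)
    for l, ch in enumerate(protein):
        a = _AA_INDEX.get(ch)
        if a is not None:
            S[l] = log_em[:, a] - log_bg[a]
    return S


def _transition_log2(profile: ProfileHMM) -> dict[str, np.ndarray]:
    """Destination-indexed log2 transition vectors over 0-based columns.

    Node ``k`` (1-based) is match column ``k``; ``transitions[r]`` holds
    the probabilities out of node ``r``.  The local aligner ignores the
    begin node's transitions (entry is uniform over columns).
    """
    t = np.log2(np.maximum(profile.transitions, 1e-300))
    K = profile.length
    # into match column j (0-based, j >= 1): out of node j
    into = slice(1, K)
    out = {
        "MM": t[into, 0], "IM": t[into, 3], "DM": t[into, 5],
        "MD": t[into, 2], "DD": t[into, 6],
        # insert after column j (node j+1), defined for j = 0..K-2
        "MI": t[1:K, 1], "II": t[1:K, 4],
    }
    return out


def viterbi_align(
    profile: ProfileHMM,
    protein: str,
    min_score_bits: float = DEFAULT_MIN_SCORE_BITS,
    target_id: str = "",
) -> AlignmentSegment | None:
    """Best single local alignment of ``profile`` to ``protein``.

    Residues outside the 20-letter alphabet ('X', '*') cannot occupy
    match states — they may only sit in inserts or the free flanks — so
    standard-code stop characters inside a reading frame never force a
    decoding.  Returns ``None`` when the best path scores below
    ``min_score_bits``.
    """
    if not protein:
        return None
    K = profile.length
    L = len(protein)
    entry = exit_ = -np.log2(K)
    S = _emission_logodds(profile, protein)
    t = _transition_log2(profile)

    VM = np.full((L, K), _NEG)
    VI = np.full((L, K), _NEG)   # VI[:, j] = insert after column j (j <= K-2)
    VD = np.full((L, K), _NEG)

    # prefix sums for the delete-chain scan: P[j] = sum of DD into 1..j
    P = np.zeros(K)
    if K > 1:
        P[1:] = np.cumsum(t["DD"])

    def delete_scan(vm_row: np.ndarray) -> np.ndarray:
        """VD[l, j] = best of M(l, i) -> D -> ... -> D(l, j) for i < j."""
        vd = np.full(K, _NEG)
        if K > 1:
            with np.errstate(invalid="ignore"):
                B = vm_row[:-1] + t["MD"] - P[1:]
            B[~np.isfinite(B)] = _NEG
            vd[1:] = P[1:] + np.maximum.accumulate(B)
        return vd

    VM[0] = S[0] + entry
    VD[0] = delete_scan(VM[0])
    for l in range(1, L):
        prevM, prevI, prevD = VM[l - 1], VI[l - 1], VD[l - 1]
        cand = np.full(K, entry)
        if K > 1:
            incoming = np.maximum(
                np.maximum(prevM[:-1] + t["MM"], prevI[:-1] + t["IM"]),
                prevD[:-1] + t["DM"],
            )
            cand[1:] = np.maximum(cand[1:], incoming)
        VM[l] = S[l] + cand
        if K > 1:
            VI[l, :-1] = np.maximum(prevM[:-1] + t["MI"], prevI[:-1] + t["II"])
        VD[l] = delete_scan(VM[l])

    ends = VM + exit_
    best = float(np.max(ends))
    if not np.isfinite(best) or best < min_score_bits:
        return None
    l, j = np.unravel_index(int(np.argmax(ends)), ends.shape)
    column_map = _traceback(S, VM, VI, VD, t, entry, int(l), int(j))
    return AlignmentSegment(
        profile_name=profile.name,
        target_id=target_id,
        score=best,
        significance=best,
        column_map=column_map,
    )


def _traceback(S, VM, VI, VD, t, entry, l, j) -> list[tuple[int, int]]:
    pairs = [(j + 1, l)]
    state = "M"
    while True:
        if state == "M":
            if j == 0 or l == 0 or np.isclose(VM[l, j], S[l, j] + entry, atol=1e-6):
                break
            opts = (
                ("M", VM[l - 1, j - 1] + t["MM"][j - 1]),
                ("I", VI[l - 1, j - 1] + t["IM"][j - 1]),
                ("D", VD[l - 1, j - 1] + t["DM"][j - 1]),
            )
            state, _ = max(opts, key=lambda o: o[1])
            if state == "M":
                l, j = l - 1, j - 1
                pairs.append((j + 1, l))
            elif state == "I":
                l, j = l - 1, j - 1
            else:
                l, j = l - 1, j - 1
        elif state == "I":
            # VI[l, j]: insert after column j, entered from M or I at l-1
            m = VM[l - 1, j] + t["MI"][j]
            i = VI[l - 1, j] + t["II"][j]
            if m >= i:
                state = "M"
                l = l - 1
                pairs.append((j + 1, l))
            else:
                l = l - 1
        else:  # D
            m = VM[l, j - 1] + t["MD"][j - 1]
            d = VD[l, j - 1] + t["DD"][j - 1]
            if m + 1e-9 >= d:
                state = "M"
                j = j - 1
                pairs.append((j + 1, l))
            else:
                state = "D"
                j = j - 1
    pairs.reverse()
    return pairs


def align_profiles_to_translations(
    profiles,
    translations,
    min_score_bits: float = DEFAULT_MIN_SCORE_BITS,
    min_target_length: int = 5,
) -> list[AlignmentSegment]:
    """Run the internal aligner for every (profile, frame) pair, in order."""
    segments = []
    for tr in translations:
        if len(tr.protein) < min_target_length:
            continue
        for p in profiles:
            seg = viterbi_align(p, tr.protein, min_score_bits, tr.target_id)
            if seg is not None:
                segments.append(seg)
    return segments


# ---------------------------------------------------------------------------
# External hmmscan driver
# ---------------------------------------------------------------------------

def run_external_search(
    profile_db_path: str | Path,
    translations_fasta_path: str | Path,
    out_dir: str | Path,
    n_workers: int = 1,
    executable: str = "hmmscan",
    extra_options: tuple[str, ...] = (),
) -> list[Path]:
    """Run ``hmmscan`` on a six-frame translation FASTA.

    The translation FASTA is split into ``n_workers`` contiguous chunks
    of whole sequences; one scan runs per chunk and the output paths are
    returned in input order, so downstream parsing is deterministic
    regardless of worker count.  Raises :class:`MissingExecutableError`
    if the tool is absent (use the internal aligner instead) and
    :class:`SearchFailedError` with captured stderr on non-zero exit.
    """
    from Bio import SeqIO

    exe = shutil.which(executable)
    if exe is None:
        raise MissingExecutableError(
            f"{executable!r} not found on PATH; use aligner='internal'"
        )
    records = list(SeqIO.parse(str(translations_fasta_path), "fasta"))
    if not records:
        raise InvalidSequenceError(
            f"no sequences in {translations_fasta_path}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db = _pressed_db(Path(profile_db_path), out_dir)

    n_workers = max(1, min(int(n_workers), len(records)))
    bounds = np.linspace(0, len(records), n_workers + 1).astype(int)
    chunks = [records[bounds[i]: bounds[i + 1]] for i in range(n_workers)]

    procs = []
    outputs = []
    for i, chunk in enumerate(chunks):
        fasta = out_dir / f"chunk{i:03d}.faa"
        SeqIO.write(chunk, str(fasta), "fasta")
        out = out_dir / f"chunk{i:03d}.hmmscan.out"
        cmd = [exe, "--notextw", "-o", str(out), *extra_options, str(db), str(fasta)]
        procs.append((cmd, subprocess.Popen(
            cmd, stdout=subprocess.DEVNULL, stderr=subprocess.PIPE, text=True
        )))
        outputs.append(out)
    for cmd, proc in procs:
        _, err = proc.communicate()
        if proc.returncode != 0:
            raise SearchFailedError(
                f"{' '.join(cmd)} exited {proc.returncode}: {err.strip()}"
            )
    return outputs


def _pressed_db(db: Path, workdir: Path) -> Path:
    """Ensure hmmpress index files exist next to a (copy of) the database."""
    if all((db.parent / (db.name + ext)).exists()
           for ext in (".h3m", ".h3i", ".h3f", ".h3p")):
        return db
    local = workdir / db.name
    if local.resolve() != db.resolve():
        shutil.copyfile(db, local)
    exe = shutil.which("hmmpress")
    if exe is None:
        raise MissingExecutableError("'hmmpress' not found on PATH")
    res = subprocess.run(
        [exe, "-f", str(local)], capture_output=True, text=True
    )
    if res.returncode != 0:
        raise SearchFailedError(f"hmmpress failed: {res.stderr.strip()}")
    return local


_DOMAIN_RE = re.compile(
    r"==\s+domain\s+\d+\s+score:\s+([-\d.]+)\s+bits;.*E-value:\s+(\S+)"
)


def parse_search_alignments(text: str) -> list[AlignmentSegment]:
    """Parse hmmscan standard output into :class:`AlignmentSegment` records.

    The column map is rebuilt by walking each domain's aligned profile
    and target strings: positions where both show a residue are match
    correspondences; a ``.`` in the profile line is an insertion in the
    target (target advances alone); a ``-`` in the target line is a
    deletion (profile advances alone).
    """
    segments: list[AlignmentSegment] = []
    query = None
    model = None
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if line.startswith("Query:"):
            query = line.split()[1]
        elif line.startswith(">> "):
            model = line.split()[1]
        elif "== domain" in line and model is not None:
            m = _DOMAIN_RE.search(line)
            if m is None:
                raise TruncatedAlignmentError(
                    f"unparseable domain header for {model!r}: {line.strip()!r}"
                )
            score = float(m.group(1))
            evalue = float(m.group(2))
            seg, i = _parse_domain_block(lines, i + 1, query, model, score, evalue)
            segments.append(seg)
            continue
        i += 1
    return segments


def _parse_domain_block(lines, i, query, model, score, evalue):
    hmm_chunks: list[str] = []
    tgt_chunks: list[str] = []
    hmm_from = hmm_to = ali_from = ali_to = None
    n = len(lines)
    while i < n:
        line = lines[i]
        stripped = line.strip()
        if (stripped.startswith("== domain") or line.startswith(">> ")
                or line.startswith("Query:")
                or line.startswith("Internal pipeline")):
            break
        toks = stripped.split()
        if len(toks) == 4 and toks[0] == model and toks[1].isdigit():
            hmm_chunks.append(toks[2])
            if hmm_from is None:
                hmm_from = int(toks[1])
            hmm_to = int(toks[3])
        elif len(toks) == 4 and toks[0] == query and toks[1].isdigit():
            tgt_chunks.append(toks[2])
            if ali_from is None:
                ali_from = int(toks[1])
            ali_to = int(toks[3])
        i += 1
    ident = f"{model} vs {query}"
    if not hmm_chunks or not tgt_chunks or len(hmm_chunks) != len(tgt_chunks):
        raise TruncatedAlignmentError(f"incomplete alignment block for {ident}")
    hmm_seq = "".join(hmm_chunks)
    tgt_seq = "".join(tgt_chunks)
    if len(hmm_seq) != len(tgt_seq):
        raise TruncatedAlignmentError(
            f"profile/target length mismatch for {ident}"
        )
    column_map = []
    col = hmm_from
    pos = ali_from - 1  # hmmscan coordinates are 1-based
    for hc, tc in zip(hmm_seq, tgt_seq):
        if hc == ".":
            pos += 1
        elif tc == "-":
            col += 1
        else:
            column_map.append((col, pos))
            col += 1
            pos += 1
    if col - 1 != hmm_to or pos != ali_to:
        raise TruncatedAlignmentError(
            f"alignment block for {ident} ends at column {col - 1}/"
            f"residue {pos}, declared {hmm_to}/{ali_to}"
        )
    return AlignmentSegment(
        profile_name=model,
        target_id=query,
        score=score,
        significance=evalue,
        column_map=column_map,
    ), i


def parse_search_output_files(paths) -> list[AlignmentSegment]:
    """Parse and concatenate hmmscan outputs in the given (input) order."""
    segments = []
    for p in paths:
        segments.extend(parse_search_alignments(Path(p).read_text()))
    return segments


# ---------------------------------------------------------------------------
# Intermediate segment file
# ---------------------------------------------------------------------------

_SEGMENT_HEADER = "#segment\tprofile\ttarget_id\tcolumn\tresidue_pos\tscore\tsignificance"


def write_segments(segments, path: str | Path) -> None:
    """One row per match correspondence; a leading id groups rows by segment."""
    with open(path, "w") as fh:
        fh.write(_SEGMENT_HEADER + "\n")
        for s_id, seg in enumerate(segments):
            for col, pos in seg.column_map:
                fh.write(
                    f"{s_id}\t{seg.profile_name}\t{seg.target_id}\t{col}\t"
                    f"{pos}\t{seg.score:.2f}\t{seg.significance:.3g}\n"
                )


def read_segments(path: str | Path) -> list[AlignmentSegment]:
    segments: dict[int, AlignmentSegment] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            s_id, prof, tid, col, pos, score, sig = line.rstrip("\n").split("\t")
            s_id = int(s_id)
            if s_id not in segments:
                segments[s_id] = AlignmentSegment(
                    profile_name=prof,
                    target_id=tid,
                    score=float(score),
                    significance=float(sig),
                    column_map=[],
                )
            segments[s_id].column_map.append((int(col), int(pos)))
    return [segments[k] for k in sorted(segments)]
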