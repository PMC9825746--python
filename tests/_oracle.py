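"""Exhaustive-enumeration oracle for the local profile aligner.

Scores every legal local path through the profile state machine by
direct recursion — no dynamic programming — under exactly the model the
package's aligner defines: uniform log2(1/K) entry and exit over match
columns, free flanking residues, insert emissions equal to background,
residues outside the 20-letter alphabet forbidden in match states.
Tractable only for tiny profiles/targets; used to certify the Viterbi
implementation on random small instances.
"""

import math

import numpy as np

from codonlens.codes import AA_ALPHABET

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


def brute_force_best_score(profile, protein: str) -> float:
    """Maximum path score in bits over all local alignments; -inf if none."""
    K = profile.length
    L = len(protein)
    entry = exit_ = -math.log2(K)
    t = np.log2(np.maximum(profile.transitions, 1e-300))

    S = np.full((L, K), -np.inf)
    log_em = np.log2(profile.match_emissions)
    log_bg = np.log2(profile.background)
    for l, ch in enumerate(protein):
        a = _AA_INDEX.get(ch)
        if a is not None:
            S[l] = log_em[:, a] - log_bg[a]

    # transitions into destination column j (0-based): out of node j
    def t_into(kind, j):
        col = {"MM": 0, "IM": 3, "DM": 5, "MD": 2, "DD": 6}[kind]
        return t[j, col]

    def t_insert(kind, j):  # insert after column j: node j + 1
        return t[j + 1, {"MI": 1, "II": 4}[kind]]

    best = [-np.inf]

    def from_match(l, j, score):
        best[0] = max(best[0], score + exit_)
        if j + 1 < K:
            if l + 1 < L and np.isfinite(S[l + 1, j + 1]):
                from_match(l + 1, j + 1,
                           score + t_into("MM", j + 1) + S[l + 1, j + 1])
            from_delete(l, j + 1, score + t_into("MD", j + 1))
        if j <= K - 2 and l + 1 < L:
            from_insert(l + 1, j, score + t_insert("MI", j))

    def from_insert(l, j, score):
        if l + 1 < L:
            from_insert(l + 1, j, score + t_insert("II", j))
            if np.isfinite(S[l + 1, j + 1]):
                from_match(l + 1, j + 1,
                           score + t_into("IM", j + 1) + S[l + 1, j + 1])

    def from_delete(l, j, score):
        if j + 1 < K:
            from_delete(l, j + 1, score + t_into("DD", j + 1))
            if l + 1 < L and np.isfinite(S[l + 1, j + 1]):
                from_match(l + 1, j + 1,
                           score + t_into("DM", j + 1) + S[l + 1, j + 1])

    for l in range(L):
        for j in range(K):
            if np.isfinite(S[l, j]):
                from_match(l, j, entry + S[l, j])
    return float(best[0])


def random_instance(rng, max_columns=4, max_target=6, alphabet="ACDE"):
    """A random tiny profile and target over a reduced amino alphabet."""
    from codonlens.profiles import ProfileHMM, floor_and_normalize

    K = int(rng.integers(1, max_columns + 1))
    L = int(rng.integers(1, max_target + 1))
    idx = [_AA_INDEX[a] for a in alphabet]
    em = np.full((K, 20), 1e-9)
    for k in range(K):
        w = rng.dirichlet(np.ones(len(idx)))
        em[k, idx] = w
        em[k] = floor_and_normalize(em[k])
    bg = np.full(20, 1e-9)
    bg[idx] = rng.dirichlet(np.ones(len(idx)) * 5)
    bg = bg / bg.sum()
    # random but proper per-node transitions to exercise indexing
    trans = np.empty((K + 1, 7))
    for r in range(K + 1):
        m = rng.dirichlet(np.ones(3) * 5)        # m->m, m->i, m->d
        i = rng.dirichlet(np.ones(2) * 5)        # i->m, i->i
        d = rng.dirichlet(np.ones(2) * 5)        # d->m, d->d
        trans[r] = [m[0], m[1], m[2], i[0], i[1], d[0], d[1]]
    profile = ProfileHMM(
        name="rnd", length=K, match_emissions=em, background=bg,
        transitions=trans,
    )
    target = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), L))
    return profile, target
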