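"""Independent reference implementations used to validate the package.

The scoring oracle enumerates every possible local alignment (choice of
query subsequence, profile node interval and state path) and computes its
log-odds in plain probability space, with none of the dynamic-programming
machinery of the implementation under test.  Exponential in size, so only
usable for tiny models and sequences.
"""

from __future__ import annotations

import math

import numpy as np

from markergenie.profilehmm import AMINO_ACIDS, ProfileHMM

_MM, _MI, _MD, _IM, _II, _DM, _DD = range(7)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def enumerate_local_score(hmm: ProfileHMM, protein: str):
    """Best local alignment by exhaustive path enumeration.

    Returns ``(score_bits, seq_start, seq_end, node_start, node_end)``
    (half-open, 0-based) under the same model definition as the package:
    uniform 1/M entry into any match node, free exit from any match node,
    no cost for unaligned query flanks, ties broken toward the smallest
    seq_start then node_start.  Returns None when no path has probability
    > 0 (possible only with zero emission probabilities).
    """
    m = hmm.length
    L = len(protein)
    xs = [(-1 if c == "X" else _AA_INDEX[c]) for c in protein]
    me, ie = hmm.match_emissions, hmm.insert_emissions
    t, bg = hmm.transitions, hmm.background
    best = None  # (score, seq_start, node_start, seq_end, node_end)

    def ratio(emrow, x):
        if x < 0:
            return 1.0
        return emrow[x] / bg[x] if bg[x] > 0 else 0.0

    def visit(score_lin, i, k, state, s0, k0):
        # state just consumed: 'M' at node k having consumed residue i-1
        nonlocal best
        if score_lin <= 0.0:
            return
        if state == "M":
            cand = (math.log2(score_lin), s0, k0, i, k)
            if best is None:
                best = cand
            else:
                b = best
                if (cand[0] > b[0] + 1e-15 or
                        (abs(cand[0] - b[0]) <= 1e-15 and (cand[1], cand[2]) < (b[1], b[2]))):
                    best = cand
        if state == "M":
            if k < m and i < L:
                visit(score_lin * t[k][_MM] * ratio(me[k], xs[i]), i + 1, k + 1, "M", s0, k0)
            if i < L:
                visit(score_lin * t[k][_MI] * ratio(ie[k - 1], xs[i]), i + 1, k, "I", s0, k0)
            if k < m:
                visit(score_lin * t[k][_MD], i, k + 1, "D", s0, k0)
        elif state == "I":
            if k < m and i < L:
                visit(score_lin * t[k][_IM] * ratio(me[k], xs[i]), i + 1, k + 1, "M", s0, k0)
            if i < L:
                visit(score_lin * t[k][_II] * ratio(ie[k - 1], xs[i]), i + 1, k, "I", s0, k0)
        elif state == "D":
            if k < m and i < L:
                visit(score_lin * t[k][_DM] * ratio(me[k], xs[i]), i + 1, k + 1, "M", s0, k0)
            if k < m:
                visit(score_lin * t[k][_DD], i, k + 1, "D", s0, k0)

    entry = 1.0 / m
    for i0 in range(L):
        for k0 in range(1, m + 1):
            # enter directly into match state k0 emitting residue i0
            visit(entry * ratio(me[k0 - 1], xs[i0]), i0 + 1, k0, "M", i0, k0)
    if best is None:
        return None
    score, s0, k0, i_end, k_end = best
    return score, s0, i_end, k0 - 1, k_end


def random_profile_hmm(
    rng: np.random.Generator, m: int, name: str = "rand", sparse: bool = False
) -> ProfileHMM:
    """A random valid ProfileHMM (optionally with some zero probabilities)."""
    def rows(shape):
        a = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1]) if len(shape) > 1 \
            else rng.dirichlet(np.ones(shape[0]))
        return a

    match = rows((m, 20))
    insert = rows((m, 20))
    bg = rows((20,))
    trans = np.zeros((m + 1, 7))
    for k in range(m + 1):
        mrow = rng.dirichlet(np.ones(3))
        irow = rng.dirichlet(np.ones(2))
        drow = rng.dirichlet(np.ones(2))
        if sparse and rng.random() < 0.3:
            mrow = np.array([mrow[0] + mrow[1], 0.0, mrow[2]])
        trans[k] = [mrow[0], mrow[1], mrow[2], irow[0], irow[1], drow[0], drow[1]]
    trans[m, _MM] += trans[m, _MD]
    trans[m, _MD] = 0.0
    trans[m, _DM] = 1.0
    trans[m, _DD] = 0.0
    hmm = ProfileHMM(name=name, match_emissions=match, insert_emissions=insert,
                     transitions=trans, background=bg)
    hmm.validate()
    return hmm


def pairwise_identity(a: str, b: str) -> float:
    """Best ungapped-overlap identity over the shorter sequence (reference)."""
    if len(a) < len(b):
        a, b = b, a
    best = 0
    for off in range(-len(b) + 1, len(a)):
        matches = sum(
            1 for i in range(max(0, off), min(len(a), off + len(b)))
            if a[i] == b[i - off]
        )
        best = max(best, matches)
    return best / len(b)
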