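"""Profile hidden Markov models of protein families.

A :class:`ProfileHMM` is the classic position-specific model of a protein
family: a chain of match states (one per conserved column of a seed
alignment) with insert and delete states between them.  Homology of a query
protein is scored as a log-odds *bit score*: log2 of the probability of the
aligned residues under the best state path through the model divided by
their probability under a background (null) composition.

The module covers the full life cycle of such a model:

* reading and writing the HMMER3 ASCII profile format (``HMMER3/f``),
* building a model from a gapped seed alignment with Laplace-style
  pseudocounts, and
* local Viterbi scoring of protein sequences (:func:`score_local`).

Scoring is fully local: the alignment may start at any match node (uniform
entry probability 1/M), end at any match node (free exit), and unaligned
query flanks cost nothing.  Multi-hit (J-state) paths are not modelled —
each query yields at most one best local hit, which is what a
presence/absence marker-gene inventory needs.  All dynamic programming is
carried out in log2 space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import IO, Iterable, Optional, Sequence

import numpy as np

from .errors import ConstructionError, FormatError, HmmParseError, ValidationError

#: Ordered amino-acid alphabet used throughout (HMMER column order).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Transition tuple layout per node: M->M, M->I, M->D, I->M, I->I, D->M, D->D
TRANS_ORDER = ("mm", "mi", "md", "im", "ii", "dm", "dd")
_MM, _MI, _MD, _IM, _II, _DM, _DD = range(7)

_GAP_CHARS = frozenset("-.")
_PROB_TOL = 1e-6


@dataclass
class CutoffPair:
    """Bit-score thresholds attached to one profile.

    ``trusted`` is the lowest score seen for a curated true family member,
    ``noise`` the highest score seen for a curated non-member (``-inf``
    when no false positives exist), and ``gathering`` the operational
    acceptance threshold sitting between them.  ``separable`` records
    whether the two labelled score sets were disjoint when the cutoffs
    were derived.
    """

    trusted: float
    noise: float
    gathering: float
    separable: bool

    def validate(self) -> None:
        if self.separable and not (self.noise < self.gathering <= self.trusted):
            raise ValidationError(
                f"separable cutoffs must satisfy noise < gathering <= trusted, "
                f"got noise={self.noise}, gathering={self.gathering}, trusted={self.trusted}"
            )


@dataclass
class HmmHit:
    """Best local alignment of one protein against one profile.

    ``seq_start``/``seq_end`` are a 0-based half-open residue interval on
    the query; ``node_start``/``node_end`` the matched profile node
    interval, also 0-based half-open.
    """

    orf_id: str
    hmm_name: str
    bit_score: float
    seq_start: int
    seq_end: int
    node_start: int
    node_end: int

    def validate(self) -> None:
        if not self.seq_start < self.seq_end:
            raise ValidationError("seq_start must be < seq_end")
        if not self.node_start <= self.node_end:
            raise ValidationError("node_start must be <= node_end")
        if not math.isfinite(self.bit_score):
            raise ValidationError("bit_score must be finite")


@dataclass
class ProfileHMM:
    """A profile HMM over the 20 standard amino acids.

    Parameters are stored as plain probabilities.  ``transitions`` has
    ``M + 1`` rows; row ``k`` holds the 7-tuple of transitions leaving
    node ``k`` (row 0 is the begin node).  Emission rows are indexed by
    match node (0-based) and by :data:`AMINO_ACIDS` position.
    """

    name: str
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (M, 20)
    transitions: np.ndarray  # (M + 1, 7)
    background: np.ndarray  # (20,)
    cutoffs: Optional[CutoffPair] = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        """Number of match states M."""
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        m = self.length
        if m < 1:
            raise ValidationError(f"{self.name}: model must have >= 1 match state")
        for label, arr, shape in (
            ("match_emissions", self.match_emissions, (m, 20)),
            ("insert_emissions", self.insert_emissions, (m, 20)),
            ("transitions", self.transitions, (m + 1, 7)),
            ("background", self.background, (20,)),
        ):
            if arr.shape != shape:
                raise ValidationError(f"{self.name}: {label} has shape {arr.shape}, want {shape}")
            if np.any(arr < -_PROB_TOL) or np.any(arr > 1 + _PROB_TOL):
                raise ValidationError(f"{self.name}: {label} has entries outside [0, 1]")
        for label, arr in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
        ):
            sums = arr.sum(axis=1)
            bad = np.nonzero(np.abs(sums - 1.0) > _PROB_TOL)[0]
            if bad.size:
                raise ValidationError(
                    f"{self.name}: {label} row {bad[0]} sums to {sums[bad[0]]:.8f}, not 1"
                )
        if abs(self.background.sum() - 1.0) > _PROB_TOL:
            raise ValidationError(f"{self.name}: background sums to {self.background.sum():.8f}")
        t = self.transitions
        groups = (("M", t[:, _MM] + t[:, _MI] + t[:, _MD]),
                  ("I", t[:, _IM] + t[:, _II]),
                  ("D", t[:, _DM] + t[:, _DD]))
        for label, sums in groups:
            bad = np.nonzero(np.abs(sums - 1.0) > _PROB_TOL)[0]
            if bad.size:
                raise ValidationError(
                    f"{self.name}: {label}-state transitions at node {bad[0]} sum to "
                    f"{sums[bad[0]]:.8f}, not 1"
                )
        if self.cutoffs is not None:
            self.cutoffs.validate()

    def consensus(self) -> str:
        """Most probable residue of each match state."""
        idx = np.argmax(self.match_emissions, axis=1)
        return "".join(AMINO_ACIDS[i] for i in idx)

    def with_cutoffs(self, cutoffs: CutoffPair) -> "ProfileHMM":
        return replace(self, cutoffs=cutoffs)


# ---------------------------------------------------------------------------
# HMMER3 ASCII I/O
# ---------------------------------------------------------------------------

def _decode(token: str, *, line_no: int, what: str) -> float:
    """Negative-natural-log token -> probability ('*' encodes zero)."""
    if token == "*":
        return 0.0
    try:
        return math.exp(-float(token))
    except ValueError:
        raise HmmParseError(f"line {line_no}: non-numeric {what} token {token!r}") from None


def _encode(p: float) -> str:
    """Probability -> negative-natural-log token, '*' for zero.

    Eight decimals keep the round-trip error per probability below 1e-8,
    comfortably inside the 1e-6 contract (stock hmmbuild prints five).
    """
    if p <= 0.0:
        return "            *"
    return f"{max(-math.log(p), 0.0):13.8f}"


def parse_hmm3(stream: IO[str] | Iterable[str]) -> list[ProfileHMM]:
    """Parse one or more profiles from a HMMER3 ASCII stream.

    Probabilities are recovered as ``exp(-value)``; ``*`` means zero.
    ``GA``/``TC``/``NC`` header lines, when present, populate
    :attr:`ProfileHMM.cutoffs`.  The node-0 insert emission line is taken
    as the background (null) composition, which is how HMMER files carry
    it in practice.
    """
    lines = list(stream)
    models: list[ProfileHMM] = []
    i = 0
    n = len(lines)

    def skip_blank(j: int) -> int:
        while j < n and not lines[j].strip():
            j += 1
        return j

    i = skip_blank(i)
    if i >= n:
        raise FormatError("empty stream: no HMMER3 header found")
    while True:
        i = skip_blank(i)
        if i >= n:
            break
        header = lines[i].strip()
        if not header.startswith("HMMER3"):
            raise FormatError(
                f"line {i + 1}: expected a HMMER3 format header, got {header.splitlines()[0]!r}"
            )
        i += 1
        name = ""
        leng = -1
        ga = tc = nc = None
        # --- per-record header section
        while i < n:
            line = lines[i].rstrip("\n")
            tok = line.split()
            if tok and tok[0] == "HMM":
                break
            if tok:
                key = tok[0]
                if key == "NAME" and len(tok) > 1:
                    name = tok[1]
                elif key == "LENG":
                    leng = int(tok[1])
                elif key == "ALPH" and tok[1].lower() != "amino":
                    raise HmmParseError(f"line {i + 1}: unsupported alphabet {tok[1]!r}")
                elif key in ("GA", "TC", "NC"):
                    val = float(tok[1].rstrip(";"))
                    if key == "GA":
                        ga = val
                    elif key == "TC":
                        tc = val
                    else:
                        nc = val
            i += 1
        if i >= n:
            raise HmmParseError(f"record {name!r}: no HMM parameter section found")
        i += 1  # skip "HMM  A  C ..." column-header line
        if i < n and lines[i].split()[:1] == ["m->m"]:
            i += 1
        else:
            raise HmmParseError(f"line {i + 1}: expected transition-order header line")
        i = skip_blank(i)
        if i < n and lines[i].split()[:1] == ["COMPO"]:
            i += 1  # average model composition; background comes from insert0
        # node 0: insert emissions + begin transitions
        bg_tokens = lines[i].split()
        if len(bg_tokens) != 20:
            raise HmmParseError(f"node 0: insert emission row has {len(bg_tokens)} values, want 20")
        background = np.array(
            [_decode(t, line_no=i + 1, what="insert emission") for t in bg_tokens]
        )
        i += 1
        t0_tokens = lines[i].split()
        if len(t0_tokens) != 7:
            raise HmmParseError(f"node 0: transition row has {len(t0_tokens)} values, want 7")
        trans_rows = [[_decode(t, line_no=i + 1, what="transition") for t in t0_tokens]]
        i += 1
        match_rows: list[list[float]] = []
        insert_rows: list[list[float]] = []
        node = 0
        while i < n:
            tok = lines[i].split()
            if tok and tok[0] == "//":
                i += 1
                break
            node += 1
            if not tok or not tok[0].isdigit() or int(tok[0]) != node:
                raise HmmParseError(f"node {node}: expected match-state line, got {lines[i]!r}")
            vals = tok[1:21]
            if len(vals) < 20:
                raise HmmParseError(f"node {node}: match emission row has {len(vals)} values, want 20")
            match_rows.append([_decode(t, line_no=i + 1, what="match emission") for t in vals])
            i += 1
            ins = lines[i].split()
            if len(ins) != 20:
                raise HmmParseError(f"node {node}: insert emission row has {len(ins)} values, want 20")
            insert_rows.append([_decode(t, line_no=i + 1, what="insert emission") for t in ins])
            i += 1
            tr = lines[i].split()
            if len(tr) != 7:
                raise HmmParseError(f"node {node}: transition row has {len(tr)} values, want 7")
            trans_rows.append([_decode(t, line_no=i + 1, what="transition") for t in tr])
            i += 1
        if leng >= 0 and node != leng:
            raise HmmParseError(f"record {name!r}: LENG says {leng} nodes but {node} parsed")
        # Five-decimal negative-log encodings (stock hmmbuild precision) leave
        # row sums off by a few 1e-6; renormalize, but reject gross deviations.
        match_arr = np.array(match_rows)
        insert_arr = np.array(insert_rows)
        trans_arr = np.array(trans_rows)
        for label, arr in (("match emission", match_arr), ("insert emission", insert_arr)):
            sums = arr.sum(axis=1)
            bad = np.nonzero(np.abs(sums - 1.0) > 1e-3)[0]
            if bad.size:
                raise HmmParseError(
                    f"record {name!r}: {label} row at node {bad[0] + 1} sums to "
                    f"{sums[bad[0]]:.6f}, not 1"
                )
            arr /= sums[:, None]
        bg_sum = background.sum()
        if abs(bg_sum - 1.0) > 1e-3:
            raise HmmParseError(f"record {name!r}: background sums to {bg_sum:.6f}, not 1")
        background = background / bg_sum
        for grp in ((0, 1, 2), (3, 4), (5, 6)):
            sums = trans_arr[:, grp].sum(axis=1)
            bad = np.nonzero(np.abs(sums - 1.0) > 1e-3)[0]
            if bad.size:
                raise HmmParseError(
                    f"record {name!r}: transition group at node {bad[0]} sums to "
                    f"{sums[bad[0]]:.6f}, not 1"
                )
            trans_arr[:, grp] /= sums[:, None]
        cutoffs = None
        if ga is not None or tc is not None or nc is not None:
            g = ga if ga is not None else (tc if tc is not None else nc)
            trusted = tc if tc is not None else g
            noise = nc if nc is not None else -math.inf
            cutoffs = CutoffPair(
                trusted=trusted, noise=noise, gathering=g,
                separable=noise < g <= trusted,
            )
        hmm = ProfileHMM(
            name=name or f"model{len(models) + 1}",
            match_emissions=match_arr,
            insert_emissions=insert_arr,
            transitions=trans_arr,
            background=background,
            cutoffs=cutoffs,
        )
        hmm.validate()
        models.append(hmm)
    if not models:
        raise FormatError("stream contained a header but no complete record")
    return models


def write_hmm3(hmm: ProfileHMM, stream: IO[str] | None = None) -> str:
    """Serialise one profile to HMMER3/f ASCII; returns the text.

    Parameters are written as negative natural logs (``*`` for
    probability zero).  Cutoffs, when present, become ``GA``/``TC``/``NC``
    lines.  The output re-parses to an equal model within 1e-6.
    """
    hmm.validate()
    m = hmm.length
    out: list[str] = []
    out.append("HMMER3/f [3.4 | Aug 2023]")
    out.append(f"NAME  {hmm.name}")
    out.append(f"LENG  {m}")
    out.append("ALPH  amino")
    out.append("RF    no")
    out.append("MM    no")
    out.append("CONS  yes")
    out.append("CS    no")
    out.append("MAP   no")
    if hmm.cutoffs is not None:
        c = hmm.cutoffs
        out.append(f"GA    {c.gathering:.2f} {c.gathering:.2f};")
        if math.isfinite(c.trusted):
            out.append(f"TC    {c.trusted:.2f} {c.trusted:.2f};")
        if math.isfinite(c.noise):
            out.append(f"NC    {c.noise:.2f} {c.noise:.2f};")
    out.append("HMM     " + "".join(f"{a:>13s}" for a in AMINO_ACIDS))
    out.append("        " + "".join(
        f"{t:>13s}" for t in ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")))
    # COMPO: written as the background composition (informational only).
    out.append("  COMPO " + "".join(_encode(p) for p in hmm.background))
    out.append("        " + "".join(_encode(p) for p in hmm.background))
    out.append("        " + "".join(_encode(p) for p in hmm.transitions[0]))
    cons = hmm.consensus()
    for k in range(m):
        row = "".join(_encode(p) for p in hmm.match_emissions[k])
        out.append(f"{k + 1:7d} {row}      - {cons[k].lower()} - - -")
        out.append("        " + "".join(_encode(p) for p in hmm.insert_emissions[k]))
        out.append("        " + "".join(_encode(p) for p in hmm.transitions[k + 1]))
    out.append("//")
    text = "\n".join(out) + "\n"
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Construction from a seed alignment
# ---------------------------------------------------------------------------

def build_from_alignment(
    aligned_seqs: Sequence[str],
    pseudocount: float = 1.0,
    match_fraction: float = 0.5,
    name: str = "model",
) -> ProfileHMM:
    """Build a profile from a gapped protein alignment.

    Columns whose non-gap fraction is at least ``match_fraction`` become
    match states.  Match emissions are Laplace-smoothed column counts,
    ``(count + pseudocount) / (column_total + 20 * pseudocount)``;
    transitions are smoothed counts over the observed per-sequence state
    paths; the background is the smoothed overall residue composition.
    Insert states emit the background (zero log-odds contribution).
    """
    if len(aligned_seqs) < 2:
        raise ValidationError("need at least 2 aligned sequences")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if not (0 < match_fraction <= 1):
        raise ValidationError("match_fraction must be in (0, 1]")
    seqs = [s.upper() for s in aligned_seqs]
    ncol = len(seqs[0])
    if ncol < 1 or any(len(s) != ncol for s in seqs):
        raise ValidationError("aligned sequences must share one non-zero length")
    for s in seqs:
        bad = set(s) - set(AMINO_ACIDS) - _GAP_CHARS
        if bad:
            raise ValidationError(f"alignment contains non-amino characters: {sorted(bad)}")

    nseq = len(seqs)
    is_match = [
        sum(1 for s in seqs if s[c] not in _GAP_CHARS) / nseq >= match_fraction
        for c in range(ncol)
    ]
    m = sum(is_match)
    if m == 0:
        raise ConstructionError("no alignment column passes the match-state rule")

    match_counts = np.zeros((m, 20))
    bg_counts = np.zeros(20)
    # transition counts per node 0..M; states encoded 0=M, 1=I, 2=D
    tcounts = np.zeros((m + 1, 7))
    _pair_to_slot = {(0, 0): _MM, (0, 1): _MI, (0, 2): _MD,
                     (1, 0): _IM, (1, 1): _II,
                     (2, 0): _DM, (2, 2): _DD}
    for s in seqs:
        prev_state, prev_node = 0, 0  # begin acts as match state of node 0
        node = 0
        for c in range(ncol):
            ch = s[c]
            gap = ch in _GAP_CHARS
            if not gap:
                bg_counts[_AA_INDEX[ch]] += 1
            if is_match[c]:
                node += 1
                state = 2 if gap else 0
                if not gap:
                    match_counts[node - 1, _AA_INDEX[ch]] += 1
                tcounts[prev_node, _pair_to_slot[(prev_state, state)]] += 1
                prev_state, prev_node = state, node
            elif not gap:
                state = 1  # insert attached to current node
                slot = _pair_to_slot.get((prev_state, state))
                if slot is None:  # D -> I: not representable; treat as I continuation
                    slot = _II
                tcounts[prev_node, slot] += 1
                prev_state, prev_node = state, node
        # exit: transition into the (virtual) match state of node M+1
        if prev_state in (0, 1, 2):
            slot = _pair_to_slot.get((prev_state, 0), _DM)
            tcounts[prev_node, slot] += 1

    match_totals = match_counts.sum(axis=1, keepdims=True)
    match_em = (match_counts + pseudocount) / (match_totals + 20 * pseudocount)
    background = (bg_counts + pseudocount) / (bg_counts.sum() + 20 * pseudocount)
    insert_em = np.tile(background, (m, 1))

    trans = np.zeros((m + 1, 7))
    smoothed = tcounts + pseudocount
    # node M has no downstream delete state: M->D and D->D are structural zeros
    smoothed[m, _MD] = 0.0
    smoothed[m, _DD] = 0.0
    for grp in ((_MM, _MI, _MD), (_IM, _II), (_DM, _DD)):
        sub = smoothed[:, grp]
        tot = sub.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(tot > 0, sub / tot, 0.0)
        trans[:, grp] = norm
    trans[m, _DM] = 1.0
    trans[m, _DD] = 0.0

    hmm = ProfileHMM(
        name=name,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        background=background,
    )
    hmm.validate()
    return hmm


# ---------------------------------------------------------------------------
# Local Viterbi scoring
# ---------------------------------------------------------------------------

def _log2(arr: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(arr)


def _encode_protein(protein: str) -> list[int]:
    if not protein:
        raise ValidationError("protein sequence is empty")
    idx = []
    for ch in protein.upper():
        if ch == "X":
            idx.append(-1)
        elif ch in _AA_INDEX:
            idx.append(_AA_INDEX[ch])
        else:
            raise ValidationError(f"protein contains invalid residue {ch!r}")
    return idx


def viterbi_raw(hmm: ProfileHMM, protein: str) -> tuple[float, int, int, int, int]:
    """Best local-alignment log-odds score in bits, with coordinates.

    Returns ``(score, seq_start, seq_end, node_start, node_end)`` with
    half-open 0-based intervals.  Unlike :func:`score_local` this always
    returns the best score, even when it is non-positive.  Ties between
    equal-scoring alignments are broken toward the smallest ``seq_start``,
    then the smallest ``node_start``.

    Entry into the model is uniform over the M match nodes (a fixed
    ``-log2(M)`` bits); exit from any match node is free; residues outside
    the aligned interval contribute nothing.  Unknown residues ``X`` have
    zero log-odds in every state.
    """
    xs = _encode_protein(protein)
    m = hmm.length
    L = len(xs)
    lbg = _log2(hmm.background)
    me = _log2(hmm.match_emissions) - lbg[None, :]  # (M, 20) log-odds
    ie = _log2(hmm.insert_emissions) - lbg[None, :]
    lt = _log2(hmm.transitions)  # (M+1, 7)
    entry = -math.log2(m)
    NEG = -math.inf

    # transition vectors indexed by destination match node j (0-based):
    # predecessor node = j (1-based) -> row j of lt
    tMM = lt[:-1, _MM]  # from node k (row k) for k=0..M-1; used shifted
    tIM = lt[:-1, _IM]
    tDM = lt[:-1, _DM]
    tMI = lt[1:, _MI]  # insert I_j fed from M_j: row j (1-based) = lt[1:]
    tII = lt[1:, _II]
    tMD = lt[1:-1, _MD] if m > 1 else np.zeros(0)  # D_{j+1} from M_j, rows 1..M-1
    tDD = lt[1:-1, _DD] if m > 1 else np.zeros(0)

    vm = np.full(m, NEG)
    vi = np.full(m, NEG)
    vd = np.full(m, NEG)
    # start coordinates carried per cell (lexicographic tie-break)
    sm_i = np.zeros(m, dtype=np.int64); sm_j = np.zeros(m, dtype=np.int64)
    si_i = np.zeros(m, dtype=np.int64); si_j = np.zeros(m, dtype=np.int64)
    sd_i = np.zeros(m, dtype=np.int64); sd_j = np.zeros(m, dtype=np.int64)

    best = NEG
    best_start = (0, 0)
    best_end = (0, 0)
    js = np.arange(m, dtype=np.int64)

    def reduce_lex(cands):
        s, a, b = cands[0]
        for s2, a2, b2 in cands[1:]:
            take = (s2 > s) | ((s2 == s) & ((a2 < a) | ((a2 == a) & (b2 < b))))
            s = np.where(take, s2, s)
            a = np.where(take, a2, a)
            b = np.where(take, b2, b)
        return s, a, b

    def shift(arr, fill=NEG):
        out = np.empty_like(arr)
        out[0] = fill
        out[1:] = arr[:-1]
        return out

    for i, x in enumerate(xs):
        em = me[:, x] if x >= 0 else np.zeros(m)
        emi = ie[:, x] if x >= 0 else np.zeros(m)
        cands = [
            (np.full(m, entry), np.full(m, i, dtype=np.int64), js),
            (shift(vm) + np.concatenate(([NEG], tMM[1:])) if m > 1 else np.full(m, NEG),
             shift(sm_i, 0), shift(sm_j, 0)),
            (shift(vi) + np.concatenate(([NEG], tIM[1:])) if m > 1 else np.full(m, NEG),
             shift(si_i, 0), shift(si_j, 0)),
            (shift(vd) + np.concatenate(([NEG], tDM[1:])) if m > 1 else np.full(m, NEG),
             shift(sd_i, 0), shift(sd_j, 0)),
        ]
        with np.errstate(invalid="ignore"):
            nvm_base, nsm_i, nsm_j = reduce_lex(cands)
        nvm = em + nvm_base
        # insert states (same-node, previous row)
        ci = [
            (vm + tMI, sm_i, sm_j),
            (vi + tII, si_i, si_j),
        ]
        nvi_base, nsi_i, nsi_j = reduce_lex(ci)
        nvi = emi + nvi_base
        # delete chain along the new row (D consumes no residue)
        nvd = np.full(m, NEG)
        nsd_i = np.zeros(m, dtype=np.int64)
        nsd_j = np.zeros(m, dtype=np.int64)
        if m > 1:
            lvm = nvm.tolist(); lvd = [NEG] * m
            lmi = nsm_i.tolist(); lmj = nsm_j.tolist()
            ldi = [0] * m; ldj = [0] * m
            ltMD = tMD.tolist(); ltDD = tDD.tolist()
            for j in range(1, m):
                a = lvm[j - 1] + ltMD[j - 1]
                b = lvd[j - 1] + ltDD[j - 1]
                if a > b or (a == b and (lmi[j - 1], lmj[j - 1]) <= (ldi[j - 1], ldj[j - 1])):
                    lvd[j] = a; ldi[j] = lmi[j - 1]; ldj[j] = lmj[j - 1]
                else:
                    lvd[j] = b; ldi[j] = ldi[j - 1]; ldj[j] = ldj[j - 1]
            nvd = np.array(lvd)
            nsd_i = np.array(ldi, dtype=np.int64)
            nsd_j = np.array(ldj, dtype=np.int64)
        vm, vi, vd = nvm, nvi, nvd
        sm_i, sm_j, si_i, si_j, sd_i, sd_j = nsm_i, nsm_j, nsi_i, nsi_j, nsd_i, nsd_j
        # ends must be in a match state; exit is free
        row_best = np.max(vm)
        if row_best > NEG:
            mask = vm == row_best
            cand_idx = np.nonzero(mask)[0]
            # among tied cells prefer smallest (start_i, start_j), then node
            order = sorted(cand_idx, key=lambda j: (sm_i[j], sm_j[j], j))
            jbest = order[0]
            if (row_best > best
                    or (row_best == best
                        and (sm_i[jbest], sm_j[jbest]) < best_start)):
                best = row_best
                best_start = (int(sm_i[jbest]), int(sm_j[jbest]))
                best_end = (i, int(jbest))
    if not math.isfinite(best):
        # degenerate: every single-residue alignment hit a zero emission
        return (NEG, 0, 1, 0, 1)
    return (float(best), best_start[0], best_end[0] + 1, best_start[1], best_end[1] + 1)


def score_local(hmm: ProfileHMM, protein: str, orf_id: str = "query") -> Optional[HmmHit]:
    """Score a protein against a profile; return the best local hit.

    Returns ``None`` when no local alignment achieves a strictly positive
    bit score.  See :func:`viterbi_raw` for the scoring definition.
    """
    score, s0, s1, n0, n1 = viterbi_raw(hmm, protein)
    if not (score > 0.0):
        return None
    hit = HmmHit(
        orf_id=orf_id, hmm_name=hmm.name, bit_score=score,
        seq_start=s0, seq_end=s1, node_start=n0, node_end=n1,
    )
    hit.validate()
    return hit


def hits_to_tsv(hits: Iterable[HmmHit]) -> str:
    """Render hits as the package's TSV interchange format."""
    lines = ["orf_id\thmm_name\tbit_score\tseq_start\tseq_end\tnode_start\tnode_end"]
    for h in hits:
        lines.append(
            f"{h.orf_id}\t{h.hmm_name}\t{h.bit_score:.4f}\t"
            f"{h.seq_start}\t{h.seq_end}\t{h.node_start}\t{h.node_end}"
        )
    return "\n".join(lines) + "\n"
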