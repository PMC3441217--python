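"""Stem-loop folding and novel-miRNA candidate calling.

The folder finds, by dynamic programming, the nested (pseudoknot-free)
secondary structure minimizing a stacking-energy objective on the kcal/mol
scale: per-stacked-pair energies come from an embedded nearest-neighbor-style
constant table (GC-rich stacks more stable than AU, G:T wobble weakest), with
hairpin-loop, bulge and internal-loop penalties from embedded constant tables
and a flat multiloop-closing penalty.  Energies are held internally in integer
tenths of kcal/mol, so ties are exact and the 5'-most pairing is preferred
deterministically.  Absolute values approximate standard nearest-neighbor
magnitudes but are not those of a full thermodynamic folder; candidate
acceptance is therefore validated with planted/shuffled contrasts rather than
absolute energies.

Candidate calling mirrors the classical single-read hairpin criteria: a
genome-mapped tag of 18-26 nt is embedded in two windows (tag on the 5' or
3' arm), each window is folded, and the candidate passes if the fold energy
is at most -18 kcal/mol, the mature lies wholly on one arm, at least 14 bases
of the mature pair with a star region at most 35 nt away, at least 60% of
mature bases are paired, and at least 10 nt of flank lie inside the window
on both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io import UniqueTag

__all__ = [
    "HairpinConfig",
    "HairpinCandidate",
    "fold_hairpin",
    "structure_energy",
    "pairs_from_dotbracket",
    "call_candidates",
    "evaluate_window",
    "star_overhang_check",
    "dinucleotide_shuffle",
    "map_tag_to_genome",
]

INF = 10_000_000
MIN_LOOP = 3  # smallest hairpin loop
MAX_TWOLOOP = 30  # largest unpaired stretch per side in a bulge/internal loop

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}

# pair codes: AT=0 TA=1 GC=2 CG=3 GT=4 TG=5; -1 = not pairable
_PAIR_CODE = -np.ones((4, 4), dtype=np.int32)
for _code, (_a, _b) in enumerate(["AT", "TA", "GC", "CG", "GT", "TG"]):
    _PAIR_CODE[_ENC[_a], _ENC[_b]] = _code

# stacking energies in deci-kcal/mol by pair-class of the outer/inner pair
_CLS = {0: 0, 1: 0, 2: 1, 3: 1, 4: 2, 5: 2}  # 0=A:T, 1=G:C, 2=G:T
_STACK_BY_CLS = {
    (0, 0): -11, (0, 1): -22, (1, 1): -33,
    (0, 2): -7, (1, 2): -14, (2, 2): -4,
}
_STACK = np.zeros((6, 6), dtype=np.int32)
for _i in range(6):
    for _j in range(6):
        _a, _b = sorted((_CLS[_i], _CLS[_j]))
        _STACK[_i, _j] = _STACK_BY_CLS[(_a, _b)]

_MULTI_CLOSE = 46  # flat penalty for closing a multiloop


def _loop_tables(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hairpin / bulge / internal penalty tables (deci-kcal) up to size n."""
    hp = np.full(n + 1, INF, dtype=np.int32)
    base_hp = {3: 56, 4: 50, 5: 48, 6: 50, 7: 52, 8: 54}
    for s in range(3, n + 1):
        hp[s] = base_hp.get(s, 54 + round(17.5 * math.log(s / 8.0)))
    bulge = np.full(n + 1, INF, dtype=np.int32)
    for s in range(1, n + 1):
        bulge[s] = 38 if s == 1 else 52 + round(17.5 * math.log(s / 2.0))
    internal = np.full(n + 1, INF, dtype=np.int32)
    for s in range(2, n + 1):
        internal[s] = 50 + round(17.5 * math.log(s / 2.0))
    return hp, bulge, internal


_TAB_N = 512
_HP_TAB, _BULGE_TAB, _INTERNAL_TAB = _loop_tables(_TAB_N)


def _twoloop_energy(pc_out: int, pc_in: int, n1: int, n2: int) -> int:
    """Energy of the loop between two pairs with n1/n2 unpaired per side."""
    if n1 == 0 and n2 == 0:
        return int(_STACK[pc_out, pc_in])
    if n1 == 0 or n2 == 0:
        return int(_BULGE_TAB[n1 + n2])
    return int(_INTERNAL_TAB[n1 + n2]) + min(30, 5 * abs(n1 - n2))


@njit(cache=True)
def _fill_dp(s, pair_code, stack, hp_tab, bulge_tab, internal_tab):  # pragma: no cover
    n = s.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    M = np.full((n, n), INF, dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            pc = pair_code[s[i], s[j]]
            if pc >= 0:
                best = int(hp_tab[j - i - 1]) if j - i - 1 <= _TAB_N_C else INF
                kmax = min(i + 1 + MAX_TWOLOOP, j - 2)
                for k in range(i + 1, kmax + 1):
                    lmin = max(k + 1, j - 1 - MAX_TWOLOOP)
                    for l in range(lmin, j):
                        if V[k, l] < INF:
                            n1 = k - i - 1
                            n2 = j - l - 1
                            if n1 == 0 and n2 == 0:
                                e = stack[pc, pair_code[s[k], s[l]]]
                            elif n1 == 0 or n2 == 0:
                                e = bulge_tab[n1 + n2]
                            else:
                                asym = 5 * (n1 - n2 if n1 > n2 else n2 - n1)
                                if asym > 30:
                                    asym = 30
                                e = internal_tab[n1 + n2] + asym
                            cand = e + V[k, l]
                            if cand < best:
                                best = cand
                for m in range(i + 2, j - 2):
                    if M[i + 1, m] < INF and M[m + 1, j - 1] < INF:
                        cand = _MULTI_C + M[i + 1, m] + M[m + 1, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # M: at least one branch in [i, j]
            best_m = M[i, j - 1] if j > i else INF
            for k in range(i, j - MIN_LOOP):
                if V[k, j] < INF:
                    pre = 0
                    if k > i and M[i, k - 1] < 0:
                        pre = M[i, k - 1]
                    cand = V[k, j] + pre
                    if cand < best_m:
                        best_m = cand
            M[i, j] = best_m
    W = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        best = W[j]
        for i in range(0, j - MIN_LOOP):
            if V[i, j] < INF:
                cand = W[i] + V[i, j]
                if cand < best:
                    best = cand
        W[j + 1] = best
    return V, M, W


# module-level constants for numba (closed over as globals)
_TAB_N_C = _TAB_N
_MULTI_C = _MULTI_CLOSE


def _encode(seq: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT character(s) {sorted(bad)} in fold input")
    return np.array([_ENC[c] for c in s], dtype=np.int8)


def _trace_V(i, j, s, V, M, pairs):
    pairs.append((i, j))
    pc = int(_PAIR_CODE[s[i], s[j]])
    target = int(V[i, j])
    if j - i - 1 <= _TAB_N and target == int(_HP_TAB[j - i - 1]):
        return
    kmax = min(i + 1 + MAX_TWOLOOP, j - 2)
    for k in range(i + 1, kmax + 1):
        lmin = max(k + 1, j - 1 - MAX_TWOLOOP)
        for l in range(j - 1, lmin - 1, -1):  # widest inner pair first
            if V[k, l] < INF:
                pc_in = int(_PAIR_CODE[s[k], s[l]])
                e = _twoloop_energy(pc, pc_in, k - i - 1, j - l - 1)
                if e + int(V[k, l]) == target:
                    _trace_V(k, l, s, V, M, pairs)
                    return
    for m in range(i + 2, j - 2):
        if M[i + 1, m] < INF and M[m + 1, j - 1] < INF:
            if _MULTI_CLOSE + int(M[i + 1, m]) + int(M[m + 1, j - 1]) == target:
                _trace_M(i + 1, m, s, V, M, pairs)
                _trace_M(m + 1, j - 1, s, V, M, pairs)
                return
    raise AssertionError("traceback failed (inconsistent DP tables)")


def _trace_M(i, j, s, V, M, pairs):
    target = int(M[i, j])
    for k in range(i, j - MIN_LOOP):  # 5'-most branch first
        if V[k, j] < INF:
            pre = int(M[i, k - 1]) if (k > i and M[i, k - 1] < 0) else 0
            if int(V[k, j]) + pre == target:
                if pre:
                    _trace_M(i, k - 1, s, V, M, pairs)
                _trace_V(k, j, s, V, M, pairs)
                return
    if j > i and int(M[i, j - 1]) == target:
        _trace_M(i, j - 1, s, V, M, pairs)
        return
    raise AssertionError("traceback failed (inconsistent DP tables)")


def fold_hairpin(seq: str) -> tuple[str, float]:
    """Fold a sequence; returns (dot-bracket structure, energy in kcal/mol).

    The energy is <= 0; a sequence with no admissible pairs (or where every
    structure costs more than the open chain) returns the open structure with
    energy 0.  Deterministic: ties are broken toward 5'-most pairings.
    """
    s = _encode(seq)
    n = len(s)
    if n < MIN_LOOP + 2:
        return "." * n, 0.0
    V, M, W = _fill_dp(s, _PAIR_CODE, _STACK, _HP_TAB, _BULGE_TAB, _INTERNAL_TAB)
    pairs: list[tuple[int, int]] = []
    j = n - 1
    while j >= 0:
        if int(W[j + 1]) == int(W[j]):
            j -= 1
            continue
        chosen = None
        for i in range(0, j - MIN_LOOP):  # 5'-most pairing preferred
            if V[i, j] < INF and int(W[i]) + int(V[i, j]) == int(W[j + 1]):
                chosen = i
                break
        assert chosen is not None
        _trace_V(chosen, j, s, V, M, pairs)
        j = chosen - 1
    db = ["."] * n
    for a, b in pairs:
        db[a], db[b] = "(", ")"
    return "".join(db), int(W[n]) / 10.0


def pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def structure_energy(seq: str, structure: str) -> float:
    """Score a dot-bracket structure under the embedded energy model (kcal/mol).

    Pure-Python loop decomposition: each pair closes either a hairpin loop, a
    two-loop (stack / bulge / internal) or a multiloop; external bases are
    free.  The folder's returned (structure, energy) always satisfy
    ``structure_energy(seq, structure) == energy``.
    """
    s = _encode(seq)
    pairs = pairs_from_dotbracket(structure)
    partner = {a: b for a, b in pairs} | {b: a for a, b in pairs}
    total = 0
    for (i, j) in pairs:
        pc = int(_PAIR_CODE[s[i], s[j]])
        if pc < 0:
            raise ValueError(f"non-pairable bases at ({i}, {j})")
        if j - i - 1 < MIN_LOOP:
            raise ValueError(f"hairpin loop below {MIN_LOOP} nt at ({i}, {j})")
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            total += int(_HP_TAB[j - i - 1])
        elif len(children) == 1:
            (k, l) = children[0]
            pc_in = int(_PAIR_CODE[s[k], s[l]])
            total += _twoloop_energy(pc, pc_in, k - i - 1, j - l - 1)
        else:
            total += _MULTI_CLOSE
    return total / 10.0


# ---------------------------------------------------------------------------
# candidate calling
# ---------------------------------------------------------------------------

@dataclass
class HairpinConfig:
    """Knobs of the hairpin caller (defaults follow the classical criteria)."""

    flank: int = 10  # nt of genomic flank required inside the window
    loop_max: int = 35  # max space between mature and star
    energy_max: float = -18.0  # kcal/mol; fold energy must be <= this
    duplex_min: int = 14  # min mature bases paired to the star region
    pct_min: float = 0.60  # min fraction of mature bases paired
    tag_len_range: tuple[int, int] = (18, 26)
    fold_len_range: tuple[int, int] = (40, 200)
    overhang_hard_filter: bool = False
    min_tpm: float | None = None  # abundance post-filter, off by default


@dataclass
class HairpinCandidate:
    contig: str
    start: int  # 0-based half-open genomic interval of the window
    end: int
    strand: str
    window_seq: str
    structure: str
    energy: float
    mature_tag: UniqueTag
    mature_local: tuple[int, int]  # 0-based inclusive within window
    star_interval: tuple[int, int] | None
    duplex_pairs: int
    loop_span: int | None
    flank_5: int
    flank_3: int
    passed: dict[str, bool] = field(default_factory=dict)
    accepted: bool = False


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def map_tag_to_genome(
    seq: str, genome: dict[str, str]
) -> list[tuple[str, int, str]]:
    """All exact occurrences of ``seq`` as (contig, 0-based start, strand)."""
    hits = []
    for contig, cseq in genome.items():
        for strand, text in (("+", cseq), ("-", _revcomp(cseq))):
            i = text.find(seq)
            while i != -1:
                start = i if strand == "+" else len(cseq) - i - len(seq)
                hits.append((contig, start, strand))
                i = text.find(seq, i + 1)
    return hits


def evaluate_window(
    window_seq: str,
    mature_local: tuple[int, int],
    config: HairpinConfig,
) -> tuple[str, float, dict[str, bool], tuple[int, int] | None, int, int | None]:
    """Fold one window and test the acceptance criteria.

    Returns (structure, energy, per-criterion flags, star interval,
    duplex pair count, loop span).
    """
    structure, energy = fold_hairpin(window_seq)
    m0, m1 = mature_local
    mlen = m1 - m0 + 1
    pairs = pairs_from_dotbracket(structure)
    partner = {a: b for a, b in pairs} | {b: a for a, b in pairs}

    one_arm = not any(m0 <= a <= m1 and m0 <= b <= m1 for a, b in pairs)
    partners = sorted(
        partner[k] for k in range(m0, m1 + 1) if k in partner
    ) if one_arm else []
    # the star strand is a Dicer product of about mature length: count only
    # mature pairs landing in the best mature-sized window of partner sites
    star_span = mlen + 2
    duplex_pairs = 0
    best_run: tuple[int, int] | None = None
    lo = 0
    for hi in range(len(partners)):
        while partners[hi] - partners[lo] + 1 > star_span:
            lo += 1
        if hi - lo + 1 > duplex_pairs:
            duplex_pairs = hi - lo + 1
            best_run = (partners[lo], partners[hi])
    star: tuple[int, int] | None = None
    loop_span: int | None = None
    coherent = False
    if best_run is not None:
        star = best_run
        if star[0] > m1:  # star on the 3' side
            coherent = True
            loop_span = star[0] - m1 - 1
        elif star[1] < m0:  # star on the 5' side
            coherent = True
            loop_span = m0 - star[1] - 1
    flank_5 = m0
    flank_3 = len(window_seq) - 1 - m1
    passed = {
        "energy": energy <= config.energy_max,
        "one_arm": one_arm and (coherent or duplex_pairs == 0),
        "duplex_pairs": duplex_pairs >= config.duplex_min,
        "mature_paired_pct": duplex_pairs / mlen >= config.pct_min,
        "loop_span": loop_span is not None and loop_span <= config.loop_max,
        "flanks": flank_5 >= config.flank and flank_3 >= config.flank,
    }
    return structure, energy, passed, star, duplex_pairs, loop_span


def call_candidates(
    tags: list[UniqueTag],
    genome: dict[str, str],
    config: HairpinConfig | None = None,
) -> list[HairpinCandidate]:
    """Call hairpin candidates for genome-mapped tags of 18-26 nt.

    For each genomic hit two windows are evaluated (tag on the 5' arm, tag on
    the 3' arm); minus-strand windows are reverse-complemented before folding.
    Overlapping accepted windows of the same tag are merged keeping the lower
    energy.
    """
    config = config or HairpinConfig()
    lo, hi = config.tag_len_range
    out: list[HairpinCandidate] = []
    for tag in tags:
        L = len(tag.sequence)
        if not (lo <= L <= hi):
            continue
        if config.min_tpm is not None and tag.tpm < config.min_tpm:
            continue
        accepted_for_tag: list[HairpinCandidate] = []
        hits = map_tag_to_genome(tag.sequence, genome)
        if not hits:
            raise ValueError(
                f"tag {tag.sequence!r} has no exact genomic coordinates"
            )
        for contig, g0, strand in hits:
            clen = len(genome[contig])
            g1 = g0 + L
            spans = [
                (g0 - config.flank, g1 + config.loop_max + L + config.flank),
                (g0 - config.flank - config.loop_max - L, g1 + config.flank),
            ]
            for w0, w1 in spans:
                w0, w1 = max(0, w0), min(clen, w1)
                if not (
                    config.fold_len_range[0]
                    <= w1 - w0
                    <= config.fold_len_range[1]
                ):
                    continue
                window = genome[contig][w0:w1]
                if strand == "-":
                    window = _revcomp(window)
                    m0 = (w1 - w0) - (g1 - w0)
                else:
                    m0 = g0 - w0
                m1 = m0 + L - 1
                if "N" in window:
                    continue
                structure, energy, passed, star, dpx, loop_span = evaluate_window(
                    window, (m0, m1), config
                )
                cand = HairpinCandidate(
                    contig=contig,
                    start=w0,
                    end=w1,
                    strand=strand,
                    window_seq=window,
                    structure=structure,
                    energy=energy,
                    mature_tag=tag,
                    mature_local=(m0, m1),
                    star_interval=star,
                    duplex_pairs=dpx,
                    loop_span=loop_span,
                    flank_5=m0,
                    flank_3=(w1 - w0) - 1 - m1,
                    passed=passed,
                )
                cand.accepted = all(passed.values())
                if cand.accepted and config.overhang_hard_filter:
                    cand.accepted = star_overhang_check(cand)
                if cand.accepted:
                    accepted_for_tag.append(cand)
                else:
                    out.append(cand)
        # merge overlapping accepted windows for this tag, keeping lower energy
        accepted_for_tag.sort(key=lambda c: (c.contig, c.strand, c.start))
        merged: list[HairpinCandidate] = []
        for cand in accepted_for_tag:
            if (
                merged
                and merged[-1].contig == cand.contig
                and merged[-1].strand == cand.strand
                and cand.start < merged[-1].end
            ):
                if cand.energy < merged[-1].energy:
                    merged[-1] = cand
            else:
                merged.append(cand)
        out.extend(merged)
    return out


def star_overhang_check(candidate: HairpinCandidate) -> bool:
    """Canonical Dicer geometry: ~2-nt 3' overhang on the mature/star duplex.

    Read off the structure: the mature's loop-facing 3'-side should leave
    2 +/- 1 nt unpaired (the 3' overhang of the duplex) while its 5' end is
    paired within 1 nt.  Reported as a flag; not a hard filter by default.
    """
    m0, m1 = candidate.mature_local
    pairs = pairs_from_dotbracket(candidate.structure)
    partner = {a: b for a, b in pairs} | {b: a for a, b in pairs}
    paired = [k for k in range(m0, m1 + 1) if k in partner]
    if not paired:
        return False
    u5 = paired[0] - m0
    u3 = m1 - paired[-1]
    return u5 <= 1 and 1 <= u3 <= 3


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving exact dinucleotide counts."""
    if len(seq) <= 3:
        return seq
    chars = list(seq)
    edges: dict[str, list[str]] = {}
    for a, b in zip(chars, chars[1:]):
        edges.setdefault(a, []).append(b)
    last = chars[-1]
    vertices = list(edges.keys())
    for _ in range(1000):
        # pick a candidate terminal edge for every vertex except the last
        last_edge: dict[str, str] = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        # the chosen terminal edges must lead every vertex to `last`
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        shuffled: dict[str, list[str]] = {}
        for v, succ in edges.items():
            rest = list(succ)
            if v in last_edge:
                rest.remove(last_edge[v])
            perm = [rest[i] for i in rng.permutation(len(rest))]
            if v in last_edge:
                perm.append(last_edge[v])
            shuffled[v] = perm
        walk = [chars[0]]
        ptr = {v: 0 for v in shuffled}
        cur = chars[0]
        for _ in range(len(chars) - 1):
            nxt = shuffled[cur][ptr[cur]]
            ptr[cur] += 1
            walk.append(nxt)
            cur = nxt
        return "".join(walk)
    raise RuntimeError("dinucleotide shuffle failed to converge")
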