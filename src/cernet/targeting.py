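"""Plant miRNA target discovery: cleavage sites and endogenous target mimics.

Plant miRNAs pair with their targets with perfect or near-perfect antiparallel
complementarity, guiding AGO-mediated cleavage between the target bases paired
to miRNA positions 10 and 11. Endogenous target mimics (eTMs) instead carry a
short bulge on the target strand opposite the miRNA's central positions, which
blocks cleavage and sequesters the miRNA.

Two modes are implemented over one duplex representation:

* ``cleavage`` — no bulges allowed; penalty-scored complementarity with the
  central positions required to be Watson-Crick.
* ``mimic`` — exactly one target-side bulge of 1-4 nt inserted at a "middle"
  insertion point (between the target bases paired to miRNA positions 9-10 or
  10-11 by default), with a mismatch budget over the non-middle positions.

All sequences are RNA-space (A/C/G/U), miRNA positions are 1-based 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "PairingRules",
    "Bulge",
    "DuplexAlignment",
    "TargetSite",
    "pair_state",
    "align_duplex",
    "score_cleavage",
    "check_mimic",
    "scan_transcript",
]

PairState = Literal["WC", "GU", "MM"]

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

# pair-state lookup: rows = miRNA base, cols = target base; 0=WC, 1=GU, 2=MM.
_STATE_TABLE = np.full((5, 5), 2, dtype=np.int8)
for _m, _t in ((0, 3), (3, 0), (1, 2), (2, 1)):  # A:U, U:A, C:G, G:C
    _STATE_TABLE[_m, _t] = 0
for _m, _t in ((2, 3), (3, 2)):  # G:U wobble
    _STATE_TABLE[_m, _t] = 1

_STATE_NAMES = ("WC", "GU", "MM")


@dataclass(frozen=True)
class PairingRules:
    """Tunable constants of the pairing model.

    ``middle`` is the span of miRNA positions treated as the scissile middle
    (inclusive); mimic bulges must insert between consecutive positions inside
    it, and middle positions are excluded from the mimic mismatch budget.
    Cleavage penalties are doubled over ``core_span`` (the 5' pairing core).
    """

    middle: tuple[int, int] = (9, 11)
    bulge_min: int = 1
    bulge_max: int = 4
    mm_penalty: float = 1.0
    gu_penalty: float = 0.5
    core_span: tuple[int, int] = (2, 13)
    core_multiplier: float = 2.0
    max_score: float = 4.0
    mimic_mm_budget: float = 4.0
    mimic_max_run: int = 2

    def middle_insertion_points(self) -> tuple[int, ...]:
        """miRNA positions j such that a bulge may insert between j and j+1."""
        lo, hi = self.middle
        return tuple(range(lo, hi))


DEFAULT_RULES = PairingRules()


@dataclass(frozen=True)
class Bulge:
    """An unpaired run on one side of the duplex.

    For ``side == 'target'`` the bulge inserts between the target bases paired
    to miRNA positions ``after`` and ``after + 1``.
    """

    after: int
    side: Literal["target", "mirna"]
    length: int


@dataclass
class DuplexAlignment:
    """A miRNA:target pairing with per-miRNA-position states.

    ``pair_states[i]`` is the state of miRNA position ``i + 1`` (5'->3').
    ``target_window`` is 1-based inclusive in transcript space. ``score`` is
    defined only in cleavage mode.
    """

    mirna_id: str
    target_id: str
    target_window: tuple[int, int]
    pair_states: list[PairState]
    bulges: list[Bulge]
    mode: Literal["cleavage", "mimic"]
    score: float | None = None

    @property
    def mirna_length(self) -> int:
        return len(self.pair_states)


@dataclass
class TargetSite:
    """An accepted duplex placed on a transcript.

    ``cleavage_position`` (cleavage mode only) is the transcript base paired
    to miRNA position 10 — the 5' end of the 3' cleavage fragment.
    """

    duplex: DuplexAlignment
    cleavage_position: int | None
    accept: bool = True


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-RNA character {exc.args[0]!r} in sequence") from None


def pair_state(mirna_base: str, target_base: str) -> PairState:
    return _STATE_NAMES[_STATE_TABLE[_ENCODE[mirna_base], _ENCODE[target_base]]]


def _pairing_states(mirna: np.ndarray, window: np.ndarray, insertion: int | None, k: int) -> list[PairState]:
    """States per miRNA position for a window with a target bulge of length
    ``k`` after miRNA position ``insertion`` (``None`` for no bulge)."""
    L, Lw = len(mirna), len(window)
    states: list[PairState] = []
    for i in range(1, L + 1):  # miRNA position, 1-based
        col = Lw - i if insertion is None or i <= insertion else Lw - i - k
        states.append(_STATE_NAMES[_STATE_TABLE[mirna[i - 1], window[col]]])
    return states


def _plain_penalty(states: Sequence[PairState], rules: PairingRules) -> float:
    pen = {"WC": 0.0, "GU": rules.gu_penalty, "MM": rules.mm_penalty}
    return sum(pen[s] for s in states)


def align_duplex(
    mirna: str,
    window: str,
    mode: Literal["cleavage", "mimic"],
    rules: PairingRules = DEFAULT_RULES,
    mirna_id: str = "miRNA",
    target_id: str = "target",
    window_start: int = 1,
) -> DuplexAlignment | None:
    """Antiparallel pairing of a target window against a miRNA.

    Cleavage mode admits only bulge-free windows (length equal to the miRNA).
    Mimic mode admits one target-side bulge of ``bulge_min``-``bulge_max`` nt
    at a middle insertion point; among admissible insertion points the
    minimal-penalty one is chosen, ties broken by the leftmost insertion
    point. Returns ``None`` when the window length is inadmissible for the
    mode. ``window_start`` anchors ``target_window`` in transcript space.
    """
    m = _encode(mirna.upper().replace("T", "U"))
    w = _encode(window.upper().replace("T", "U"))
    L, Lw = len(m), len(w)
    if Lw < L - 1 or Lw > L + rules.bulge_max:
        raise ValueError(
            f"window length {Lw} outside admissible range "
            f"[{L - 1}, {L + rules.bulge_max}] for miRNA length {L}"
        )
    span = (window_start, window_start + Lw - 1)

    if mode == "cleavage":
        if Lw != L:
            return None
        states = _pairing_states(m, w, None, 0)
        d = DuplexAlignment(mirna_id, target_id, span, states, [], "cleavage")
        d.score = score_cleavage(d, rules)[0]
        return d

    if mode == "mimic":
        k = Lw - L
        if k == 0:
            return DuplexAlignment(mirna_id, target_id, span, _pairing_states(m, w, None, 0), [], "mimic")
        if k < rules.bulge_min or k > rules.bulge_max:
            return None
        best: tuple[float, int, list[PairState]] | None = None
        for j in rules.middle_insertion_points():
            states = _pairing_states(m, w, j, k)
            penalty = _plain_penalty(states, rules)
            if best is None or penalty < best[0]:
                best = (penalty, j, states)
        if best is None:
            return None
        _, j, states = best
        return DuplexAlignment(
            mirna_id, target_id, span, states, [Bulge(j, "target", k)], "mimic"
        )

    raise ValueError(f"unknown mode {mode!r}")


def score_cleavage(
    d: DuplexAlignment, rules: PairingRules = DEFAULT_RULES
) -> tuple[float, bool]:
    """Penalty score and acceptance for a cleavage-mode duplex.

    Score sums MM=1 and G:U=0.5 penalties, doubled over the core span
    (miRNA positions 2-13). Accept iff score <= ``max_score`` and the bases at
    miRNA positions 10-11 (the scissile site) are Watson-Crick.
    """
    if d.mode != "cleavage":
        raise ValueError("score_cleavage requires a cleavage-mode alignment")
    pen = {"WC": 0.0, "GU": rules.gu_penalty, "MM": rules.mm_penalty}
    lo, hi = rules.core_span
    score = 0.0
    for i, s in enumerate(d.pair_states, start=1):
        p = pen[s]
        if lo <= i <= hi:
            p *= rules.core_multiplier
        score += p
    scissile_ok = all(
        d.pair_states[i - 1] == "WC"
        for i in (10, 11)
        if i <= len(d.pair_states)
    )
    return score, (score <= rules.max_score and scissile_ok)


def check_mimic(
    d: DuplexAlignment, rules: PairingRules = DEFAULT_RULES
) -> tuple[bool, list[str]]:
    """Validate a mimic-mode duplex against the three target-mimicry rules.

    I.  Exactly one bulge, on the target (ncRNA) side, inserting at a middle
        insertion point.
    II. Over non-middle miRNA positions: mismatch budget (MM=1, G:U=0.5)
        <= 4, and no run of more than two consecutive mismatches (G:U pairs
        neither count toward nor extend a run).
    III. No bulge anywhere else.

    Returns ``(accept, reasons)``; ``reasons`` lists each violated rule.
    """
    if d.mode != "mimic":
        raise ValueError("check_mimic requires a mimic-mode alignment")
    reasons: list[str] = []
    lo, hi = rules.middle
    middle_points = set(rules.middle_insertion_points())

    target_middle_bulges = [
        b for b in d.bulges if b.side == "target" and b.after in middle_points
    ]
    other_bulges = [b for b in d.bulges if b not in target_middle_bulges]
    if len(target_middle_bulges) != 1:
        reasons.append("I: requires exactly one target-side bulge at a middle insertion point")
    else:
        b = target_middle_bulges[0]
        if not (rules.bulge_min <= b.length <= rules.bulge_max):
            reasons.append(
                f"I: bulge length {b.length} outside "
                f"[{rules.bulge_min}, {rules.bulge_max}]"
            )
    if other_bulges:
        reasons.append("III: bulge at a non-middle position or on the miRNA side")

    pen = {"WC": 0.0, "GU": rules.gu_penalty, "MM": rules.mm_penalty}
    budget = 0.0
    run = 0
    max_run = 0
    for i, s in enumerate(d.pair_states, start=1):
        if lo <= i <= hi:
            run = 0  # middle positions are outside rule II entirely
            continue
        budget += pen[s]
        if s == "MM":
            run += 1
            max_run = max(max_run, run)
        else:
            run = 0
    if budget > rules.mimic_mm_budget:
        reasons.append(
            f"II: mismatch budget {budget:.1f} exceeds {rules.mimic_mm_budget:.1f}"
        )
    if max_run > rules.mimic_max_run:
        reasons.append(
            f"II: {max_run} consecutive mismatches exceed run limit {rules.mimic_max_run}"
        )
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# Transcript scanning (vectorized; must agree with align_duplex per window)
# ---------------------------------------------------------------------------

def _penalty_vectors(rules: PairingRules, L: int, mode: str) -> np.ndarray:
    """(3, L) penalty per (state, miRNA position)."""
    base = np.array([0.0, rules.gu_penalty, rules.mm_penalty])
    pens = np.tile(base[:, None], (1, L))
    if mode == "cleavage":
        lo, hi = rules.core_span
        core = np.zeros(L, dtype=bool)
        core[max(lo - 1, 0) : hi] = True
        pens[:, core] *= rules.core_multiplier
    return pens


def _scan_cleavage(
    m: np.ndarray, s: np.ndarray, rules: PairingRules
) -> list[tuple[int, float, np.ndarray]]:
    """(window_start0, score, states) for accepted cleavage windows."""
    L, n = len(m), len(s)
    if n < L:
        return []
    wins = np.lib.stride_tricks.sliding_window_view(s, L)  # (n_win, L), target 5'->3'
    # miRNA position i (1-based) pairs window column L - i (0-based).
    states = _STATE_TABLE[m[None, :], wins[:, ::-1]]  # (n_win, L), col = miRNA pos - 1
    pens = _penalty_vectors(rules, L, "cleavage")
    pos_idx = np.arange(L)
    scores = pens[states, pos_idx[None, :]].sum(axis=1)
    ok = scores <= rules.max_score
    for i in (10, 11):
        if i <= L:
            ok &= states[:, i - 1] == 0
    out = []
    for w0 in np.nonzero(ok)[0]:
        out.append((int(w0), float(scores[w0]), states[w0]))
    return out


def _scan_mimic(
    m: np.ndarray, s: np.ndarray, rules: PairingRules
) -> list[tuple[int, int, np.ndarray, int, int]]:
    """(window_start0, window_len, states, insertion, bulge_len) for candidate
    mimic windows whose minimal-penalty middle-bulge pairing passes rule II's
    budget prefilter; final acceptance is via :func:`check_mimic`."""
    L, n = len(m), len(s)
    results = []
    pens = _penalty_vectors(rules, L, "mimic")
    pos_idx = np.arange(L)
    for k in range(rules.bulge_min, rules.bulge_max + 1):
        Lw = L + k
        if n < Lw:
            continue
        wins = np.lib.stride_tricks.sliding_window_view(s, Lw)
        best_pen = None
        best_states = None
        best_j = None
        for j in rules.middle_insertion_points():
            cols = np.where(pos_idx + 1 <= j, Lw - 1 - pos_idx, Lw - 1 - pos_idx - k)
            states = _STATE_TABLE[m[None, :], wins[:, cols]]
            penalty = pens[states, pos_idx[None, :]].sum(axis=1)
            if best_pen is None:
                best_pen, best_states, best_j = penalty, states, np.full(len(wins), j)
            else:
                better = penalty < best_pen
                best_states = np.where(better[:, None], states, best_states)
                best_j = np.where(better, j, best_j)
                best_pen = np.minimum(best_pen, penalty)
        # loose prefilter: rule II budget over all positions incl. middle
        cand = best_pen <= rules.mimic_mm_budget + (rules.middle[1] - rules.middle[0] + 1)
        for w0 in np.nonzero(cand)[0]:
            results.append((int(w0), Lw, best_states[w0], int(best_j[w0]), k))
    return results


def scan_transcript(
    mirna: str,
    transcript_seq: str,
    mode: Literal["cleavage", "mimic"],
    rules: PairingRules = DEFAULT_RULES,
    mirna_id: str = "miRNA",
    target_id: str = "target",
    circular: bool = False,
) -> list[TargetSite]:
    """Scan a transcript for accepted target sites in one mode.

    Slides every admissible window, aligns it against the miRNA and keeps
    windows passing :func:`score_cleavage` / :func:`check_mimic`. For circular
    transcripts (``circular=True``) the sequence is doubled so that windows
    may span the back-splice junction; duplicate hits are removed by modular
    position. Cleavage hits are deduplicated to the best-scoring window per
    cleavage position and sorted by (score, position).
    """
    mseq = mirna.upper().replace("T", "U")
    seq = transcript_seq.upper().replace("T", "U")
    L, n = len(mseq), len(seq)
    if n < L:
        return []
    m = _encode(mseq)
    scan_seq = seq + seq if circular else seq
    s = _encode(scan_seq)

    sites: list[TargetSite] = []
    if mode == "cleavage":
        best_by_pos: dict[int, TargetSite] = {}
        for w0, score, states in _scan_cleavage(m, s, rules):
            if circular and w0 >= n:
                continue
            pos = w0 + 1 + L - 10  # transcript base paired to miRNA nt 10
            if circular:
                pos = (pos - 1) % n + 1
            d = DuplexAlignment(
                mirna_id,
                target_id,
                (w0 + 1, w0 + L),
                [_STATE_NAMES[c] for c in states],
                [],
                "cleavage",
                score=score,
            )
            site = TargetSite(d, pos)
            prev = best_by_pos.get(pos)
            if prev is None or score < prev.duplex.score:
                best_by_pos[pos] = site
        sites = sorted(
            best_by_pos.values(),
            key=lambda t: (t.duplex.score, t.cleavage_position),
        )
    else:
        seen: set[tuple[int, int]] = set()
        for w0, Lw, states, j, k in _scan_mimic(m, s, rules):
            if circular and w0 >= n:
                continue
            start = (w0 % n) + 1 if circular else w0 + 1
            key = (start, Lw)
            if key in seen:
                continue
            d = DuplexAlignment(
                mirna_id,
                target_id,
                (w0 + 1, w0 + Lw),
                [_STATE_NAMES[c] for c in states],
                [Bulge(j, "target", k)],
                "mimic",
            )
            ok, _ = check_mimic(d, rules)
            if ok:
                seen.add(key)
                if circular:
                    d.target_window = (start, start + Lw - 1)
                sites.append(TargetSite(d, None))
        sites.sort(key=lambda t: (t.duplex.target_window[0], t.duplex.target_window[1]))
    return sites
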