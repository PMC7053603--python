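"""miRNA:target duplex scanning by complementarity alignment.

A Smith-Waterman-style local alignment of the miRNA (read 3'->5') against
the target transcript (5'->3') under a complementarity scoring scheme:
Watson-Crick pairs (A:U, G:C) score as matches, G:U wobbles score between
match and mismatch, and positions falling in the miRNA seed window
(positions 2-8 from the 5' end by default) are up-weighted, reflecting the
dominant role of seed pairing.  Gap penalties are affine.  Each reported
hit also receives a hybridization free energy from a nearest-neighbor
stacking model over the contiguously paired positions; loop entropies are
ignored, so the energy is a deterministic, desk-scale approximation of a
full secondary-structure computation.

Candidate sites are screened with strict score and energy gates
(score > 140 and energy < -20 kcal/mol by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .diffexpr import ConfigError, InputError

_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Watson-Crick nearest-neighbor stack free energies (kcal/mol, 37 C),
# keyed ((a, c), (b, d)) for the stack 5'-a b-3' / 3'-c d-5'.
_WC_STACKS = {
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("U", "A")): -2.08,
    (("C", "G"), ("A", "U")): -2.11,
    (("G", "C"), ("U", "A")): -2.24,
    (("G", "C"), ("A", "U")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
}


def _full_stack_table() -> dict:
    table = dict(_WC_STACKS)
    for (p1, p2), dg in _WC_STACKS.items():
        # reading the same stack from the opposite strand
        table.setdefault(((p2[1], p2[0]), (p1[1], p1[0])), dg)
    return table


_STACK_TABLE = _full_stack_table()
_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}


def normalize_rna(seq: str) -> str:
    """Uppercase, map T->U, and validate the {A,C,G,U} alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(_BASES)
    if bad:
        raise InputError(f"invalid base(s) {sorted(bad)} in sequence")
    return s


def reverse_complement(seq: str) -> str:
    s = normalize_rna(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(s))


@dataclass(frozen=True)
class DuplexScoring:
    """Alignment scoring parameters (miRanda-flavored defaults)."""

    match_score: float = 5.0
    gu_wobble_score: float = 1.0
    mismatch_score: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_start: int = 2            # 1-based, from the miRNA 5' end
    seed_end: int = 8
    seed_scale: float = 4.0

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ConfigError("gap penalties must be <= 0")
        if not (1 <= self.seed_start < self.seed_end):
            raise ConfigError("require 1 <= seed_start < seed_end")
        if self.seed_scale < 1:
            raise ConfigError("seed_scale must be >= 1")

    def pair_score(self, mirna_base: str, target_base: str, mirna_pos: int) -> float:
        """Score one aligned column; ``mirna_pos`` is 1-based from the 5' end."""
        pair = (target_base, mirna_base)
        if pair in _WC_PAIRS:
            s = self.match_score
        elif pair in _GU_PAIRS:
            s = self.gu_wobble_score
        else:
            s = self.mismatch_score
        if self.seed_start <= mirna_pos <= self.seed_end:
            s *= self.seed_scale
        return s


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor stacking energy over contiguously paired columns.

    ``gu_stack`` is the flat energy credited to any stack involving a G:U
    wobble; ``helix_init`` is the duplex initiation penalty.
    """

    gu_stack: float = -0.5
    helix_init: float = 4.09


@dataclass(frozen=True)
class DuplexThresholds:
    """Strict score/energy gates for accepting a candidate site."""

    score_min: float = 140.0
    energy_max: float = -20.0


@dataclass
class DuplexHit:
    """One aligned miRNA:target site.

    Coordinates are 1-based inclusive; ``target_start/end`` on the target's
    5'->3' strand, ``mirna_start/end`` on the miRNA's 5'->3' strand.  The
    alignment strings show the miRNA 3'->5' over the target 5'->3';
    ``aln_pairing`` marks Watson-Crick pairs with '|', G:U wobbles with ':'
    and everything else with a space.
    """

    mirna_id: str
    target_id: str
    target_start: int
    target_end: int
    mirna_start: int
    mirna_end: int
    aln_mirna: str
    aln_pairing: str
    aln_target: str
    score: float
    energy: float


@njit(cache=False)
def _sw_kernel(S, mask, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = S.shape
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if not mask[j - 1]:
                H[i, j] = 0.0
                E[i, j] = NEG
                F[i, j] = NEG
                continue
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _pairing_char(mirna_base: str, target_base: str) -> str:
    pair = (target_base, mirna_base)
    if pair in _WC_PAIRS:
        return "|"
    if pair in _GU_PAIRS:
        return ":"
    return " "


def _score_matrix(mirna_rev: str, target: str, mirna_len: int,
                  scoring: DuplexScoring) -> np.ndarray:
    n, m = len(mirna_rev), len(target)
    S = np.empty((n, m))
    for i, mb in enumerate(mirna_rev):
        pos = mirna_len - i  # 1-based position on the miRNA 5'->3'
        for j, tb in enumerate(target):
            S[i, j] = scoring.pair_score(mb, tb, pos)
    return S


def alignment_energy(aln_mirna: str, aln_target: str,
                     model: EnergyModel = EnergyModel()) -> float:
    """Stacking free energy of an alignment (kcal/mol).

    Sums nearest-neighbor stack terms over consecutive paired columns; a
    gap or mismatch interrupts stacking, and every maximal stacked segment
    pays the helix initiation penalty (loop entropies between segments are
    otherwise ignored).  Alignments with no stacked pair get energy 0 (no
    stable duplex).
    """
    cols = list(zip(aln_mirna, aln_target))
    paired = ["-" not in (mb, tb) and (tb, mb) in (_WC_PAIRS | _GU_PAIRS)
              for mb, tb in cols]
    energy = 0.0
    in_segment = False
    for k in range(len(cols) - 1):
        if not (paired[k] and paired[k + 1]):
            in_segment = False
            continue
        (m1, t1), (m2, t2) = cols[k], cols[k + 1]
        key = ((t1, m1), (t2, m2))
        energy += _STACK_TABLE.get(key, model.gu_stack)
        if not in_segment:
            energy += model.helix_init
            in_segment = True
    return energy


def rescore_alignment(aln_mirna: str, aln_target: str, mirna_end: int,
                      scoring: DuplexScoring) -> float:
    """Recompute a hit's score from its alignment strings.

    ``mirna_end`` is the 1-based miRNA position aligned in the first column
    (the alignment shows the miRNA 3'->5', so positions decrease along it).
    """
    if len(aln_mirna) != len(aln_target):
        raise InputError("aligned strings must have equal length")
    score = 0.0
    pos = mirna_end
    in_gap_m = in_gap_t = False
    for mb, tb in zip(aln_mirna, aln_target):
        if mb == "-":
            score += scoring.gap_extend if in_gap_m else scoring.gap_open
            in_gap_m, in_gap_t = True, False
        elif tb == "-":
            score += scoring.gap_extend if in_gap_t else scoring.gap_open
            in_gap_t, in_gap_m = True, False
            pos -= 1
        else:
            score += scoring.pair_score(mb, tb, pos)
            pos -= 1
            in_gap_m = in_gap_t = False
    return score


def _traceback(H, E, F, S, i, j, mirna_rev, target, gap_extend):
    """Recover one local alignment ending at (i, j)."""
    TOL = 1e-6
    am, at = [], []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h <= TOL:
                break
            if abs(h - (H[i - 1, j - 1] + S[i - 1, j - 1])) < TOL:
                am.append(mirna_rev[i - 1])
                at.append(target[j - 1])
                i -= 1
                j -= 1
            elif abs(h - E[i, j]) < TOL:
                state = "E"
            else:
                state = "F"
        elif state == "E":      # gap in the miRNA, consume target
            am.append("-")
            at.append(target[j - 1])
            stay = abs(E[i, j] - (E[i, j - 1] + gap_extend)) < TOL
            j -= 1
            if not stay:
                state = "H"
        else:                   # gap in the target, consume miRNA
            am.append(mirna_rev[i - 1])
            at.append("-")
            stay = abs(F[i, j] - (F[i - 1, j] + gap_extend)) < TOL
            i -= 1
            if not stay:
                state = "H"
    return "".join(reversed(am)), "".join(reversed(at)), i, j



def scan_duplexes(mirna: str, target: str,
                  scoring: DuplexScoring = DuplexScoring(),
                  mirna_id: str = "mirna", target_id: str = "target",
                  energy_model: EnergyModel = EnergyModel(),
                  min_report_score: float = 0.0) -> list[DuplexHit]:
    """Scan one target for miRNA complementarity sites.

    Reports maximal non-overlapping local optima greedily by score: the
    best alignment is taken, its target interval is blocked, and scanning
    repeats until the best remaining score drops to ``min_report_score``
    (0 by default, i.e. every positive-scoring site).  Hits are sorted by
    score descending, ties by target start ascending.
    """
    mi = normalize_rna(mirna)
    tg = normalize_rna(target)
    if len(mi) < scoring.seed_end:
        raise InputError(
            f"miRNA length {len(mi)} shorter than seed_end {scoring.seed_end}")
    mirna_rev = mi[::-1]
    S = _score_matrix(mirna_rev, tg, len(mi), scoring)
    mask = np.ones(len(tg), dtype=np.bool_)
    hits: list[DuplexHit] = []
    for _ in range(len(tg)):
        H, E, F, best, bi, bj = _sw_kernel(S, mask, scoring.gap_open,
                                           scoring.gap_extend)
        if best <= max(min_report_score, 0.0):
            break
        am, at, i0, j0 = _traceback(H, E, F, S, bi, bj, mirna_rev, tg,
                                    scoring.gap_extend)
        t_start, t_end = j0 + 1, bj            # 1-based inclusive on target
        m_lo, m_hi = i0 + 1, bi                # on the reversed miRNA
        mirna_start = len(mi) - m_hi + 1       # map back to 5'->3' coords
        mirna_end = len(mi) - m_lo + 1
        hits.append(DuplexHit(
            mirna_id=mirna_id, target_id=target_id,
            target_start=t_start, target_end=t_end,
            mirna_start=mirna_start, mirna_end=mirna_end,
            aln_mirna=am,
            aln_pairing="".join(
                _pairing_char(a, b) if "-" not in (a, b) else " "
                for a, b in zip(am, at)),
            aln_target=at,
            score=float(best),
            energy=alignment_energy(am, at, energy_model),
        ))
        mask[t_start - 1:t_end] = False
    hits.sort(key=lambda h: (-h.score, h.target_start))
    return hits


def scan_all(mirnas: Mapping[str, str], targets: Mapping[str, str],
             scoring: DuplexScoring = DuplexScoring(),
             energy_model: EnergyModel = EnergyModel(),
             min_report_score: float = 0.0) -> list[DuplexHit]:
    """Scan every (miRNA, target) combination; concatenated sorted hits."""
    hits: list[DuplexHit] = []
    for m_id in sorted(mirnas):
        for t_id in sorted(targets):
            hits.extend(scan_duplexes(mirnas[m_id], targets[t_id], scoring,
                                      mirna_id=m_id, target_id=t_id,
                                      energy_model=energy_model,
                                      min_report_score=min_report_score))
    return hits


def screen_hits(hits: Sequence[DuplexHit],
                thresholds: DuplexThresholds = DuplexThresholds()) -> list[DuplexHit]:
    """Deduplicated (mirna, target) pairs passing both strict gates.

    Returns the best passing hit per pair, sorted by (mirna_id, target_id).
    """
    best: dict[tuple[str, str], DuplexHit] = {}
    for h in hits:
        if not (h.score > thresholds.score_min and h.energy < thresholds.energy_max):
            continue
        key = (h.mirna_id, h.target_id)
        cur = best.get(key)
        if cur is None or (h.score, -h.target_start) > (cur.score, -cur.target_start):
            best[key] = h
    return [best[k] for k in sorted(best)]
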