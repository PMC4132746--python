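"""Seeded local alignment of probe regions against acceptor-donor pairs.

Mimics short-query BLASTN mapping: exact word seeds choose candidate
references, each candidate is then scored by an exact affine-gap
Smith-Waterman DP (plus strand only), and the single best hit is kept
with deterministic tie-breaking.  Because candidate references are
40-mers the exact DP is cheap, so no x-drop pruning is needed for the
extension step; the x-drop parameter is retained in the config for
compatibility but the DP computes the true optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["MapperConfig", "Hit", "ProbeMapper", "smith_waterman"]

_ENCODE = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class MapperConfig:
    """Scoring and filter settings (blastn-short conventions)."""

    word_size: int = 8
    min_alignment_length: int = 30  # strict > after alignment
    max_query_start: int = 6  # strict < , 0-based
    match: int = 1
    mismatch: int = -3
    gap_open: int = 5  # cost of opening a gap (first gapped base adds gap_extend too)
    gap_extend: int = 2
    xdrop_gap: int = 7  # accepted for config compatibility; exact DP supersedes it
    best_hit_only: bool = True


@dataclass(frozen=True)
class Hit:
    """Best local alignment of a query against one reference."""

    acceptor_idx: int
    donor_idx: int
    score: int
    query_start: int
    query_end: int  # half-open
    ref_start: int
    ref_end: int
    length: int  # alignment columns, gaps included


@njit(cache=True)
def _sw(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    nq, nr = len(q), len(r)
    NEG = -(10**9)
    m_sc = np.zeros((nq + 1, nr + 1), dtype=np.int64)
    x_sc = np.full((nq + 1, nr + 1), NEG, dtype=np.int64)
    y_sc = np.full((nq + 1, nr + 1), NEG, dtype=np.int64)
    # per-state traceback info: (q_start, r_start, aln_len)
    m_info = np.zeros((nq + 1, nr + 1, 3), dtype=np.int64)
    x_info = np.zeros((nq + 1, nr + 1, 3), dtype=np.int64)
    y_info = np.zeros((nq + 1, nr + 1, 3), dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, nq + 1):
        for j in range(1, nr + 1):
            s = match if q[i - 1] == r[j - 1] else mismatch
            # match state: continue from M, X, Y, or restart
            prev = m_sc[i - 1, j - 1]
            src = 0  # 0=M, 1=X, 2=Y, 3=restart
            if x_sc[i - 1, j - 1] > prev:
                prev = x_sc[i - 1, j - 1]
                src = 1
            if y_sc[i - 1, j - 1] > prev:
                prev = y_sc[i - 1, j - 1]
                src = 2
            if prev < 0:
                prev = 0
                src = 3
            sc = prev + s
            if sc < 0:
                sc = 0
            m_sc[i, j] = sc
            if src == 3 or prev == 0:
                m_info[i, j, 0] = i - 1
                m_info[i, j, 1] = j - 1
                m_info[i, j, 2] = 1
            else:
                if src == 0:
                    info = m_info[i - 1, j - 1]
                elif src == 1:
                    info = x_info[i - 1, j - 1]
                else:
                    info = y_info[i - 1, j - 1]
                m_info[i, j, 0] = info[0]
                m_info[i, j, 1] = info[1]
                m_info[i, j, 2] = info[2] + 1
            # X: query base against gap in reference
            open_sc = m_sc[i - 1, j] - gap_open - gap_extend
            ext_sc = x_sc[i - 1, j] - gap_extend
            if open_sc >= ext_sc:
                x_sc[i, j] = open_sc
                x_info[i, j, 0] = m_info[i - 1, j, 0]
                x_info[i, j, 1] = m_info[i - 1, j, 1]
                x_info[i, j, 2] = m_info[i - 1, j, 2] + 1
            else:
                x_sc[i, j] = ext_sc
                x_info[i, j, 0] = x_info[i - 1, j, 0]
                x_info[i, j, 1] = x_info[i - 1, j, 1]
                x_info[i, j, 2] = x_info[i - 1, j, 2] + 1
            # Y: gap in query against reference base
            open_sc = m_sc[i, j - 1] - gap_open - gap_extend
            ext_sc = y_sc[i, j - 1] - gap_extend
            if open_sc >= ext_sc:
                y_sc[i, j] = open_sc
                y_info[i, j, 0] = m_info[i, j - 1, 0]
                y_info[i, j, 1] = m_info[i, j - 1, 1]
                y_info[i, j, 2] = m_info[i, j - 1, 2] + 1
            else:
                y_sc[i, j] = ext_sc
                y_info[i, j, 0] = y_info[i, j - 1, 0]
                y_info[i, j, 1] = y_info[i, j - 1, 1]
                y_info[i, j, 2] = y_info[i, j - 1, 2] + 1
            if m_sc[i, j] > best:
                best = m_sc[i, j]
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0
    qs = m_info[bi, bj, 0]
    rs = m_info[bi, bj, 1]
    ln = m_info[bi, bj, 2]
    return best, qs, bi, rs, bj, ln


def smith_waterman(query: str, ref: str, cfg: MapperConfig = MapperConfig()):
    """Exact affine-gap local alignment.

    Returns (score, q_start, q_end, r_start, r_end, aln_len); all-zero
    when no positive-scoring alignment exists.  The optimal alignment
    always ends in an aligned base pair, so only the match state is
    maximized.
    """
    return _sw(
        encode(query),
        encode(ref),
        cfg.match,
        cfg.mismatch,
        cfg.gap_open,
        cfg.gap_extend,
    )


class ProbeMapper:
    """Map probe regions to the best (acceptor_i, donor_j) combination.

    References are all n^2 concatenations acceptor_gene_i + donor_gene_j.
    A query is aligned only against references sharing at least one
    exact word seed of cfg.word_size; the best score wins, ties resolved
    to the lowest (i, j).  Hits must satisfy alignment length >
    min_alignment_length and query start < max_query_start.
    """

    def __init__(
        self,
        acceptor_seqs: list[str],
        donor_seqs: list[str],
        cfg: MapperConfig = MapperConfig(),
    ):
        if len(acceptor_seqs) != len(donor_seqs):
            raise ValueError("acceptor and donor lists must align")
        if not acceptor_seqs:
            raise ValueError("empty probe table")
        self.cfg = cfg
        self.n = len(acceptor_seqs)
        self.refs: list[str] = []
        self.pairs: list[tuple[int, int]] = []
        for i, acc in enumerate(acceptor_seqs):
            for j, don in enumerate(donor_seqs):
                self.refs.append(acc + don)
                self.pairs.append((i, j))
        k = cfg.word_size
        self.seed_index: dict[str, set[int]] = {}
        for ridx, ref in enumerate(self.refs):
            for p in range(len(ref) - k + 1):
                self.seed_index.setdefault(ref[p : p + k], set()).add(ridx)

    def _candidates(self, seq: str) -> list[int]:
        k = self.cfg.word_size
        out: set[int] = set()
        for p in range(len(seq) - k + 1):
            hits = self.seed_index.get(seq[p : p + k])
            if hits:
                out |= hits
        return sorted(out)

    def map(self, seq: str) -> Hit | None:
        """Best filtered hit for one probe-region sequence, or None."""
        cfg = self.cfg
        best: Hit | None = None
        q = encode(seq)
        for ridx in self._candidates(seq):
            score, qs, qe, rs, re_, ln = _sw(
                q,
                encode(self.refs[ridx]),
                cfg.match,
                cfg.mismatch,
                cfg.gap_open,
                cfg.gap_extend,
            )
            if score <= 0:
                continue
            if best is None or score > best.score:
                i, j = self.pairs[ridx]
                best = Hit(i, j, int(score), int(qs), int(qe), int(rs), int(re_), int(ln))
        if best is None:
            return None
        if best.length <= cfg.min_alignment_length:
            return None
        if best.query_start >= cfg.max_query_start:
            return None
        return best
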