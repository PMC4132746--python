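"""Acceptor/donor probe-set design against poly(A)-proximal windows.

For each target mRNA the designer

1. scans the 3'-terminal window (default 1 kb, where oligo(dT)-captured
   template is accessible) for 36-nt antisense candidates within Tm and
   GC bounds;
2. extends each candidate 4 nt toward the poly(A) tail and splits the
   resulting 40-mer into a 20-nt acceptor half (5' half of the antisense
   sequence, 3'-OH at the ligation junction) and a 20-nt donor half
   (5'-phosphate at the junction);
3. appends the constant adaptors (AD1 5' of the acceptor half, RCAD2
   3' of the donor half) and applies thermodynamic QC to the full
   oligos: 3'-end stability, hairpin, self-dimer, and a Tm ceiling;
4. removes probes with an off-target duplex Tm within a margin of the
   on-target Tm anywhere in a background transcriptome (both strands);
5. rank-sums distance-to-poly(A) and a Primer3-style penalty and
   greedily selects up to two probe sets per transcript whose genomic
   footprints are at least 10 nt apart;
6. emits final oligos, marking the acceptor's two 3'-terminal bases as
   ribonucleotides (required by the RNA-templated ligase) and flagging
   the donor 5'-phosphate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from scipy.stats import rankdata

from .anatomy import DEFAULT_ANATOMY, ReadAnatomy
from .thermo import (
    DEFAULT_PARAMS,
    InvalidSequenceError,
    ThermoParams,
    ThermoReport,
    duplex_tm,
    gc_percent,
    reverse_complement,
    structure_report,
)

__all__ = [
    "Transcript",
    "CandidateProbe",
    "ProbeSet",
    "DesignConfig",
    "DesignInfeasibleError",
    "BackgroundIndex",
    "generate_candidates",
    "extend_and_split",
    "qc_filter",
    "offtarget_filter",
    "rank_and_select",
    "finalize_probes",
    "design_probes",
]


class DesignInfeasibleError(ValueError):
    """Transcript too short (or otherwise unusable) for probe design."""


@dataclass(frozen=True)
class Transcript:
    """One mRNA target: sense strand, 3' end adjacent to the poly(A)
    tail (poly(A) itself excluded)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if any(b not in "ACGT" for b in seq):
            raise InvalidSequenceError(
                f"transcript {self.id!r} contains non-ACGT characters"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CandidateProbe:
    """A 36-nt antisense candidate before extension/splitting.

    Coordinates are 0-based half-open on the transcript sense strand;
    dist_to_polyA counts from the window's 3' edge to the transcript end.
    """

    transcript_id: str
    start: int
    end: int
    antisense_seq: str
    tm: float
    gc: float
    penalty: float
    dist_to_polyA: int


@dataclass(frozen=True)
class ProbeSet:
    """A finalized acceptor/donor oligo pair for one target window."""

    set_id: str
    transcript_id: str
    target_start: int
    target_end: int
    acceptor_gene_seq: str
    donor_gene_seq: str
    acceptor_full_oligo: str  # AD1 + acceptor half (uppercase DNA alphabet)
    donor_full_oligo: str  # donor half + RCAD2
    donor_5prime_phosphate: bool
    tm: float
    gc: float
    penalty: float
    rank: int
    # 3'-terminal positions of the acceptor oligo synthesized as RNA
    ribo_positions: tuple[int, ...] = (-2, -1)

    @property
    def acceptor_oligo_annotated(self) -> str:
        """Acceptor oligo with ribonucleotide positions in lowercase."""
        n = len(self.acceptor_full_oligo)
        marks = {p % n for p in self.ribo_positions}
        return "".join(
            b.lower() if i in marks else b
            for i, b in enumerate(self.acceptor_full_oligo)
        )


@dataclass(frozen=True)
class DesignConfig:
    """Tunables of the designer; defaults follow the assay's published
    operating point."""

    window: int = 1000  # 3'-terminal search window, nt
    candidate_len: int = 36
    extension: int = 4  # toward the poly(A) tail
    max_candidates: int = 20
    tm_opt: float = 68.0
    tm_min: float = 60.0
    tm_max: float = 85.0
    gc_opt: float = 50.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    tm_penalty_weight: float = 1.0
    gc_penalty_weight: float = 0.5
    # QC thresholds applied to adaptor-appended full oligos (strict <)
    end_stability: float = 4.57
    hairpin_th: float = 56.98
    self_any_th: float = 30.0
    self_end_th: float = 8.9
    tm_ceiling: float = 78.0
    offtarget_tm_margin: float = 10.0
    offtarget_seed_len: int = 8
    min_set_spacing: int = 10
    sets_per_transcript: int = 2


def _penalty(tm: float, gc: float, cfg: DesignConfig) -> float:
    return cfg.tm_penalty_weight * abs(tm - cfg.tm_opt) + cfg.gc_penalty_weight * abs(
        gc - cfg.gc_opt
    )


def generate_candidates(
    t: Transcript,
    cfg: DesignConfig = DesignConfig(),
    params: ThermoParams = DEFAULT_PARAMS,
) -> list[CandidateProbe]:
    """All QC-window candidates in the 3'-terminal search window.

    Every returned candidate is a 36-nt antisense oligo whose Tm and GC
    fall inside the configured bounds and whose window leaves room for
    the downstream 4-nt extension toward the poly(A) end.  At most
    max_candidates are kept, preferring low penalty then proximity to
    the poly(A) tail.
    """
    n = len(t)
    if n < cfg.candidate_len + cfg.extension:
        raise DesignInfeasibleError(
            f"transcript {t.id} length {n} < "
            f"{cfg.candidate_len + cfg.extension} nt minimum"
        )
    window_start = max(0, n - cfg.window)
    out = []
    for start in range(window_start, n - cfg.candidate_len - cfg.extension + 1):
        end = start + cfg.candidate_len
        sense = t.sequence[start:end]
        anti = reverse_complement(sense)
        tm = duplex_tm(anti, params)
        if not (cfg.tm_min <= tm <= cfg.tm_max):
            continue
        gc = gc_percent(anti)
        if not (cfg.gc_min <= gc <= cfg.gc_max):
            continue
        out.append(
            CandidateProbe(
                transcript_id=t.id,
                start=start,
                end=end,
                antisense_seq=anti,
                tm=tm,
                gc=gc,
                penalty=_penalty(tm, gc, cfg),
                dist_to_polyA=n - end,
            )
        )
    out.sort(key=lambda c: (c.penalty, c.dist_to_polyA, c.start))
    return out[: cfg.max_candidates]


def extend_and_split(
    c: CandidateProbe, t: Transcript, cfg: DesignConfig = DesignConfig()
) -> tuple[str, str, tuple[int, int]]:
    """Extend the candidate toward the poly(A) tail and split in half.

    Returns (acceptor_gene_seq, donor_gene_seq, (footprint_start,
    footprint_end)).  The extension is in the probe's 5' direction,
    i.e. the transcript's 3' direction; the antisense 40-mer therefore
    starts at the poly(A)-proximal edge.  The acceptor is its 5' half
    (3'-OH at the midpoint junction), the donor the 3' half.
    """
    fp_start, fp_end = c.start, c.end + cfg.extension
    if fp_end > len(t):
        raise DesignInfeasibleError(
            f"extension of candidate at {c.start}:{c.end} runs off the 3' end "
            f"of transcript {t.id}"
        )
    anti = reverse_complement(t.sequence[fp_start:fp_end])
    half = len(anti) // 2
    return anti[:half], anti[half:], (fp_start, fp_end)


def qc_filter(
    full_oligo: str,
    cfg: DesignConfig = DesignConfig(),
    params: ThermoParams = DEFAULT_PARAMS,
) -> tuple[bool, ThermoReport]:
    """Apply the five structural thresholds to an adaptor-appended oligo.

    Passing requires all strict inequalities: end_stability_dg <
    cfg.end_stability, hairpin_tm < cfg.hairpin_th, self_any_tm <
    cfg.self_any_th, self_end_tm < cfg.self_end_th, tm < cfg.tm_ceiling.
    """
    rep = structure_report(full_oligo, params)
    ok = (
        rep.end_stability_dg < cfg.end_stability
        and rep.hairpin_tm < cfg.hairpin_th
        and rep.self_any_tm < cfg.self_any_th
        and rep.self_end_tm < cfg.self_end_th
        and rep.tm < cfg.tm_ceiling
    )
    return ok, rep


class BackgroundIndex:
    """Seeded exact-match index over a background transcriptome.

    k-mers of every background sequence are indexed; a query oligo is
    screened by looking up its k-mer seeds and extending each hit to the
    maximal exact run.  Both strands are covered by also scanning the
    query's reverse complement against the stored (sense) sequences.
    """

    def __init__(self, transcripts: list[Transcript], seed_len: int = 8):
        self.seed_len = seed_len
        self.seqs = {t.id: t.sequence for t in transcripts}
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for t in transcripts:
            s = t.sequence
            for i in range(len(s) - seed_len + 1):
                self.index[s[i : i + seed_len]].append((t.id, i))

    def _scan_oriented(self, query: str, exclude: set[str]) -> tuple[int, str]:
        k = self.seed_len
        best_len, best_run = 0, ""
        seen: set[tuple[str, int, int]] = set()
        for qi in range(len(query) - k + 1):
            for tid, ti in self.index.get(query[qi : qi + k], ()):
                if tid in exclude:
                    continue
                s = self.seqs[tid]
                a, b = qi, ti
                while a > 0 and b > 0 and query[a - 1] == s[b - 1]:
                    a -= 1
                    b -= 1
                c, d = qi + k, ti + k
                while c < len(query) and d < len(s) and query[c] == s[d]:
                    c += 1
                    d += 1
                key = (tid, b, d)
                if key in seen:
                    continue
                seen.add(key)
                if c - a > best_len:
                    best_len, best_run = c - a, query[a:c]
        return best_len, best_run

    def best_offtarget_tm(
        self,
        oligo: str,
        exclude: set[str],
        params: ThermoParams = DEFAULT_PARAMS,
    ) -> float:
        """Max duplex Tm of any maximal exact run shared with the
        background (either strand); -inf-like floor when no seed hits."""
        best = -273.15
        for q in (oligo, reverse_complement(oligo)):
            length, run = self._scan_oriented(q, exclude)
            if length >= 2:
                best = max(best, duplex_tm(run, params))
        return best


def offtarget_filter(
    acceptor_gene_seq: str,
    donor_gene_seq: str,
    target: Transcript,
    background: BackgroundIndex | None,
    cfg: DesignConfig = DesignConfig(),
    params: ThermoParams = DEFAULT_PARAMS,
) -> tuple[bool, float]:
    """Keep/drop decision for one probe set against the background.

    Each 20-nt half is screened independently; the set is dropped when
    either half has an off-target duplex Tm within cfg.offtarget_tm_margin
    of that half's on-target Tm.  Returns (keep, worst off-target Tm).
    """
    if background is None:
        return True, float("-inf")
    worst = float("-inf")
    keep = True
    for half in (acceptor_gene_seq, donor_gene_seq):
        on_tm = duplex_tm(half, params)
        off_tm = background.best_offtarget_tm(half, {target.id}, params)
        worst = max(worst, off_tm)
        if off_tm >= on_tm - cfg.offtarget_tm_margin:
            keep = False
    return keep, worst


def rank_and_select(
    candidates: list[CandidateProbe],
    t: Transcript,
    cfg: DesignConfig = DesignConfig(),
) -> list[CandidateProbe]:
    """Rank-sum selection of up to sets_per_transcript candidates.

    score = rank(dist_to_polyA ascending) + rank(penalty ascending);
    ties broken by smaller dist_to_polyA then window coordinates.
    Selection is greedy subject to every selected pair of (extended)
    footprints being separated by >= min_set_spacing nt.
    """
    if not candidates:
        return []
    if len({c.transcript_id for c in candidates}) != 1:
        raise ValueError("rank_and_select expects candidates from one transcript")
    dist_rank = rankdata([c.dist_to_polyA for c in candidates], method="average")
    pen_rank = rankdata([c.penalty for c in candidates], method="average")
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            dist_rank[i] + pen_rank[i],
            candidates[i].dist_to_polyA,
            candidates[i].start,
            candidates[i].end,
        ),
    )
    selected: list[CandidateProbe] = []
    footprints: list[tuple[int, int]] = []
    for i in order:
        c = candidates[i]
        fp = (c.start, c.end + cfg.extension)
        gap_ok = all(
            max(fp[0], other[0]) - min(fp[1], other[1]) >= cfg.min_set_spacing
            for other in footprints
        )
        if gap_ok:
            selected.append(c)
            footprints.append(fp)
            if len(selected) == cfg.sets_per_transcript:
                break
    return selected


def finalize_probes(
    selected: list[CandidateProbe],
    t: Transcript,
    cfg: DesignConfig = DesignConfig(),
    anatomy: ReadAnatomy = DEFAULT_ANATOMY,
) -> list[ProbeSet]:
    """Build final ProbeSets: append adaptors, annotate the acceptor's
    two 3'-terminal ribonucleotides, flag the donor 5'-phosphate."""
    out: list[ProbeSet] = []
    seen_ids: set[str] = set()
    for rank, c in enumerate(selected, start=1):
        acc, don, (fp_start, fp_end) = extend_and_split(c, t, cfg)
        set_id = f"{t.id}_set{rank}"
        if set_id in seen_ids:
            raise ValueError(f"duplicate probe set id {set_id}")
        seen_ids.add(set_id)
        out.append(
            ProbeSet(
                set_id=set_id,
                transcript_id=t.id,
                target_start=fp_start,
                target_end=fp_end,
                acceptor_gene_seq=acc,
                donor_gene_seq=don,
                acceptor_full_oligo=anatomy.ad1 + acc,
                donor_full_oligo=don + anatomy.rcad2,
                donor_5prime_phosphate=True,
                tm=c.tm,
                gc=c.gc,
                penalty=c.penalty,
                rank=rank,
            )
        )
    return out


def design_probes(
    transcripts: list[Transcript],
    background: list[Transcript] | None = None,
    cfg: DesignConfig = DesignConfig(),
    params: ThermoParams = DEFAULT_PARAMS,
    anatomy: ReadAnatomy = DEFAULT_ANATOMY,
) -> tuple[list[ProbeSet], dict[str, dict[str, int]]]:
    """Full design pipeline over a target list.

    background defaults to the target list itself (each transcript is
    screened against all the others).  Returns the designed ProbeSets
    and per-transcript funnel counts (candidates, qc_pass,
    offtarget_pass, selected).
    """
    if background is None:
        background = transcripts
    bg_index = (
        BackgroundIndex(background, cfg.offtarget_seed_len) if background else None
    )
    probesets: list[ProbeSet] = []
    stats: dict[str, dict[str, int]] = {}
    for t in transcripts:
        cands = generate_candidates(t, cfg, params)
        survivors = []
        n_qc = 0
        for c in cands:
            acc, don, _ = extend_and_split(c, t, cfg)
            ok_a, _ = qc_filter(anatomy.ad1 + acc, cfg, params)
            ok_d, _ = qc_filter(don + anatomy.rcad2, cfg, params)
            if not (ok_a and ok_d):
                continue
            n_qc += 1
            keep, _ = offtarget_filter(acc, don, t, bg_index, cfg, params)
            if keep:
                survivors.append(c)
        selected = rank_and_select(survivors, t, cfg)
        probesets.extend(finalize_probes(selected, t, cfg, anatomy))
        stats[t.id] = {
            "candidates": len(cands),
            "qc_pass": n_qc,
            "offtarget_pass": len(survivors),
            "selected": len(selected),
        }
    return probesets, stats
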