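"""Probe designer: candidate windows, extension/splitting geometry,
QC thresholds, off-target screening, rank-sum selection and the final
oligo layout."""

import dataclasses

import pytest

from raslkit.anatomy import DEFAULT_ANATOMY
from raslkit.design import (
    BackgroundIndex,
    CandidateProbe,
    DesignConfig,
    DesignInfeasibleError,
    Transcript,
    design_probes,
    extend_and_split,
    finalize_probes,
    generate_candidates,
    offtarget_filter,
    qc_filter,
    rank_and_select,
)
from raslkit.pipeline import random_transcriptome
from raslkit.thermo import reverse_complement

CFG = DesignConfig()


@pytest.fixture(scope="module")
def transcript():
    return random_transcriptome(1, 1500, seed=1)[0]


@pytest.fixture(scope="module")
def candidates(transcript):
    return generate_candidates(transcript, CFG)


def test_candidates_are_36mers_within_window(transcript, candidates):
    assert candidates, "expected candidates on a random 1.5-kb transcript"
    assert len(candidates) <= CFG.max_candidates
    n = len(transcript)
    for c in candidates:
        assert c.end - c.start == 36
        assert len(c.antisense_seq) == 36
        assert c.start >= n - CFG.window
        assert c.end + CFG.extension <= n
        assert c.antisense_seq == reverse_complement(
            transcript.sequence[c.start : c.end]
        )
        assert CFG.tm_min <= c.tm <= CFG.tm_max
        assert CFG.gc_min <= c.gc <= CFG.gc_max
        assert c.dist_to_polyA == n - c.end


def test_short_transcript_is_infeasible():
    with pytest.raises(DesignInfeasibleError):
        generate_candidates(Transcript("tiny", "ACGTACGTACGTACGTACGTACGTACGTAC"))


def test_extend_and_split_partition(transcript, candidates):
    c = candidates[0]
    acc, don, (s, e) = extend_and_split(c, transcript, CFG)
    assert e - s == 40
    assert len(acc) == len(don) == 20
    assert acc + don == reverse_complement(transcript.sequence[s:e])
    # extension grows toward the poly(A)-proximal (3') end
    assert (s, e) == (c.start, c.end + 4)


def test_extension_cannot_run_off_the_3prime_end():
    t = Transcript("short", "ACGT" * 10)  # 40 nt: no room for extension
    c = CandidateProbe(
        transcript_id="short",
        start=4,
        end=40,
        antisense_seq=reverse_complement(t.sequence[4:40]),
        tm=65.0,
        gc=50.0,
        penalty=0.0,
        dist_to_polyA=0,
    )
    with pytest.raises(DesignInfeasibleError):
        extend_and_split(c, t, CFG)


def test_qc_filter_tm_ceiling():
    hot = "GC" * 19  # Tm far above 78 C
    ok, rep = qc_filter(hot)
    assert rep.tm > CFG.tm_ceiling
    assert not ok


def test_qc_filter_hairpin_rejection(transcript, candidates):
    # find a passing oligo, then append a strong inverted repeat
    passing = None
    for c in candidates:
        acc, don, _ = extend_and_split(c, transcript, CFG)
        oligo = DEFAULT_ANATOMY.ad1 + acc
        if qc_filter(oligo)[0]:
            passing = oligo
            break
    assert passing is not None
    stem = "GCCGGAAGCCGCGGCA"  # GC-rich 16-bp stem, duplex Tm ~61 C
    hairpinned = passing + stem + "AAAA" + reverse_complement(stem)
    ok, rep = qc_filter(hairpinned)
    assert rep.hairpin_tm > CFG.hairpin_th
    assert not ok


def test_qc_pass_iff_all_metrics_below_thresholds(candidates, transcript):
    for c in candidates[:10]:
        acc, _, _ = extend_and_split(c, transcript, CFG)
        oligo = DEFAULT_ANATOMY.ad1 + acc
        ok, rep = qc_filter(oligo)
        expected = (
            rep.end_stability_dg < CFG.end_stability
            and rep.hairpin_tm < CFG.hairpin_th
            and rep.self_any_tm < CFG.self_any_th
            and rep.self_end_tm < CFG.self_end_th
            and rep.tm < CFG.tm_ceiling
        )
        assert ok == expected


def test_loosening_thresholds_is_monotone(transcript, candidates):
    loose = dataclasses.replace(
        CFG,
        end_stability=CFG.end_stability + 5,
        hairpin_th=CFG.hairpin_th + 50,
        self_any_th=CFG.self_any_th + 50,
        self_end_th=CFG.self_end_th + 50,
        tm_ceiling=CFG.tm_ceiling + 20,
    )
    def n_pass(cfg):
        n = 0
        for c in candidates:
            acc, don, _ = extend_and_split(c, transcript, CFG)
            if (
                qc_filter(DEFAULT_ANATOMY.ad1 + acc, cfg)[0]
                and qc_filter(don + DEFAULT_ANATOMY.rcad2, cfg)[0]
            ):
                n += 1
        return n

    assert 0 <= n_pass(CFG) <= n_pass(loose) <= len(candidates)


def test_offtarget_exact_match_dropped(transcript, candidates):
    c = candidates[0]
    acc, don, _ = extend_and_split(c, transcript, CFG)
    # background transcript carrying the probe's verbatim target site
    decoy_t = Transcript("bg", "ACGT" * 30 + reverse_complement(acc) + "TGCA" * 30)
    bg = BackgroundIndex([decoy_t])
    keep, off_tm = offtarget_filter(acc, don, transcript, bg, CFG)
    assert not keep


def test_offtarget_unrelated_background_kept(transcript, candidates):
    c = candidates[0]
    acc, don, _ = extend_and_split(c, transcript, CFG)
    bg = BackgroundIndex([Transcript("bg", "ACGTAGCTAG" * 50)])
    keep, _ = offtarget_filter(acc, don, transcript, bg, CFG)
    assert keep


def test_offtarget_empty_background_keeps():
    keep, _ = offtarget_filter("A" * 20, "C" * 20, Transcript("t", "ACGT" * 20), None)
    assert keep


def test_partial_offtarget_match_below_margin_kept(transcript, candidates):
    c = candidates[0]
    acc, don, _ = extend_and_split(c, transcript, CFG)
    # only a 10-nt fragment of the target site occurs in the background
    frag = reverse_complement(acc)[:10]
    bg = BackgroundIndex([Transcript("bg", "TTCCGATAGC" * 20 + frag)])
    keep, off_tm = offtarget_filter(acc, don, transcript, bg, CFG)
    from raslkit.thermo import duplex_tm

    assert off_tm < duplex_tm(acc) - CFG.offtarget_tm_margin
    assert keep


def _mk_candidate(start, penalty, dist, n=1500):
    return CandidateProbe("t", start, start + 36, "A" * 36, 68.0, 50.0, penalty, dist)


def test_rank_prefers_polyA_proximity_on_penalty_ties(transcript):
    far = _mk_candidate(1000, penalty=1.0, dist=464)
    near = _mk_candidate(1400, penalty=1.0, dist=64)
    sel = rank_and_select([far, near], transcript)
    assert sel[0] is near


def test_selection_enforces_footprint_spacing(transcript):
    best = _mk_candidate(1400, penalty=0.0, dist=64)
    overlapping = _mk_candidate(1405, penalty=2.0, dist=59)
    distant = _mk_candidate(1300, penalty=2.0, dist=164)
    sel = rank_and_select([best, overlapping, distant], transcript)
    assert best in sel and distant in sel and overlapping not in sel


def test_single_survivor_yields_one_set(transcript):
    sel = rank_and_select([_mk_candidate(1400, 0.0, 64)], transcript)
    assert len(sel) == 1


def test_finalized_oligo_layout(transcript, candidates):
    sel = rank_and_select(candidates, transcript, CFG)
    sets = finalize_probes(sel, transcript, CFG)
    assert 1 <= len(sets) <= CFG.sets_per_transcript
    for p in sets:
        assert len(p.acceptor_full_oligo) == 17 + 20 == 37
        assert p.acceptor_full_oligo == DEFAULT_ANATOMY.ad1 + p.acceptor_gene_seq
        assert p.donor_full_oligo == p.donor_gene_seq + DEFAULT_ANATOMY.rcad2
        assert p.donor_5prime_phosphate
        annotated = p.acceptor_oligo_annotated
        lowers = [i for i, b in enumerate(annotated) if b.islower()]
        assert lowers == [35, 36]  # exactly two ribonucleotides at the 3' end
        assert p.acceptor_gene_seq + p.donor_gene_seq == reverse_complement(
            transcript.sequence[p.target_start : p.target_end]
        )


def test_design_50_transcript_panel(designed50, transcriptome50):
    probesets, stats = designed50
    seqs = {t.id: t.sequence for t in transcriptome50}
    by_tid = {}
    for p in probesets:
        by_tid.setdefault(p.transcript_id, []).append(p)
        # every footprint is the exact reverse complement of its window
        assert p.acceptor_gene_seq + p.donor_gene_seq == reverse_complement(
            seqs[p.transcript_id][p.target_start : p.target_end]
        )
    for tid, group in by_tid.items():
        assert len(group) <= 2
        if len(group) == 2:
            a, b = group
            gap = max(a.target_start, b.target_start) - min(
                a.target_end, b.target_end
            )
            assert gap >= CFG.min_set_spacing
    for s in stats.values():
        assert 0 <= s["qc_pass"] <= s["candidates"]


def test_design_is_deterministic():
    ts = random_transcriptome(3, 900, seed=5)
    a, _ = design_probes(ts)
    b, _ = design_probes(ts)
    assert a == b
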