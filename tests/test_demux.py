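"""Deconvolution: plate routing, collapsing, anatomy parsing, seeded
mapping vs an exhaustive Smith-Waterman oracle, matrices, conservation."""

import pandas as pd
import pytest

from raslkit.align import MapperConfig, ProbeMapper
from raslkit.anatomy import DEFAULT_ANATOMY
from raslkit.barcodes import BarcodeSet
from raslkit.demux import (
    MappedRead,
    build_matrices,
    collapse_unique,
    demultiplex_plates,
    parse_anatomy,
    run_demux,
)
from raslkit.pipeline import random_transcriptome
from raslkit.simulate import assemble_read, simulate_run


# --------------------------------------------------------------------------
# independent exhaustive Smith-Waterman oracle (no seeding, all pairs)
# --------------------------------------------------------------------------


def sw_score(q: str, r: str, match=1, mismatch=-3, open_=5, ext=2) -> int:
    nq, nr = len(q), len(r)
    NEG = -(10**9)
    best = 0
    M = [[0] * (nr + 1) for _ in range(nq + 1)]
    X = [[NEG] * (nr + 1) for _ in range(nq + 1)]
    Y = [[NEG] * (nr + 1) for _ in range(nq + 1)]
    for i in range(1, nq + 1):
        for j in range(1, nr + 1):
            s = match if q[i - 1] == r[j - 1] else mismatch
            M[i][j] = max(
                0, max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0) + s
            )
            X[i][j] = max(M[i - 1][j] - open_ - ext, X[i - 1][j] - ext)
            Y[i][j] = max(M[i][j - 1] - open_ - ext, Y[i][j - 1] - ext)
            best = max(best, M[i][j])
    return best


def oracle_best_pair(query, acceptors, donors):
    best = (0, None)
    for i, a in enumerate(acceptors):
        for j, d in enumerate(donors):
            s = sw_score(query, a + d)
            if s > best[0]:
                best = (s, (i, j))
    return best


@pytest.fixture(scope="module")
def small_panel():
    ts = random_transcriptome(5, 600, seed=21)
    from raslkit.design import design_probes

    ps, _ = design_probes(ts)
    panel = [p for p in ps if p.rank == 1]
    assert len(panel) == 5
    return panel


def test_mapper_matches_exhaustive_oracle(small_panel):
    import random

    accs = [p.acceptor_gene_seq for p in small_panel]
    dons = [p.donor_gene_seq for p in small_panel]
    mapper = ProbeMapper(accs, dons, MapperConfig(min_alignment_length=0, max_query_start=100))
    rng = random.Random(5)
    for trial in range(40):
        i = rng.randrange(5)
        j = rng.randrange(5)
        q = list(accs[i] + dons[j])
        for _ in range(rng.randint(0, 3)):  # up to 3 substitutions
            p = rng.randrange(len(q))
            q[p] = rng.choice([b for b in "ACGT" if b != q[p]])
        query = "".join(q)
        score, pair = oracle_best_pair(query, accs, dons)
        hit = mapper.map(query)
        assert hit is not None
        assert hit.score == score
        assert (hit.acceptor_idx, hit.donor_idx) == pair


def test_mapper_filters(small_panel):
    accs = [p.acceptor_gene_seq for p in small_panel]
    dons = [p.donor_gene_seq for p in small_panel]
    mapper = ProbeMapper(accs, dons)
    full = accs[0] + dons[0]
    hit = mapper.map(full)
    assert hit is not None and hit.length == 40 and hit.query_start == 0
    # chimeric region maps off-target
    chim = mapper.map(accs[1] + dons[2])
    assert (chim.acceptor_idx, chim.donor_idx) == (1, 2)
    # a 25-nt fragment fails the alignment-length filter
    assert mapper.map(full[:25]) is None
    # a query whose alignment starts deep inside fails the start filter
    assert mapper.map("TTTTTTTTTT" + full) is None


def test_collapse_unique_preserves_counts():
    collapsed = {c.sequence: c.count for c in collapse_unique(["X", "X", "Y"])}
    assert collapsed == {"X": 2, "Y": 1}
    distinct = collapse_unique(["A", "B", "C"])
    assert sum(c.count for c in distinct) == 3 and len(distinct) == 3


def test_parse_anatomy_exact_and_rescue():
    read = assemble_read("ACGTACGT", "A" * 20, "C" * 20)
    well, region = parse_anatomy(read)
    assert well == "ACGTACGT" and region == "A" * 20 + "C" * 20

    # one substitution inside AD1 -> rescued at the expected offset
    pos = 8 + 5
    errread = read[:pos] + ("A" if read[pos] != "A" else "G") + read[pos + 1 :]
    well2, region2 = parse_anatomy(errread)
    assert (well2, region2) == (well, region)

    # two substitutions in AD1 -> unparsed under the exact+1-mismatch policy
    p2 = 8 + 9
    err2 = errread[:p2] + ("A" if errread[p2] != "A" else "G") + errread[p2 + 1 :]
    assert parse_anatomy(err2) is None


def test_parse_anatomy_tail_fallback():
    # tail destroyed -> probe region extends to the read end
    read = assemble_read("ACGTACGT", "A" * 20, "C" * 20)
    no_tail = read[:65] + "T" * 35
    well, region = parse_anatomy(no_tail)
    assert region.startswith("A" * 20 + "C" * 20)
    assert len(region) == 100 - 25  # remainder of the read


def test_demultiplex_plates_routes_and_conserves(plates2):
    a = DEFAULT_ANATOMY
    mk = lambda bc: (bc + a.pad_base * (a.index_read_len - len(bc)))
    good0 = mk(plates2[0])
    good1 = mk(plates2[1])
    one_err = ("A" if good1[0] != "A" else "C") + good1[1:]
    garbage = mk("TTTTTTT") if "TTTTTTT" not in plates2.barcodes else mk("GGGGGGG")
    reads = [(f"r{k}", "A" * 100) for k in range(4)]
    idx = [("r0", good0), ("r1", good1), ("r2", one_err), ("r3", garbage)]
    streams, unassigned = demultiplex_plates(reads, idx, plates2)
    routed = sum(len(v) for v in streams.values())
    assert routed + unassigned == 4
    assert len(streams[0]) == 1 and len(streams[1]) == 2


def test_pairing_length_mismatch_raises(plates2):
    with pytest.raises(ValueError, match="pairing"):
        demultiplex_plates([("r", "A" * 100)], [], plates2)


def test_build_matrices_sums_multiplicities():
    mapped = [
        MappedRead(0, 1, "g1", "g1", True, 40, 0, 40, 2),
        MappedRead(0, 1, "g1", "g1", True, 36, 0, 40, 1),
        MappedRead(0, 1, "g1", "g1", True, 36, 1, 39, 1),
        MappedRead(0, 1, "g1", "g2", False, 33, 0, 40, 5),
    ]
    on, off, meta = build_matrices(mapped, ["g1", "g2"])
    assert on.loc["g1", "0:1"] == 4
    assert on.loc["g2", "0:1"] == 0
    assert off.loc["g1|g2", "0:1"] == 5


def test_metadata_join_and_collision():
    mapped = [MappedRead(0, 0, "g1", "g1", True, 40, 0, 40, 1)]
    meta = pd.DataFrame({"plate": [0], "well": [0], "drug": ["dmso"]})
    _, _, joined = build_matrices(mapped, ["g1"], meta)
    assert joined.loc["0:0", "drug"] == "dmso"
    dup = pd.DataFrame({"plate": [0, 0], "well": [0, 0], "drug": ["a", "b"]})
    with pytest.raises(ValueError, match="join"):
        build_matrices(mapped, ["g1"], dup)


def test_zero_error_run_recovers_truth_exactly(sim_cfg_factory, panel6, wells8, plates2):
    cfg = sim_cfg_factory(total_reads=20000, off_target_rate=0.03)
    res = simulate_run(cfg, seed=6)
    out = run_demux(res.reads, res.index_reads, panel6, wells8, plates2)
    s = out.stats
    assert s.plate_unassigned == s.unparsed == s.well_unassigned == s.no_hit == 0
    assert s.mapped == s.total
    truth_on = res.truth[res.truth.on_target]
    assert s.mapped_on == len(truth_on)
    grouped = truth_on.groupby(["acceptor", "plate", "well"]).size()
    for (acc, p, w), n in grouped.items():
        assert out.on_target.loc[acc, f"{p}:{w}"] == n
    assert out.on_target.values.sum() == len(truth_on)
    # off-target matrix matches the chimera truth
    chim = res.truth[~res.truth.on_target]
    assert out.off_target.values.sum() == len(chim)
    assert s.compression > 10  # deep zero-error run collapses heavily


def test_off_target_matrix_empty_without_chimeras(sim_cfg_factory, panel6, wells8, plates2):
    cfg = sim_cfg_factory(total_reads=3000)
    res = simulate_run(cfg, seed=8)
    out = run_demux(res.reads, res.index_reads, panel6, wells8, plates2)
    assert out.off_target.empty or out.off_target.values.sum() == 0
    assert out.stats.mapped_off == 0
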