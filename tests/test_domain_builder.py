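"""Domain construction against brute-force oracles, plus structural invariants."""

import numpy as np
import pytest

from vdrdomains.domain_builder import (
    AnchorSet,
    anchors_from_interactions,
    build_domains,
    domains_to_table,
    size_summary,
)
from vdrdomains.io_formats import Interaction, Peak


def _peak(pid, chrom, summit, fe=1.0):
    return Peak(pid, chrom, summit - 5, summit + 6, summit, fe)


def _anchorset(**summits):
    return AnchorSet(summits={c: np.asarray(v, dtype=np.int64) for c, v in summits.items()})


# ---------------------------------------------------------------------------
# anchor merging
# ---------------------------------------------------------------------------


def test_overlapping_anchors_merge_to_midpoint_summit():
    ints = [Interaction("chr1", (100, 200), (150, 300))]
    aset = anchors_from_interactions(ints, merge_gap=0)
    assert list(aset.summits["chr1"]) == [200]
    assert aset.intervals["chr1"] == [(100, 300)]


def test_disjoint_anchors_keep_separate_summits():
    ints = [Interaction("chr1", (0, 10), (1000, 1010))]
    aset = anchors_from_interactions(ints)
    assert list(aset.summits["chr1"]) == [5, 1005]


def test_merge_gap_joins_nearby_anchors():
    ints = [Interaction("chr1", (0, 10), (15, 25))]
    assert list(anchors_from_interactions(ints, merge_gap=0).summits["chr1"]) == [5, 20]
    assert list(anchors_from_interactions(ints, merge_gap=5).summits["chr1"]) == [12]


def test_empty_input_gives_empty_anchorset():
    aset = anchors_from_interactions([])
    assert aset.n_anchors() == 0


def test_merge_matches_coverage_oracle():
    """Merged summits equal midpoints of covered-base runs (merge_gap=0)."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = rng.integers(1, 15)
        ivals = []
        for _ in range(n):
            s = int(rng.integers(0, 500))
            e = s + int(rng.integers(1, 60))
            ivals.append((s, e))
        ints = [
            Interaction("c", ivals[i], ivals[(i + 1) % len(ivals)])
            for i in range(len(ivals))
        ]
        got = list(anchors_from_interactions(ints, merge_gap=0).summits["c"])
        # oracle: paint covered bases, read off runs, take midpoints
        cov = np.zeros(600, dtype=bool)
        for s, e in ivals:
            cov[s:e] = True
        runs = []
        i = 0
        while i < cov.size:
            if cov[i]:
                j = i
                while j < cov.size and cov[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        assert got == sorted({(s + e) // 2 for s, e in runs})


# ---------------------------------------------------------------------------
# domain building
# ---------------------------------------------------------------------------


def test_no_anchors_gives_whole_chromosome_domain():
    doms, p2d = build_domains([_peak("p", "chr1", 500)], _anchorset(), {"chr1": 1000})
    (d,) = doms
    assert (d.left, d.right, d.size) == (0, 1000, 1000)
    assert d.left_is_chrom_end and d.right_is_chrom_end
    assert p2d == {"p": d.id}


def test_peaks_with_shared_flanks_share_one_domain():
    peaks = [_peak("a", "chr1", 300), _peak("b", "chr1", 700)]
    doms, p2d = build_domains(peaks, _anchorset(chr1=[100, 900]), {"chr1": 5000})
    (d,) = doms
    assert (d.left, d.right) == (100, 900) and d.size == 800
    assert d.member_peak_ids == ["a", "b"]
    assert not d.left_is_chrom_end and not d.right_is_chrom_end


def test_anchor_at_peak_summit_counts_as_left():
    doms, _ = build_domains(
        [_peak("p", "chr1", 500)], _anchorset(chr1=[500, 800]), {"chr1": 1000}
    )
    assert (doms[0].left, doms[0].right) == (500, 800)


def test_chromosome_missing_from_anchorset_gives_whole_chromosome():
    doms, _ = build_domains(
        [_peak("p", "chr9", 10)], _anchorset(chr1=[5]), {"chr9": 50}
    )
    assert (doms[0].left, doms[0].right) == (0, 50)


def test_duplicate_peak_ids_rejected():
    peaks = [_peak("p", "chr1", 100), _peak("p", "chr1", 200)]
    with pytest.raises(ValueError, match="duplicate"):
        build_domains(peaks, _anchorset(), {"chr1": 1000})


def _oracle_domains(peaks, summits, chrom_sizes, level=1):
    """Linear-scan nearest-anchor oracle (no sorting/bisection tricks)."""
    out = {}
    for p in peaks:
        anchors = sorted(summits.get(p.chrom, []))
        lefts = [a for a in anchors if a <= p.summit]
        rights = [a for a in anchors if a > p.summit]
        left = lefts[-level] if len(lefts) >= level else 0
        right = rights[level - 1] if len(rights) >= level else chrom_sizes[p.chrom]
        lflag = len(lefts) < level
        rflag = len(rights) < level
        out.setdefault((p.chrom, left, right, lflag, rflag), set()).add(p.id)
    return out


def _random_instance(rng, n_chrom=3, max_anchors=60, max_peaks=30, clen=100_000):
    sizes = {f"chr{i}": clen for i in range(1, n_chrom + 1)}
    summits = {}
    for c in sizes:
        k = int(rng.integers(0, max_anchors))
        summits[c] = np.unique(rng.integers(0, clen, size=k))
    peaks = []
    for i in range(int(rng.integers(1, max_peaks))):
        c = f"chr{int(rng.integers(1, n_chrom + 1))}"
        peaks.append(_peak(f"p{i}", c, int(rng.integers(10, clen - 10))))
    return peaks, summits, sizes


@pytest.mark.parametrize("level", [1, 2])
def test_random_instances_match_linear_scan_oracle(level):
    rng = np.random.default_rng(7 + level)
    for _ in range(100):
        peaks, summits, sizes = _random_instance(rng)
        aset = _anchorset(**{c: v for c, v in summits.items() if len(v)})
        doms, p2d = build_domains(peaks, aset, sizes, level=level)
        got = {
            (d.chrom, d.left, d.right, d.left_is_chrom_end, d.right_is_chrom_end): set(
                d.member_peak_ids
            )
            for d in doms
        }
        assert got == _oracle_domains(peaks, summits, sizes, level=level)
        assert sum(len(d.member_peak_ids) for d in doms) == len(peaks)
        assert set(p2d) == {p.id for p in peaks}


def test_level_expansion_never_shrinks_domains():
    rng = np.random.default_rng(11)
    peaks, summits, sizes = _random_instance(rng, max_anchors=80)
    aset = _anchorset(**{c: v for c, v in summits.items() if len(v)})
    prev = None
    for level in (1, 2, 3):
        doms, p2d = build_domains(peaks, aset, sizes, level=level)
        byid = {d.id: d for d in doms}
        cur = {p.id: byid[p2d[p.id]] for p in peaks}
        if prev is not None:
            for pid, d in cur.items():
                assert d.left <= prev[pid].left and d.right >= prev[pid].right
        prev = cur


def test_build_is_deterministic():
    rng = np.random.default_rng(3)
    peaks, summits, sizes = _random_instance(rng)
    aset = _anchorset(**{c: v for c, v in summits.items() if len(v)})
    t1 = domains_to_table(build_domains(peaks, aset, sizes)[0])
    t2 = domains_to_table(build_domains(peaks, aset, sizes)[0])
    assert t1.equals(t2)


# ---------------------------------------------------------------------------
# size summaries
# ---------------------------------------------------------------------------


def _domains_of_sizes(sizes):
    from vdrdomains.domain_builder import ChromatinDomain

    return [
        ChromatinDomain(f"D{i}", "chr1", 0, int(s), member_peak_ids=[f"p{i}"])
        for i, s in enumerate(sizes)
    ]


def test_quartile_means_rank_split():
    s = size_summary(_domains_of_sizes([40, 10, 30, 20]))
    assert s.quartile_means == (10.0, 20.0, 30.0, 40.0)
    s = size_summary(_domains_of_sizes([7] * 9))
    assert s.quartile_means == (7.0, 7.0, 7.0, 7.0)
    assert size_summary(_domains_of_sizes([1, 2, 3])).quartile_means is None


def test_quartile_remainder_spreads_to_earliest_groups():
    # 6 = 2+2+1+1 on the sorted list
    s = size_summary(_domains_of_sizes([1, 2, 3, 4, 5, 6]))
    assert s.quartile_means == (1.5, 3.5, 5.0, 6.0)


def test_histogram_matches_bin_assignment_oracle():
    rng = np.random.default_rng(5)
    sizes = np.concatenate(
        [
            rng.integers(1, 1_000, 40),  # underflow
            rng.integers(1_000, 21_000_000, 200),
            rng.integers(21_000_000, 40_000_000, 5),  # overflow -> top bin
        ]
    )
    s = size_summary(_domains_of_sizes(sizes))
    assert s.hist_counts.sum() == len(sizes)
    assert len(s.hist_counts) == 15 and len(s.hist_edges) == 15
    oracle = np.zeros(15, dtype=int)
    for x in sizes:
        if x < 1_000:
            oracle[0] += 1
            continue
        k = int(np.searchsorted(s.hist_edges, x, side="right")) - 1
        oracle[1 + min(k, 13)] += 1
    assert list(s.hist_counts) == list(oracle)
    assert np.isclose(s.hist_edges[0], 1e3) and np.isclose(s.hist_edges[-1], 21e6)
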