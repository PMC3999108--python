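"""Gene-to-domain assignment distances and the enrichment fold statistic."""

import math

import numpy as np
import pytest

from vdrdomains.domain_builder import ChromatinDomain
from vdrdomains.io_formats import GeneRecord
from vdrdomains.master_classifier import MasterCall
from vdrdomains.target_enrichment import (
    assign_genes,
    enrichment,
    enrichment_from_counts,
)


def _domain(did, chrom, left, right, peaks):
    return ChromatinDomain(did, chrom, left, right, member_peak_ids=list(peaks))


def _master(pid):
    return MasterCall(pid, True, True, True)


def _nonmaster(pid):
    return MasterCall(pid, False, False, False)


@pytest.fixture()
def simple_layout():
    domains = [
        _domain("D1", "chr1", 100, 900, ["a"]),
        _domain("D2", "chr1", 2000, 3000, ["b"]),
    ]
    calls = [_master("a"), _nonmaster("b")]
    p2d = {"a": "D1", "b": "D2"}
    return domains, calls, p2d


def test_tss_inside_domain_assigned_with_zero_distances(simple_layout):
    domains, calls, p2d = simple_layout
    genes = [GeneRecord("g", "chr1", 500, "+", True)]
    df = assign_genes(genes, domains, calls, p2d)
    row = df.iloc[0]
    assert row.domain_id == "D1" and row.in_domain and row.in_master_domain
    assert row.dist_to_domain == 0 and row.dist_to_master_domain == 0


def test_tss_outside_measures_distance_to_nearest_boundary(simple_layout):
    domains, calls, p2d = simple_layout
    df = assign_genes([GeneRecord("g", "chr1", 50, "+")], domains, calls, p2d)
    row = df.iloc[0]
    assert not row.in_domain and row.dist_to_domain == 50
    assert row.dist_to_master_domain == 50
    # between the two domains: nearest is D1's right end (base 899)
    df = assign_genes([GeneRecord("g", "chr1", 950, "+")], domains, calls, p2d)
    assert df.iloc[0].dist_to_domain == 51


def test_gene_on_chromosome_without_domains_has_missing_distances(simple_layout):
    domains, calls, p2d = simple_layout
    df = assign_genes([GeneRecord("g", "chr7", 100, "+")], domains, calls, p2d)
    assert math.isnan(df.iloc[0].dist_to_domain)
    assert math.isnan(df.iloc[0].dist_to_master_domain)
    assert not df.iloc[0].in_domain


def test_tss_slop_widens_containment(simple_layout):
    domains, calls, p2d = simple_layout
    genes = [GeneRecord("g", "chr1", 95, "+")]
    assert not assign_genes(genes, domains, calls, p2d).iloc[0].in_domain
    assert assign_genes(genes, domains, calls, p2d, tss_slop=10).iloc[0].in_domain


def test_distances_match_all_pairs_oracle():
    rng = np.random.default_rng(21)
    for _ in range(30):
        # random non-overlapping domains from sorted breakpoints
        bp = np.sort(rng.choice(np.arange(10_000), size=12, replace=False))
        domains, calls, p2d = [], [], {}
        for k in range(0, len(bp) - 1, 2):
            did = f"D{k}"
            pid = f"p{k}"
            domains.append(_domain(did, "c", int(bp[k]), int(bp[k + 1]), [pid]))
            calls.append(_master(pid) if rng.random() < 0.4 else _nonmaster(pid))
            p2d[pid] = did
        genes = [
            GeneRecord(f"g{i}", "c", int(rng.integers(0, 10_000)), "+", True)
            for i in range(40)
        ]
        df = assign_genes(genes, domains, calls, p2d).set_index("gene_id")
        master_doms = {
            p2d[c.peak_id] for c in calls if c.is_master
        }
        for g in genes:
            dists = []
            mdists = []
            for d in domains:
                if d.left <= g.tss < d.right:
                    dist = 0
                elif g.tss < d.left:
                    dist = d.left - g.tss
                else:
                    dist = g.tss - (d.right - 1)
                dists.append((dist, d.id))
                if d.id in master_doms:
                    mdists.append(dist)
            row = df.loc[g.gene_id]
            assert row.dist_to_domain == min(dists)[0]
            if mdists:
                assert row.dist_to_master_domain == min(mdists)
            else:
                assert math.isnan(row.dist_to_master_domain)
            inside = [did for dist, did in dists if dist == 0]
            assert row.in_domain == bool(inside)
            if inside:
                assert row.domain_id in inside


def test_distances_symmetric_under_coordinate_reflection():
    C = 10_000
    domains = [_domain("D1", "c", 1000, 2000, ["p"])]
    calls = [_master("p")]
    p2d = {"p": "D1"}
    refl_domains = [_domain("D1", "c", C - 2000, C - 1000, ["p"])]
    for tss in (0, 500, 1500, 2050, 9000):
        d1 = assign_genes([GeneRecord("g", "c", tss, "+")], domains, calls, p2d)
        d2 = assign_genes(
            [GeneRecord("g", "c", C - 1 - tss, "+")], refl_domains, calls, p2d
        )
        assert d1.iloc[0].dist_to_domain == d2.iloc[0].dist_to_domain


# ---------------------------------------------------------------------------
# enrichment fold
# ---------------------------------------------------------------------------


def test_worked_example_from_published_style_counts():
    """52 of 179 target-gene domains with a master vs 160 of 2,340 peaks
    gives an enrichment fold of ~4.25, i.e. 'more than 4-fold'."""
    rep = enrichment_from_counts(
        n_peaks=2340,
        n_master_peaks=160,
        n_target_domains=179,
        n_target_domains_with_master=52,
    )
    assert rep.master_domain_fraction == pytest.approx(52 / 179)
    assert rep.master_peak_fraction == pytest.approx(160 / 2340)
    assert rep.fold_likelihood == pytest.approx(4.2487, abs=1e-3)
    assert rep.fold_likelihood > 4.0


def test_saturated_case_gives_n_over_m():
    # every domain has a master and every target is in a domain
    domains = [_domain("D1", "c", 0, 100, ["a", "b"])]
    calls = [_master("a"), _nonmaster("b")]
    p2d = {"a": "D1", "b": "D1"}
    genes = [GeneRecord("g", "c", 50, "+", True)]
    rep = enrichment(assign_genes(genes, domains, calls, p2d), calls)
    assert rep.master_domain_fraction == 1.0
    assert rep.fold_likelihood == pytest.approx(len(calls) / 1)


def test_domain_with_several_targets_counts_once():
    domains = [_domain("D1", "c", 0, 100, ["a"])]
    calls = [_master("a")]
    genes = [GeneRecord(f"g{i}", "c", 10 * i + 5, "+", True) for i in range(3)]
    rep = enrichment(assign_genes(genes, domains, calls, {"a": "D1"}), calls)
    assert rep.n_targets == 3 and rep.n_targets_in_domain == 3
    assert rep.n_target_domains == 1 and rep.n_target_domains_with_master == 1


def test_missing_fold_when_denominators_zero():
    rep = enrichment_from_counts(0, 0, 0, 0)
    assert rep.fold_likelihood is None
    rep = enrichment_from_counts(10, 0, 0, 0)
    assert rep.master_peak_fraction == 0 and rep.fold_likelihood is None


def test_uniform_target_placement_over_domains_recovers_neutral_fold():
    """Targets thrown uniformly over domains drive the numerator fraction to
    the master-domain fraction, so L -> (masters/domains)/(M/N)."""
    rng = np.random.default_rng(31)
    n_dom, n_master_dom, n_peaks = 50, 10, 400
    domains, calls, p2d = [], [], {}
    for i in range(n_dom):
        did, pid = f"D{i}", f"p{i}"
        domains.append(_domain(did, "c", 1000 * i, 1000 * i + 500, [pid]))
        calls.append(_master(pid) if i < n_master_dom else _nonmaster(pid))
        p2d[pid] = did
    # pad peak count so M/N is small, as in real data
    for j in range(n_dom, n_peaks):
        pid = f"q{j}"
        calls.append(_nonmaster(pid))
        p2d[pid] = f"D{j % n_dom}"
    folds = []
    for _ in range(200):
        genes = [
            GeneRecord(f"g{k}", "c", 1000 * int(rng.integers(0, n_dom)) + 250, "+", True)
            for k in range(30)
        ]
        rep = enrichment(assign_genes(genes, domains, calls, p2d), calls)
        folds.append(rep.fold_likelihood)
    expected = (n_master_dom / n_dom) / (n_master_dom / n_peaks)
    got = np.mean(folds)
    assert got == pytest.approx(expected, rel=0.1)
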