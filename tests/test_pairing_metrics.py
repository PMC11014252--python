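import numpy as np
import pytest

from circtdmd import (
    CircRNARecord,
    InteractionRecord,
    MiRNARecord,
    ParameterError,
    assign_quartiles,
    circ_load_index,
    effective_sites_per_circ,
    filter_interactions,
    join_sites_to_circrnas,
    pairing_by_region,
    summarize_mirna_pairing,
)
from circtdmd.pairing_metrics import MiRNAPairingSummary, assign_quartile_labels


def mk_circ(cid="c1", chrom="chr1", start=50, end=500, strand="+",
            pre=10.0, post=10.0, region="CDS"):
    return CircRNARecord(
        id=cid, chrom=chrom, start=start, end=end, strand=strand,
        junction_reads_pre=pre, junction_reads_post=post,
        region_of_origin=region,
    )


def mk_interaction(mid="m1", tid="c1", chrom="chr1", start=100, end=120,
                   strand="+", clip=1, programs=2):
    return InteractionRecord(
        mirna_id=mid, target_id=tid, target_class="circRNA", chrom=chrom,
        site_start=start, site_end=end, strand=strand,
        clip_experiments=clip, supporting_programs=programs,
    )


def mk_mirna(mid="m1", pre=5.0, post=15.0):
    seq = "UGAGGUAGUAGGUUGUAUAGUU"
    return MiRNARecord(id=mid, sequence=seq, abundance_pre=pre, abundance_post=post)


# ---------------------------------------------------------------------------
# Interaction filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "clip,programs,kept",
    [(1, 2, True), (0, 5, False), (3, 1, False), (2, 2, True)],
)
def test_filter_interactions_applies_both_evidence_thresholds(clip, programs, kept):
    recs = [mk_interaction(clip=clip, programs=programs)]
    assert (len(filter_interactions(recs, 1, 2)) == 1) is kept


def test_zero_thresholds_are_identity():
    recs = [mk_interaction(clip=0, programs=0), mk_interaction(clip=5, programs=5)]
    assert filter_interactions(recs, 0, 0) == recs


# ---------------------------------------------------------------------------
# Genomic join (full containment, same chrom and strand)
# ---------------------------------------------------------------------------

def test_join_requires_containment_chrom_and_strand():
    circs = [mk_circ()]
    inside = mk_interaction(start=100, end=120)
    wrong_chrom = mk_interaction(chrom="chr2")
    wrong_strand = mk_interaction(strand="-")
    spans_boundary = mk_interaction(start=40, end=60)  # crosses the 5' edge
    counts = join_sites_to_circrnas(
        [inside, wrong_chrom, wrong_strand, spans_boundary], circs
    )
    assert counts == {("m1", "c1"): 1}


def test_join_matches_interval_bruteforce_on_random_sets():
    rng = np.random.default_rng(17)
    circs = [
        mk_circ(cid=f"c{i}", chrom=f"chr{rng.integers(1, 3)}",
                start=int(s), end=int(s + rng.integers(100, 400)),
                strand="+-"[rng.integers(0, 2)])
        for i, s in enumerate(rng.integers(0, 2000, size=12))
    ]
    interactions = []
    for j in range(200):
        s = int(rng.integers(0, 2400))
        interactions.append(
            mk_interaction(mid=f"m{rng.integers(0, 5)}", chrom=f"chr{rng.integers(1, 3)}",
                           start=s, end=s + int(rng.integers(5, 40)),
                           strand="+-"[rng.integers(0, 2)])
        )
    counts = join_sites_to_circrnas(interactions, circs)
    brute = {}
    for rec in interactions:
        for c in circs:
            if (rec.chrom == c.chrom and rec.strand == c.strand
                    and c.start <= rec.site_start and rec.site_end <= c.end):
                brute[(rec.mirna_id, c.id)] = brute.get((rec.mirna_id, c.id), 0) + 1
    assert counts == brute


def test_one_site_can_match_overlapping_circrnas():
    circs = [mk_circ("c1", start=0, end=300), mk_circ("c2", start=50, end=400)]
    counts = join_sites_to_circrnas([mk_interaction(start=100, end=120)], circs)
    assert counts == {("m1", "c1"): 1, ("m1", "c2"): 1}


# ---------------------------------------------------------------------------
# Effective sites / pairing coefficient
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "count,pre,post,expected",
    [(4, 10, 20, 60.0), (0, 7, 3, 0.0), (3, 0, 0, 0.0)],
)
def test_effective_sites_weight_by_mean_junction_reads(count, pre, post, expected):
    assert effective_sites_per_circ(count, mk_circ(pre=pre, post=post)) == expected


def test_hand_computed_toy_summary():
    """2 sites on circ X (reads 10,10) + 1 on circ Y (reads 4,0), abundance
    (5,15): effective = 2*10 + 1*2 = 22 and coefficient = 22/10 = 2.2."""
    circs = [mk_circ("X", pre=10, post=10), mk_circ("Y", pre=4, post=0)]
    counts = {("m1", "X"): 2, ("m1", "Y"): 1}
    (s,) = summarize_mirna_pairing(counts, circs, [mk_mirna("m1", 5, 15)])
    assert s.absolute_sites == 3
    assert s.effective_sites == 22.0
    assert s.mean_abundance == 10.0
    assert s.pairing_coefficient == 2.2


def test_siteless_mirna_has_zero_everything():
    (s,) = summarize_mirna_pairing({}, [mk_circ()], [mk_mirna()])
    assert (s.absolute_sites, s.effective_sites, s.pairing_coefficient) == (0, 0.0, 0.0)


def test_zero_abundance_mirna_excluded():
    out = summarize_mirna_pairing({}, [mk_circ()], [mk_mirna(pre=0, post=0)])
    assert out == []


def test_aggregation_order_conservation(small_dataset):
    """Summing per miRNA equals summing over the count table directly."""
    from circtdmd.pairing_metrics import filter_interactions, join_sites_to_circrnas

    ds = small_dataset
    counts = join_sites_to_circrnas(
        filter_interactions(ds.interactions, 1, 2), ds.circrnas
    )
    summaries = summarize_mirna_pairing(counts, ds.circrnas, ds.mirnas)
    total_by_mirna = sum(s.effective_sites for s in summaries)
    reads = {c.id: c.mean_junction_reads for c in ds.circrnas}
    total_direct = sum(n * reads[cid] for (_, cid), n in counts.items())
    assert total_by_mirna == pytest.approx(total_direct, abs=1e-9)


def test_scale_equivariance_of_reads_and_abundance():
    circs = [mk_circ("X", pre=10, post=10), mk_circ("Y", pre=4, post=0)]
    counts = {("m1", "X"): 2, ("m1", "Y"): 1}
    mirnas = [mk_mirna("m1", 5, 15)]
    (base,) = summarize_mirna_pairing(counts, circs, mirnas)
    k = 3.0
    scaled_circs = [mk_circ("X", pre=30, post=30), mk_circ("Y", pre=12, post=0)]
    (s1,) = summarize_mirna_pairing(counts, scaled_circs, mirnas)
    assert s1.effective_sites == pytest.approx(k * base.effective_sites)
    assert s1.pairing_coefficient == pytest.approx(k * base.pairing_coefficient)
    scaled_mirnas = [mk_mirna("m1", 5 * k, 15 * k)]
    (s2,) = summarize_mirna_pairing(counts, circs, scaled_mirnas)
    assert s2.pairing_coefficient == pytest.approx(base.pairing_coefficient / k)
    loads = circ_load_index(counts, scaled_mirnas)
    base_loads = circ_load_index(counts, mirnas)
    for a, b in zip(loads, base_loads):
        assert a.load_index == pytest.approx(k * b.load_index)


# ---------------------------------------------------------------------------
# Quartiles
# ---------------------------------------------------------------------------

def test_eight_distinct_coefficients_split_two_per_quartile():
    labels = assign_quartile_labels([1, 2, 3, 4, 5, 6, 7, 8])
    assert labels == [1, 1, 2, 2, 3, 3, 4, 4]


def test_all_ties_fall_in_quartile_one():
    assert assign_quartile_labels([5.0] * 8) == [1] * 8


def test_quartiles_permutation_invariant():
    rng = np.random.default_rng(3)
    vals = list(rng.lognormal(0, 1, 40))
    base = assign_quartile_labels(vals)
    perm = rng.permutation(40)
    shuffled = assign_quartile_labels([vals[i] for i in perm])
    assert [base[i] for i in perm] == shuffled


def test_quartiles_require_four_summaries():
    summaries = [
        MiRNAPairingSummary("m1", 1, 1.0, 1.0, 1.0),
        MiRNAPairingSummary("m2", 1, 2.0, 1.0, 2.0),
    ]
    with pytest.raises(ParameterError):
        assign_quartiles(summaries)


def test_high_propensity_mirnas_occupy_top_quartile(small_dataset):
    """The cohort generated as most highly paired lands in quartile 4."""
    ds = small_dataset
    counts = join_sites_to_circrnas(
        filter_interactions(ds.interactions, 1, 2), ds.circrnas
    )
    summaries = assign_quartiles(
        summarize_mirna_pairing(counts, ds.circrnas, ds.mirnas)
    )
    q4 = {s.mirna_id for s in summaries if s.quartile == 4}
    high = {m for m, t in ds.tiers.items() if t == "high"}
    assert len(q4 & high) / len(q4) >= 0.5
    lam = [ds.propensity[s.mirna_id] for s in summaries]
    coef = [s.pairing_coefficient for s in summaries]
    from scipy.stats import spearmanr
    assert spearmanr(lam, coef).statistic > 0.3


# ---------------------------------------------------------------------------
# Load index
# ---------------------------------------------------------------------------

def test_load_index_hand_computed():
    mirnas = [mk_mirna("A", 10, 10), mk_mirna("B", 4, 4)]
    counts = {("A", "c1"): 2, ("B", "c1"): 1}
    (load,) = circ_load_index(counts, mirnas)
    assert (load.total_sites, load.load_index) == (3, 24.0)


def test_siteless_circ_has_zero_load():
    loads = circ_load_index({}, [mk_mirna()], [mk_circ("c9")])
    assert loads == [type(loads[0])("c9", 0, 0.0)]


# ---------------------------------------------------------------------------
# Pairing by region of origin
# ---------------------------------------------------------------------------

def test_identical_regions_rarely_differ():
    rng = np.random.default_rng(1)
    rejections = 0
    for rep in range(40):
        circs, counts = [], {}
        for i in range(40):
            region = "CDS" if i < 20 else "3UTR"
            cid = f"c{i}"
            circs.append(mk_circ(cid, start=i * 1000, end=i * 1000 + 300, region=region))
            counts[("m1", cid)] = int(rng.poisson(5))
        _, tests = pairing_by_region(circs, counts)
        rejections += any(t.p_adjusted < 0.05 for t in tests)
    assert rejections <= 4  # ~FWER-level false positives over 40 replicates


def test_tenfold_region_difference_detected():
    rng = np.random.default_rng(2)
    circs, counts = [], {}
    for i in range(40):
        region = "CDS" if i < 20 else "3UTR"
        cid = f"c{i}"
        circs.append(mk_circ(cid, start=i * 1000, end=i * 1000 + 300, region=region))
        lam = 30 if region == "3UTR" else 3
        counts[("m1", cid)] = int(rng.poisson(lam))
    summaries, tests = pairing_by_region(circs, counts)
    assert any(t.p_adjusted < 0.05 for t in tests)


def test_single_region_skips_test():
    circs = [mk_circ(f"c{i}", start=i * 1000, end=i * 1000 + 100) for i in range(4)]
    summaries, tests = pairing_by_region(circs, {("m1", "c0"): 1})
    assert tests is None and "CDS" in summaries


def test_all_unknown_regions_is_an_error():
    circs = [mk_circ("c1", region="unknown")]
    with pytest.raises(ParameterError):
        pairing_by_region(circs, {})
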