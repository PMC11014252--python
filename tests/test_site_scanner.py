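import numpy as np
import pytest

from circtdmd import (
    Alignment3p,
    MiRNARecord,
    ParameterError,
    RunConfig,
    SiteMatch,
    align_3prime,
    circularize_sequence,
    classify_architecture,
    find_seed_matches,
    reverse_complement,
    scan_pairs,
)
from circtdmd.io_formats import ConsistencyError, InputError
from circtdmd.synthetic_data import plant_site

from oracles import naive_scan

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


def mk_mirna(seq=LET7, mid="mir"):
    return MiRNARecord(id=mid, sequence=seq, abundance_pre=1.0, abundance_post=1.0)


def random_rna(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# circularize_sequence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,window,expected",
    [("ACGU", 3, "ACGUAC"), ("ACGU", 1, "ACGU"), ("ACGU", 4, "ACGUACG")],
)
def test_circularize_appends_window_minus_one(seq, window, expected):
    assert circularize_sequence(seq, window) == expected


def test_circularize_rejects_oversized_window():
    with pytest.raises(ParameterError):
        circularize_sequence("ACGU", 5)


# ---------------------------------------------------------------------------
# find_seed_matches
# ---------------------------------------------------------------------------

def test_let7_8mer_site():
    sites = find_seed_matches("AAACUACCUCAAAA", mk_mirna())
    assert sites == [(10, "8mer")]


def test_full_reverse_complement_is_7mer_m8_unless_m1_is_U():
    m = mk_mirna("GGAGGUAGUAGGUUGUAUAGUU")  # m1 = G, so t1 = C (not A)
    target = reverse_complement(m.sequence)
    sites = find_seed_matches(target, m)
    assert sites == [(len(target) - 1, "7mer-m8")]
    # with m1 = U, the complement places an A opposite position 1: 8mer
    m2 = mk_mirna(LET7)
    target2 = reverse_complement(m2.sequence)
    assert find_seed_matches(target2, m2) == [(len(target2) - 1, "8mer")]


def test_seed_mutant_target_yields_no_sites():
    target = list("AAACUACCUCAAAA")
    # disrupt the complement of seed positions 3-5 (target indices 7..9)
    for i in (5, 6, 7):
        target[i] = "G" if target[i] != "G" else "C"
    assert find_seed_matches("".join(target), mk_mirna()) == []


def test_min_class_filter_never_increases_calls():
    rng = np.random.default_rng(5)
    m = mk_mirna()
    counts = []
    for min_class in ("6mer", "7mer-A1", "7mer-m8", "8mer"):
        total = 0
        for i in range(50):
            rng2 = np.random.default_rng(i)
            total += len(find_seed_matches(random_rna(rng2, 200), m, min_class))
        counts.append(total)
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# align_3prime
# ---------------------------------------------------------------------------

def test_perfect_tdmd_geometry_recovers_bulge_and_full_pairing():
    rng = np.random.default_rng(0)
    m = mk_mirna()
    flank = random_rna(rng, 10)
    seq, t1 = plant_site(
        flank + random_rna(rng, 30), m, "TDMD-like", 10, rng,
        bulge_len=3, n_mismatches=0,
    )
    aln = align_3prime(seq, t1, m)
    assert (aln.paired_3p, aln.mismatches_3p, aln.bulge_len) == (10, 0, 3)


def test_perfect_complement_aligns_with_no_bulge():
    m = mk_mirna()
    target = "GG" + reverse_complement(m.sequence) + "GG"
    (offset, _), = find_seed_matches(target, m, "7mer-m8")
    aln = align_3prime(target, offset, m)
    assert aln == Alignment3p(10, 0, 0, 10, 8)


def test_seed_only_site_rarely_reaches_tdmd_pairing():
    """Random 3' flanks almost never reach the TDMD pairing threshold."""
    m = mk_mirna()
    rng = np.random.default_rng(42)
    hits = 0
    n = 1000
    for _ in range(n):
        target = random_rna(rng, 14) + "CUACCUCA" + "AA"
        (q, _), = [s for s in find_seed_matches(target, m) if s[0] == 21]
        aln = align_3prime(target, q, m)
        cfg = RunConfig()
        tdmd_like = (
            aln.paired_3p >= cfg.min_paired_3p
            and aln.paired_run_3p >= cfg.min_contiguous_paired
            and aln.mismatches_3p <= cfg.max_mismatches
        )
        hits += tdmd_like
    assert hits / n < 0.05


# ---------------------------------------------------------------------------
# classify_architecture
# ---------------------------------------------------------------------------

def _site(**kw):
    base = dict(
        mirna_id="m", target_id="t", target_topology="linear", offset=30,
        seed_class="8mer", paired_3p=10, mismatches_3p=0, bulge_len=3,
        paired_run_3p=10, mirna_length=22,
    )
    base.update(kw)
    return SiteMatch(**base)


@pytest.mark.parametrize(
    "fields,expected",
    [
        # full 3' pairing with a central bulge: the TDMD geometry
        (dict(), "TDMD-like"),
        # more than 3 mismatches disqualifies even with a bulge
        (dict(paired_3p=6, mismatches_3p=4, paired_run_3p=6), "canonical"),
        # perfect contiguous complement enables slicing
        (dict(bulge_len=0, mismatches_3p=0, paired_3p=10), "slicing"),
        # seed-only site is canonical
        (dict(seed_class="6mer", paired_3p=2, mismatches_3p=8,
              bulge_len=2, paired_run_3p=2), "canonical"),
        # 7mer seed with 3 mismatches and a contiguous run still qualifies
        (dict(seed_class="7mer-A1", paired_3p=7, mismatches_3p=3,
              paired_run_3p=7), "TDMD-like"),
        # bulge outside the 1-5 range is not a TDMD central loop
        (dict(bulge_len=6, mismatches_3p=1, paired_3p=9, paired_run_3p=9), "canonical"),
    ],
)
def test_architecture_classification(fields, expected):
    assert classify_architecture(_site(**fields)) == expected


def test_inconsistent_fields_raise():
    with pytest.raises(ConsistencyError):
        classify_architecture(_site(paired_3p=11))  # only 10 3' positions exist
    with pytest.raises(ConsistencyError):
        classify_architecture(_site(paired_3p=5, paired_run_3p=7))


def test_raising_max_mismatches_never_loses_tdmd_calls(small_dataset):
    mirnas = small_dataset.mirnas
    targets = small_dataset.targets()
    counts = []
    for mm in (0, 1, 2, 3, 5):
        cfg = RunConfig(max_mismatches=mm)
        sites = scan_pairs(targets, mirnas, cfg)
        counts.append(sum(1 for s in sites if s.architecture == "TDMD-like"))
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# scan_pairs: junctions, rotation, duplicates
# ---------------------------------------------------------------------------

def test_junction_spanning_site_found_exactly_once():
    rng = np.random.default_rng(3)
    m = mk_mirna()
    base = random_rna(rng, 50)
    # footprint 25 starting at position 40 wraps 15 nt past the junction
    seq, t1 = plant_site(base, m, "TDMD-like", 40, rng, bulge_len=3,
                         n_mismatches=0, circular=True)
    sites = scan_pairs([("c", seq, "circular")], [m])
    tdmd = [s for s in sites if s.architecture == "TDMD-like"]
    assert len(tdmd) == 1
    assert tdmd[0].offset == t1 < 50
    # the same sequence read as a linear molecule has no such site
    linear = scan_pairs([("l", seq, "linear")], [m])
    assert all(s.architecture != "TDMD-like" for s in linear)


def test_rotation_invariance_of_circular_scan():
    rng = np.random.default_rng(9)
    m = mk_mirna()
    seq, _ = plant_site(random_rna(rng, 60), m, "TDMD-like", 20, rng,
                        bulge_len=2, n_mismatches=1, circular=True)
    reference = scan_pairs([("c", seq, "circular")], [m])
    ref_set = {
        (s.seed_class, s.paired_3p, s.mismatches_3p, s.bulge_len, s.architecture)
        for s in reference
    }
    for shift in (1, 13, 37, 59):
        rotated = seq[shift:] + seq[:shift]
        sites = scan_pairs([("c", rotated, "circular")], [m])
        got = {
            (s.seed_class, s.paired_3p, s.mismatches_3p, s.bulge_len, s.architecture)
            for s in sites
        }
        assert got == ref_set
        offsets = {(s.offset + shift) % len(seq) for s in sites}
        assert offsets == {s.offset for s in reference}


def test_duplicate_target_ids_rejected():
    m = mk_mirna()
    with pytest.raises(InputError):
        scan_pairs([("t", "ACGU" * 10, "linear"), ("t", "ACGU" * 10, "linear")], [m])


def test_scan_with_no_mirnas_is_empty():
    assert scan_pairs([("t", "ACGU" * 10, "linear")], []) == []


# ---------------------------------------------------------------------------
# Oracle equivalence (small randomized suite; the full 500-case suite
# runs in the acceptance tests)
# ---------------------------------------------------------------------------

def test_scanner_matches_bruteforce_enumeration_on_random_cases():
    rng = np.random.default_rng(2024)
    cfg = RunConfig()
    for case in range(150):
        m = mk_mirna(random_rna(rng, 22), f"m{case}")
        target = random_rna(rng, int(rng.integers(20, 61)))
        if rng.random() < 0.4:  # seed a planted site in some cases
            arch = ["canonical", "TDMD-like", "slicing"][int(rng.integers(0, 3))]
            pos = int(rng.integers(0, max(1, len(target) - 28)))
            try:
                target, _ = plant_site(target, m, arch, pos, rng)
            except ParameterError:
                pass
        got = scan_pairs([("t", target, "linear")], [m], cfg)
        expected = naive_scan(target, m.sequence)
        assert len(got) == len(expected), f"case {case}"
        for g, e in zip(got, expected):
            assert (
                g.offset, g.seed_class, g.paired_3p, g.mismatches_3p,
                g.bulge_len, g.paired_run_3p, g.architecture,
            ) == (
                e["offset"], e["seed_class"], e["paired_3p"], e["mismatches_3p"],
                e["bulge_len"], e["paired_run_3p"], e["architecture"],
            ), f"case {case} offset {g.offset}"
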