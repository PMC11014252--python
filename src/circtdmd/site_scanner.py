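"""Detection and classification of miRNA binding sites on linear and circular RNAs.

The scanner finds seed matches (6mer / 7mer-A1 / 7mer-m8 / 8mer by the
standard m8-pairing and t1-adenosine rules), scores 3'-supplementary
pairing by exhaustive enumeration of target-side central-loop
geometries, and labels each site's architecture:

* ``slicing``   - contiguous perfect complementarity over the full
  miRNA (no central bulge, no 3' mismatches): the geometry that enables
  AGO2-catalyzed target cleavage.
* ``TDMD-like`` - seed pairing (>= 7mer) plus extensive 3'-end
  complementarity: a central target-side bulge of 1-5 nt opposite miRNA
  positions 9-12, at least 6 of positions 13-22 paired including a
  contiguous run of >= 4, and no more than 3 mismatches in addition to
  the central bulge.
* ``canonical`` - any other seed match (ordinary silencing-style site).

Coordinates: a site's ``offset`` is the 0-based target position of the
t1 nucleotide (opposite miRNA position 1); the duplex is antiparallel,
so miRNA position k faces target position ``offset - (k-1)``, shifted by
the bulge length for positions 3' of the loop.  Circular targets are
scanned through a sequence extension covering the backsplice junction
and offsets are reported modulo the circle length, so junction-spanning
sites are found exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .io_formats import (
    SEED_CLASSES,
    ConsistencyError,
    InputError,
    ParameterError,
    RunConfig,
    ValidationError,
    logger,
)

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_WOBBLE = {("G", "U"), ("U", "G")}

SEED_RANK = {name: i for i, name in enumerate(SEED_CLASSES)}

ARCHITECTURES = ("canonical", "TDMD-like", "slicing")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MiRNARecord:
    """A mature miRNA: 5'->3' RNA sequence plus two-condition abundance."""

    id: str
    sequence: str
    abundance_pre: float = 0.0
    abundance_post: float = 0.0

    def __post_init__(self) -> None:
        if not (18 <= len(self.sequence) <= 26):
            raise ValidationError(
                f"miRNA {self.id!r} length {len(self.sequence)} outside 18..26"
            )
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ValidationError(f"miRNA {self.id!r} has non-ACGU characters {sorted(bad)}")
        if self.abundance_pre < 0 or self.abundance_post < 0:
            raise ValidationError(f"miRNA {self.id!r} has negative abundance")

    @property
    def mean_abundance(self) -> float:
        return (self.abundance_pre + self.abundance_post) / 2.0

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (the seed region)."""
        return self.sequence[1:8]


@dataclass
class CircRNARecord:
    """A circRNA: genomic span, junction-read abundance and backspliced sequence."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    junction_reads_pre: float = 0.0
    junction_reads_post: float = 0.0
    sequence: str | None = None
    region_of_origin: str = "unknown"
    host_gene: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"circRNA {self.id!r}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"circRNA {self.id!r}: bad strand {self.strand!r}")
        if self.junction_reads_pre < 0 or self.junction_reads_post < 0:
            raise ValidationError(f"circRNA {self.id!r}: negative junction reads")
        if self.sequence is not None and len(self.sequence) < 1:
            raise ValidationError(f"circRNA {self.id!r}: empty sequence")
        if self.region_of_origin not in ("5UTR", "CDS", "3UTR", "mixed", "unknown"):
            raise ValidationError(
                f"circRNA {self.id!r}: bad region {self.region_of_origin!r}"
            )

    @property
    def mean_junction_reads(self) -> float:
        return (self.junction_reads_pre + self.junction_reads_post) / 2.0


@dataclass
class SiteMatch:
    """One sequence-level binding site with its pairing geometry."""

    mirna_id: str
    target_id: str
    target_topology: str  # linear | circular
    offset: int           # 0-based target position of the t1 nucleotide
    seed_class: str
    paired_3p: int        # paired miRNA nucleotides among positions 13..end
    mismatches_3p: int    # mismatched (non-bulge) positions among 9..end
    bulge_len: int        # target-side central loop opposite positions 9-12
    paired_run_3p: int    # longest contiguous paired run among 13..end
    mirna_length: int
    architecture: str = "canonical"


class Alignment3p(NamedTuple):
    """Best 3'-supplementary pairing geometry for one seed-matched site."""

    paired_3p: int
    mismatches_3p: int
    bulge_len: int
    paired_run_3p: int
    bulge_after: int  # loop sits 3' of this miRNA position (8..11)


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _pairs(m: str, t: str, wobble: bool = False) -> bool:
    if _COMPLEMENT.get(m) == t:
        return True
    return wobble and (m, t) in _WOBBLE


def circularize_sequence(seq: str, window: int) -> str:
    """Extend a circular sequence past its backsplice junction.

    Returns ``seq`` concatenated with its first ``window - 1``
    nucleotides so that every site whose footprint spans the junction
    appears contiguously in the extension.
    """
    if not 0 <= window <= len(seq):
        raise ParameterError(
            f"window {window} outside 0..{len(seq)} for circular sequence"
        )
    if window == 0:
        return seq
    return seq + seq[: window - 1]


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


# ---------------------------------------------------------------------------
# Seed matching
# ---------------------------------------------------------------------------

def find_seed_matches(
    target: str, mirna: MiRNARecord, min_class: str = "6mer"
) -> list[tuple[int, str]]:
    """Find seed-matched candidate sites in a (linear) target sequence.

    Returns ``[(offset, seed_class), ...]`` in increasing offset order.
    The 6mer core is strict Watson-Crick complementarity of miRNA
    positions 2-7; the class is upgraded by m8 pairing (7mer-m8) and by
    a target adenosine opposite position 1 (7mer-A1 / 8mer).  G:U pairs
    never count as seed pairing.
    """
    if min_class not in SEED_RANK:
        raise ParameterError(f"unknown seed class {min_class!r}")
    bad = set(target) - set("ACGUN")
    if bad:
        raise ValidationError(f"target has non-ACGUN characters {sorted(bad)}")
    m = mirna.sequence
    core = reverse_complement(m[1:7])  # complements m2..m7, target 5'->3'
    min_rank = SEED_RANK[min_class]
    out = []
    for s in _find_all(target, core):
        q = s + 6  # t1 position: core occupies q-6..q-1
        if q >= len(target):
            continue  # t1 would fall off the 3' end
        m8_paired = q - 7 >= 0 and _pairs(m[7], target[q - 7])
        t1_a = target[q] == "A"
        if m8_paired and t1_a:
            seed_class = "8mer"
        elif m8_paired:
            seed_class = "7mer-m8"
        elif t1_a:
            seed_class = "7mer-A1"
        else:
            seed_class = "6mer"
        if SEED_RANK[seed_class] >= min_rank:
            out.append((q, seed_class))
    return out


# ---------------------------------------------------------------------------
# 3' supplementary pairing
# ---------------------------------------------------------------------------

def align_3prime(
    target: str,
    offset: int,
    mirna: MiRNARecord,
    max_bulge: int = 5,
    gu_wobble: bool = False,
) -> Alignment3p:
    """Score 3'-supplementary pairing of a seed-matched site.

    Exhaustively enumerates target-side loop lengths ``0..max_bulge``
    inserted at every point opposite miRNA positions 9-12 and returns
    the geometry maximizing the number of paired nucleotides among
    positions 13..end, breaking ties by fewer mismatches, then smaller
    bulge, then the 5'-most loop placement.  Pairing is Watson-Crick;
    G:U counts as a mismatch unless ``gu_wobble`` is set.  Target
    positions outside the sequence count as unpaired.
    """
    m = mirna.sequence
    n = len(m)
    best: tuple | None = None
    best_aln: Alignment3p | None = None
    for b in range(0, max_bulge + 1):
        # the loop sits between the target nt facing m_j and m_{j+1}
        placements = (8,) if b == 0 else (8, 9, 10, 11)
        for j in placements:
            paired_flags = []
            mism = 0
            for k in range(9, n + 1):
                t = offset - (k - 1) - (b if k > j else 0)
                ok = 0 <= t < len(target) and _pairs(m[k - 1], target[t], gu_wobble)
                if k >= 13:
                    paired_flags.append(ok)
                if not ok:
                    mism += 1
            paired = sum(paired_flags)
            run = best_run = 0
            for f in paired_flags:
                run = run + 1 if f else 0
                best_run = max(best_run, run)
            key = (-paired, mism, b, j)
            if best is None or key < best:
                best = key
                best_aln = Alignment3p(paired, mism, b, best_run, j)
    assert best_aln is not None
    return best_aln


# ---------------------------------------------------------------------------
# Architecture classification
# ---------------------------------------------------------------------------

def classify_architecture(site: SiteMatch, config: RunConfig | None = None) -> str:
    """Label a site canonical / TDMD-like / slicing from its pairing fields.

    ``slicing`` requires contiguous perfect complementarity over the
    whole miRNA: full seed (>= 7mer-m8), no central bulge, no 3'
    mismatches and every 3' position paired.  ``TDMD-like`` requires a
    seed match of at least 7mer class, a central bulge within the
    configured range, at least ``min_paired_3p`` of positions 13..end
    paired including a contiguous run of ``min_contiguous_paired``, and
    at most ``max_mismatches`` mismatches in addition to the bulge.
    """
    cfg = config or RunConfig()
    n3 = site.mirna_length - 12
    if site.paired_3p < 0 or site.paired_3p > n3:
        raise ConsistencyError(
            f"paired_3p={site.paired_3p} exceeds 3' length {n3} "
            f"for {site.mirna_id}:{site.target_id}"
        )
    if site.mismatches_3p < 0 or site.paired_run_3p > site.paired_3p:
        raise ConsistencyError(
            f"inconsistent 3' fields for {site.mirna_id}:{site.target_id}"
        )
    rank = SEED_RANK[site.seed_class]
    if (
        rank >= SEED_RANK["7mer-m8"]
        and site.bulge_len == 0
        and site.mismatches_3p == 0
        and site.paired_3p == n3
    ):
        return "slicing"
    if (
        rank >= SEED_RANK["7mer-A1"]
        and cfg.bulge_min <= site.bulge_len <= cfg.bulge_max
        and site.paired_3p >= cfg.min_paired_3p
        and site.paired_run_3p >= cfg.min_contiguous_paired
        and site.mismatches_3p <= cfg.max_mismatches
    ):
        return "TDMD-like"
    return "canonical"


# ---------------------------------------------------------------------------
# Full scan
# ---------------------------------------------------------------------------

def site_footprint(mirna_length: int, max_bulge: int) -> int:
    """Maximal target footprint of one site (miRNA length + largest loop)."""
    return mirna_length + max_bulge


def scan_pairs(
    targets: Sequence[tuple[str, str, str]],
    mirnas: Sequence[MiRNARecord],
    config: RunConfig | None = None,
) -> list[SiteMatch]:
    """Scan every (target, miRNA) pair and classify all seed-matched sites.

    ``targets`` is ``[(id, sequence, topology), ...]`` with topology
    ``linear`` or ``circular``.  Circular targets are extended across
    the backsplice junction before scanning and offsets are reported
    modulo the circle length; junction-wrapped duplicates are collapsed
    keeping the representative with full upstream context.  Output is
    sorted by (target id, miRNA id, offset).
    """
    cfg = config or RunConfig()
    seen_ids: set[str] = set()
    for tid, _, topo in targets:
        if tid in seen_ids:
            raise InputError(f"duplicate target id {tid!r}")
        seen_ids.add(tid)
        if topo not in ("linear", "circular"):
            raise InputError(f"target {tid!r}: bad topology {topo!r}")

    results: list[SiteMatch] = []
    for tid, seq, topo in targets:
        for mir in mirnas:
            footprint = site_footprint(len(mir.sequence), cfg.bulge_max)
            if topo == "circular":
                window = min(footprint, len(seq))
                scan_seq = circularize_sequence(seq, window)
            else:
                scan_seq = seq
            per_offset: dict[int, tuple[int, str]] = {}
            for q, seed_class in find_seed_matches(scan_seq, mir, cfg.min_seed_class):
                rep = q % len(seq) if topo == "circular" else q
                prev = per_offset.get(rep)
                # keep the wrapped representative (largest q): it has
                # full upstream context on a circle
                if prev is None or q > prev[0]:
                    per_offset[rep] = (q, seed_class)
            for rep in sorted(per_offset):
                q, seed_class = per_offset[rep]
                aln = align_3prime(scan_seq, q, mir, cfg.bulge_max, cfg.gu_wobble)
                site = SiteMatch(
                    mirna_id=mir.id,
                    target_id=tid,
                    target_topology=topo,
                    offset=rep,
                    seed_class=seed_class,
                    paired_3p=aln.paired_3p,
                    mismatches_3p=aln.mismatches_3p,
                    bulge_len=aln.bulge_len,
                    paired_run_3p=aln.paired_run_3p,
                    mirna_length=len(mir.sequence),
                )
                site.architecture = classify_architecture(site, cfg)
                results.append(site)
    results.sort(key=lambda s: (s.target_id, s.mirna_id, s.offset))
    return results
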