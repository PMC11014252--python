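"""Interaction-weighted pairing statistics for circRNA-miRNA networks.

From a CLIP-supported interaction table and two-condition expression
data this module derives, per miRNA, the number of *effective sites*
offered by circRNAs (absolute validated site counts weighted by each
circRNA's mean backsplice-junction reads across the two conditions) and
the *pairing coefficient* (effective sites divided by the miRNA's mean
abundance), stratifies miRNAs into quartiles of increasing pairing
coefficient ('- paired' .. '+++ paired'), and computes, per circRNA,
the *pairing load* index (pooled site counts weighted by miRNA mean
abundance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import InputError, ParameterError, ValidationError, logger
from .site_scanner import CircRNARecord, MiRNARecord

QUARTILE_LABELS = {1: "- paired", 2: "+ paired", 3: "++ paired", 4: "+++ paired"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class InteractionRecord:
    """One ENCORI-style miRNA-target interaction with its evidence counts."""

    mirna_id: str
    target_id: str
    target_class: str  # circRNA | mRNA | lncRNA
    chrom: str
    site_start: int    # 0-based half-open
    site_end: int
    strand: str
    clip_experiments: int = 0
    supporting_programs: int = 0

    def __post_init__(self) -> None:
        if self.site_start >= self.site_end:
            raise ValidationError(
                f"interaction {self.mirna_id}:{self.target_id}: start >= end"
            )
        if self.clip_experiments < 0 or self.supporting_programs < 0:
            raise ValidationError(
                f"interaction {self.mirna_id}:{self.target_id}: negative evidence count"
            )


@dataclass
class MiRNAPairingSummary:
    mirna_id: str
    absolute_sites: int
    effective_sites: float
    mean_abundance: float
    pairing_coefficient: float
    quartile: int | None = None  # 1 ('- paired') .. 4 ('+++ paired')


@dataclass
class CircLoadSummary:
    circ_id: str
    total_sites: int
    load_index: float


# ---------------------------------------------------------------------------
# Filtering and the fuzzy genomic join
# ---------------------------------------------------------------------------

def filter_interactions(
    records: Sequence[InteractionRecord],
    min_clip: int = 1,
    min_programs: int = 2,
) -> list[InteractionRecord]:
    """Keep interactions with enough CLIP and prediction-program support.

    Defaults reproduce the validated-interaction download criteria
    (clipExpNum >= 1, programNum >= 2); order is preserved.
    """
    return [
        r
        for r in records
        if r.clip_experiments >= min_clip and r.supporting_programs >= min_programs
    ]


def join_sites_to_circrnas(
    interactions: Sequence[InteractionRecord],
    circrnas: Sequence[CircRNARecord],
) -> dict[tuple[str, str], int]:
    """Assign interaction sites to circRNAs by genomic location.

    A site belongs to a circRNA iff it is on the same chromosome and
    strand and its interval lies fully within the circRNA's genomic
    span; an interaction may match several overlapping circRNAs.
    Returns ``{(mirna_id, circ_id): absolute site count}``.
    """
    by_key: dict[tuple[str, str], list[CircRNARecord]] = {}
    for c in circrnas:
        by_key.setdefault((c.chrom, c.strand), []).append(c)
    counts: dict[tuple[str, str], int] = {}
    for rec in interactions:
        for c in by_key.get((rec.chrom, rec.strand), ()):
            if rec.site_start >= c.start and rec.site_end <= c.end:
                key = (rec.mirna_id, c.id)
                counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Effective sites, pairing coefficient, quartiles
# ---------------------------------------------------------------------------

def effective_sites_per_circ(count: int, circ: CircRNARecord) -> float:
    """Weight a circRNA's site count by its mean junction reads.

    ``count * (junction_reads_pre + junction_reads_post) / 2`` — the
    contribution of one circRNA to a miRNA's effective sites.
    """
    if count < 0:
        raise ParameterError("site count must be >= 0")
    return count * circ.mean_junction_reads


def summarize_mirna_pairing(
    counts: Mapping[tuple[str, str], int],
    circrnas: Sequence[CircRNARecord],
    mirnas: Sequence[MiRNARecord],
    condition: str = "mean",
) -> list[MiRNAPairingSummary]:
    """Per-miRNA effective sites and pairing coefficient.

    Effective sites are summed over all circRNAs; the pairing
    coefficient divides by the miRNA's mean abundance across the two
    conditions.  miRNAs with zero mean abundance are excluded (their
    coefficient is undefined) and logged.

    ``condition="pre"`` weights by pre-differentiation junction reads
    and abundances only.  This variant exists for stratifying tests on
    differentiation fold changes: the default mean weighting contains
    the post-differentiation outcome, so conditioning such a test on it
    selects on the outcome and fabricates attenuation.
    """
    if condition not in ("mean", "pre"):
        raise ParameterError(f"unknown condition {condition!r}")
    circ_by_id = {c.id: c for c in circrnas}
    abs_by_mir: dict[str, int] = {}
    eff_by_mir: dict[str, float] = {}
    for (mid, cid), n in counts.items():
        circ = circ_by_id[cid]
        weight = circ.mean_junction_reads if condition == "mean" else circ.junction_reads_pre
        abs_by_mir[mid] = abs_by_mir.get(mid, 0) + n
        eff_by_mir[mid] = eff_by_mir.get(mid, 0.0) + n * weight
    out = []
    for mir in mirnas:
        absolute = abs_by_mir.get(mir.id, 0)
        effective = eff_by_mir.get(mir.id, 0.0)
        mean_ab = mir.mean_abundance if condition == "mean" else mir.abundance_pre
        if mean_ab <= 0:
            logger.info("excluding miRNA %s: zero mean abundance", mir.id)
            continue
        out.append(
            MiRNAPairingSummary(
                mirna_id=mir.id,
                absolute_sites=absolute,
                effective_sites=effective,
                mean_abundance=mean_ab,
                pairing_coefficient=effective / mean_ab,
            )
        )
    return out


def quartile_breaks(values: Sequence[float]) -> tuple[float, float, float]:
    """Empirical 25/50/75 percentile breaks (linear interpolation)."""
    if len(values) < 4:
        raise ParameterError(f"need >= 4 values for quartiles, got {len(values)}")
    q1, q2, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(q1), float(q2), float(q3)


def assign_quartile_labels(values: Sequence[float]) -> list[int]:
    """Quartile (1..4) per value; ties at a break go to the lower quartile."""
    b1, b2, b3 = quartile_breaks(values)
    return [1 + (v > b1) + (v > b2) + (v > b3) for v in values]


def assign_quartiles(summaries: Sequence[MiRNAPairingSummary]) -> list[MiRNAPairingSummary]:
    """Stratify miRNAs into quartiles of increasing pairing coefficient.

    Quartile 1 is '- paired' (least), quartile 4 '+++ paired' (most).
    Summaries are modified in place and returned.
    """
    qs = assign_quartile_labels([s.pairing_coefficient for s in summaries])
    for s, q in zip(summaries, qs):
        s.quartile = q
    return list(summaries)


# ---------------------------------------------------------------------------
# circRNA pairing load
# ---------------------------------------------------------------------------

def circ_load_index(
    counts: Mapping[tuple[str, str], int],
    mirnas: Sequence[MiRNARecord],
    circrnas: Sequence[CircRNARecord] | None = None,
) -> list[CircLoadSummary]:
    """Per-circRNA pooled site count and miRNA-abundance-weighted load.

    ``load_index(c) = sum_m sites(m, c) * mean_abundance(m)``.  When
    ``circrnas`` is given, every circRNA appears in the output (zero
    load if siteless); otherwise only circRNAs present in the count
    table do.
    """
    ab = {m.id: m.mean_abundance for m in mirnas}
    total: dict[str, int] = {}
    load: dict[str, float] = {}
    for (mid, cid), n in counts.items():
        if mid not in ab:
            continue
        total[cid] = total.get(cid, 0) + n
        load[cid] = load.get(cid, 0.0) + n * ab[mid]
    ids = [c.id for c in circrnas] if circrnas is not None else sorted(total)
    return [
        CircLoadSummary(circ_id=cid, total_sites=total.get(cid, 0), load_index=load.get(cid, 0.0))
        for cid in ids
    ]


# ---------------------------------------------------------------------------
# Pairing by genomic region of origin
# ---------------------------------------------------------------------------

def pairing_by_region(
    circrnas: Sequence[CircRNARecord],
    counts: Mapping[tuple[str, str], int],
    alpha: float = 0.05,
):
    """Distribution of per-circRNA pooled pairing by region of origin.

    Groups each circRNA's total validated site count by its genomic
    region of origin (5'UTR / CDS / 3'UTR / mixed) and runs a
    rank-based comparison of every region against the first, testing
    whether pairing depends on where circRNAs originate.  Returns
    ``(per-region summaries, group_compare results or None)``.
    """
    from .differential_stats import group_compare

    total: dict[str, int] = {}
    for (mid, cid), n in counts.items():
        total[cid] = total.get(cid, 0) + n
    groups: dict[str, list[float]] = {}
    for c in circrnas:
        if c.region_of_origin == "unknown":
            continue
        groups.setdefault(c.region_of_origin, []).append(float(total.get(c.id, 0)))
    if not groups:
        raise ParameterError("all circRNAs have unknown region of origin")
    summaries = {
        region: {
            "n": len(vals),
            "mean": float(np.mean(vals)),
            "median": float(np.median(vals)),
        }
        for region, vals in sorted(groups.items())
    }
    if len(groups) < 2:
        logger.info("pairing_by_region: single region present, test skipped")
        return summaries, None
    reference = sorted(groups)[0]
    tests = group_compare(groups, reference, method="wilcoxon_hochberg")
    return summaries, tests
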