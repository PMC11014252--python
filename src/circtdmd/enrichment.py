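"""Quartile-wise enrichment of TDMD-like site architectures.

For each pairing-coefficient quartile this module computes the
proportion of miRNAs with at least one predicted TDMD-like site on the
requested target class (circRNAs; linear RNAs pooled over 5'UTR, CDS
and 3'UTR; or the 3'UTR-only sensitivity variant) and tests each
quartile against the least-paired quartile with Fisher's exact test.
Sites on circRNAs are first restricted to expressed circRNAs (at least
one junction read in either condition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .io_formats import InputError, ParameterError, logger
from .pairing_metrics import MiRNAPairingSummary
from .site_scanner import CircRNARecord, SiteMatch

TARGET_CLASSES = ("circRNA", "linearRNA", "linear_3UTR_only")


@dataclass
class EnrichmentResult:
    quartile: int
    target_class: str
    n_with_tdmd: int
    n_total: int
    proportion: float
    odds_ratio: float = float("nan")
    p_value: float = float("nan")


# ---------------------------------------------------------------------------
# Expressed-target filter
# ---------------------------------------------------------------------------

def filter_expressed_targets(
    sites: Sequence[SiteMatch],
    circrnas: Sequence[CircRNARecord],
    min_reads: float = 1.0,
    linear_abundance: Mapping[str, float] | None = None,
) -> list[SiteMatch]:
    """Keep sites on expressed targets only.

    A circRNA counts as expressed with at least ``min_reads`` junction
    reads in either condition.  Sites on linear targets pass through
    unless ``linear_abundance`` (max abundance per target id) is given,
    in which case the same threshold applies.
    """
    circ_by_id = {c.id: c for c in circrnas}
    out = []
    for s in sites:
        if s.target_topology == "circular":
            c = circ_by_id.get(s.target_id)
            if c is None:
                continue
            if max(c.junction_reads_pre, c.junction_reads_post) >= min_reads:
                out.append(s)
        else:
            if linear_abundance is None or linear_abundance.get(s.target_id, 0.0) >= min_reads:
                out.append(s)
    return out


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def tdmd_proportions(
    sites: Sequence[SiteMatch],
    summaries: Sequence[MiRNAPairingSummary],
    target_class: str = "circRNA",
    regions: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Per-quartile proportion of miRNAs with >= 1 TDMD-like site.

    ``target_class`` selects the site pool: circular targets, all
    linear targets, or linear targets annotated as 3'UTR in
    ``regions`` (target id -> region label) for the sensitivity
    variant.  Denominators are quartile sizes; a miRNA with many
    TDMD-like sites counts once.
    """
    if target_class not in TARGET_CLASSES:
        raise ParameterError(f"unknown target class {target_class!r}")
    if target_class == "linear_3UTR_only" and regions is None:
        raise ParameterError("linear_3UTR_only requires a target-region mapping")

    def in_pool(s: SiteMatch) -> bool:
        if target_class == "circRNA":
            return s.target_topology == "circular"
        if s.target_topology != "linear":
            return False
        if target_class == "linearRNA":
            return True
        return regions.get(s.target_id) == "3UTR"

    with_tdmd = {
        s.mirna_id for s in sites if s.architecture == "TDMD-like" and in_pool(s)
    }
    results = []
    for q in (1, 2, 3, 4):
        members = [s.mirna_id for s in summaries if s.quartile == q]
        hits = sum(1 for m in members if m in with_tdmd)
        prop = hits / len(members) if members else float("nan")
        results.append(
            EnrichmentResult(
                quartile=q,
                target_class=target_class,
                n_with_tdmd=hits,
                n_total=len(members),
                proportion=prop,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Fisher's exact test vs the least-paired quartile
# ---------------------------------------------------------------------------

def fisher_one_sided(a: int, b: int, c: int, d: int, alternative: str = "greater") -> float:
    """Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Rows are (group, reference); columns are (with TDMD, without).
    ``greater`` tests enrichment of the first row.
    """
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(p)


def fisher_enrichment(
    results: Sequence[EnrichmentResult],
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Add Fisher's exact test of each quartile vs the least paired.

    The least-paired quartile ('- paired') is the reference and gets
    ``p = 1`` by convention.  Zero-margin tables get ``p = 1`` with an
    undefined (NaN) odds ratio.
    """
    by_q = {r.quartile: r for r in results}
    if 1 not in by_q:
        raise InputError("reference quartile 1 missing from results")
    populated = [r for r in results if r.n_total >= 1]
    if len(populated) < 2:
        raise InputError("need >= 2 quartiles with members for enrichment tests")
    ref = by_q[1]
    out = []
    for r in results:
        if r.quartile == 1:
            out.append(
                EnrichmentResult(
                    r.quartile, r.target_class, r.n_with_tdmd, r.n_total,
                    r.proportion, odds_ratio=1.0, p_value=1.0,
                )
            )
            continue
        a, b = r.n_with_tdmd, r.n_total - r.n_with_tdmd
        c, d = ref.n_with_tdmd, ref.n_total - ref.n_with_tdmd
        col1, col2 = a + c, b + d
        if col1 == 0 or col2 == 0 or r.n_total == 0 or ref.n_total == 0:
            p, orr = 1.0, float("nan")
            logger.info(
                "fisher_enrichment: zero-margin table for quartile %d, odds ratio undefined",
                r.quartile,
            )
        else:
            p = fisher_one_sided(a, b, c, d, alternative=alternative)
            orr = (a * d) / (b * c) if b * c > 0 else float("inf")
        out.append(
            EnrichmentResult(
                r.quartile, r.target_class, r.n_with_tdmd, r.n_total,
                r.proportion, odds_ratio=orr, p_value=p,
            )
        )
    return out
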