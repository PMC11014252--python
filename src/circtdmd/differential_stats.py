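"""Fold-change computation and quartile-stratified comparisons.

The central question these statistics address: changes in mature miRNA
abundance across differentiation largely track changes in transcription
(pri-miRNA fold changes as the proxy), but for the most highly
circRNA-paired miRNAs the mature~pri correlation weakens — the
signature of a post-transcriptional effect acting in parallel to
transcription.  The complementary circRNA-side check asks whether
circRNA fold changes depend on their miRNA pairing load (they should
not, if circRNAs escape miRNA-directed degradation).

Group comparisons use field-standard conventions: pairwise Wilcoxon
rank-sum tests against a reference group with Hochberg correction, or a
linear-model fit with treatment contrasts against the reference (the
GLM-with-contrasts analog).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import InputError, ParameterError, ValidationError, logger
from .pairing_metrics import MiRNAPairingSummary, CircLoadSummary, assign_quartile_labels


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeRecord:
    feature_id: str
    feature_class: str
    log2fc: float
    mean_abundance: float


@dataclass
class QuartileCorrelation:
    quartile: int
    n: int
    rho: float          # NaN when n < 3
    p_value: float
    method: str


@dataclass
class GroupCompareResult:
    group: str
    statistic: float    # rank-sum U or model coefficient
    p_value: float
    p_adjusted: float


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def log2_fold_change(pre: float, post: float, pseudocount: float = 1.0) -> float:
    """log2((post + pseudocount) / (pre + pseudocount))."""
    if pre < 0 or post < 0:
        raise ValidationError("abundances must be >= 0")
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    if pseudocount == 0 and (pre == 0 or post == 0):
        raise ValidationError(
            "fold change undefined with zero abundance and zero pseudocount"
        )
    return math.log2((post + pseudocount) / (pre + pseudocount))


def fold_changes_from_table(df, pseudocount: float = 1.0) -> list[FoldChangeRecord]:
    """Per-feature log2 fold changes from a canonical expression frame."""
    return [
        FoldChangeRecord(
            feature_id=row.feature_id,
            feature_class=row.feature_class,
            log2fc=log2_fold_change(row.abundance_pre, row.abundance_post, pseudocount),
            mean_abundance=(row.abundance_pre + row.abundance_post) / 2.0,
        )
        for row in df.itertuples(index=False)
    ]


def aggregate_pri_counts(pri_df, mapping: Mapping[str, str] | None = None):
    """Sum pri-miRNA counts mapping to the same mature miRNA.

    ``mapping`` takes pri-transcript ids to mature miRNA ids (identity
    by default); miRNAs expressed from several loci use the summed
    precursor counts as their transcription proxy.
    """
    df = pri_df.copy()
    ids = df["feature_id"].map(lambda x: (mapping or {}).get(x, x))
    df["feature_id"] = ids
    agg = df.groupby("feature_id", as_index=False, sort=True).agg(
        feature_class=("feature_class", "first"),
        abundance_pre=("abundance_pre", "sum"),
        abundance_post=("abundance_post", "sum"),
    )
    return agg[["feature_id", "feature_class", "abundance_pre", "abundance_post"]]


# ---------------------------------------------------------------------------
# Quartile-stratified correlation
# ---------------------------------------------------------------------------

def correlate_by_quartile(
    mirna_fc: Sequence[FoldChangeRecord],
    pri_fc: Sequence[FoldChangeRecord],
    summaries: Sequence[MiRNAPairingSummary],
    method: str = "spearman",
) -> list[QuartileCorrelation]:
    """Mature-vs-pri fold-change correlation within each pairing quartile.

    Records are matched by miRNA id (aggregate multi-locus pri counts
    with :func:`aggregate_pri_counts` upstream).  Quartiles with fewer
    than 3 matched pairs are reported with ``rho = NaN``.
    """
    if method not in ("spearman", "pearson"):
        raise ParameterError(f"unknown correlation method {method!r}")
    pri_by_id = {r.feature_id: r for r in pri_fc}
    quart_by_id = {s.mirna_id: s.quartile for s in summaries if s.quartile is not None}
    pairs: dict[int, list[tuple[float, float]]] = {q: [] for q in (1, 2, 3, 4)}
    n_matched = 0
    for rec in mirna_fc:
        pri = pri_by_id.get(rec.feature_id)
        q = quart_by_id.get(rec.feature_id)
        if pri is None or q is None:
            continue
        pairs[q].append((rec.log2fc, pri.log2fc))
        n_matched += 1
    if n_matched == 0:
        raise InputError("no mature/pri miRNA pairs matched by id")
    out = []
    for q in (1, 2, 3, 4):
        xy = pairs[q]
        if len(xy) < 3:
            logger.info("quartile %d has %d matched pairs (<3): reported missing", q, len(xy))
            out.append(QuartileCorrelation(q, len(xy), float("nan"), float("nan"), method))
            continue
        x = np.array([a for a, _ in xy])
        y = np.array([b for _, b in xy])
        if method == "spearman":
            rho, p = stats.spearmanr(x, y)
        else:
            rho, p = stats.pearsonr(x, y)
        out.append(QuartileCorrelation(q, len(xy), float(rho), float(p), method))
    return out


def correlation_attenuation_test(
    rho_ref: float, n_ref: int, rho_other: float, n_other: int,
    method: str = "spearman",
) -> float:
    """One-sided p-value that ``rho_other`` is smaller than ``rho_ref``.

    Independent-samples comparison of two correlation coefficients via
    Fisher's z transform.  The sampling variance of atanh(r) is
    1/(n-3) for Pearson's r and approximately 1.06/(n-3) for
    Spearman's rho (Fieller's correction).
    """
    if n_ref < 4 or n_other < 4:
        raise ParameterError("need n >= 4 in both groups to compare correlations")
    var_factor = 1.06 if method == "spearman" else 1.0
    z1 = math.atanh(max(-0.999999, min(0.999999, rho_ref)))
    z2 = math.atanh(max(-0.999999, min(0.999999, rho_other)))
    se = math.sqrt(var_factor / (n_ref - 3) + var_factor / (n_other - 3))
    z = (z1 - z2) / se
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    reference: str,
    method: str = "wilcoxon_hochberg",
) -> list[GroupCompareResult]:
    """Compare every group against a reference group.

    ``wilcoxon_hochberg``: two-sided Wilcoxon rank-sum (Mann-Whitney U)
    test of each group versus the reference, Hochberg-adjusted across
    groups.  ``lm_contrasts``: a single linear model of value on group
    with treatment contrasts against the reference; both raw and
    Hochberg-adjusted contrast p-values are reported.
    """
    if reference not in values_by_group:
        raise InputError(f"reference group {reference!r} not present")
    if len(values_by_group) < 2:
        raise InputError("need at least 2 groups")
    for g, vals in values_by_group.items():
        if len(vals) == 0:
            raise InputError(f"group {g!r} is empty")
    others = [g for g in values_by_group if g != reference]
    ref_vals = np.asarray(values_by_group[reference], dtype=float)

    if method == "wilcoxon_hochberg":
        stats_, pvals = [], []
        for g in others:
            vals = np.asarray(values_by_group[g], dtype=float)
            res = stats.mannwhitneyu(vals, ref_vals, alternative="two-sided")
            stats_.append(float(res.statistic))
            pvals.append(float(res.pvalue))
    elif method == "lm_contrasts":
        import statsmodels.api as sm

        y, x = [], []
        levels = [reference] + others
        for g in levels:
            for v in values_by_group[g]:
                y.append(float(v))
                x.append(g)
        design = np.zeros((len(y), len(levels)))
        design[:, 0] = 1.0  # intercept = reference mean
        for i, g in enumerate(x):
            if g != reference:
                design[i, levels.index(g)] = 1.0
        fit = sm.OLS(np.asarray(y), design).fit()
        stats_ = [float(fit.params[i]) for i in range(1, len(levels))]
        pvals = [float(fit.pvalues[i]) for i in range(1, len(levels))]
    else:
        raise ParameterError(f"unknown method {method!r}")

    adjusted = multipletests(pvals, method="simes-hochberg")[1] if pvals else []
    return [
        GroupCompareResult(group=g, statistic=s, p_value=p, p_adjusted=float(pa))
        for g, s, p, pa in zip(others, stats_, pvals, adjusted)
    ]


def circ_fc_by_load(
    circ_fc: Sequence[FoldChangeRecord],
    loads: Sequence[CircLoadSummary],
    method: str = "lm_contrasts",
) -> list[GroupCompareResult]:
    """circRNA fold changes across pairing-load quartiles vs the least loaded.

    Load quartiles follow the same empirical-percentile rule as the
    miRNA pairing quartiles.  An empty quartile (degenerate tied loads)
    is an input error.
    """
    fc_by_id = {r.feature_id: r.log2fc for r in circ_fc}
    usable = [l for l in loads if l.circ_id in fc_by_id]
    if len(usable) < 4:
        raise InputError("need >= 4 circRNAs with both load and fold change")
    quartiles = assign_quartile_labels([l.load_index for l in usable])
    groups: dict[str, list[float]] = {f"Q{q}": [] for q in (1, 2, 3, 4)}
    for load, q in zip(usable, quartiles):
        groups[f"Q{q}"].append(fc_by_id[load.circ_id])
    empty = [g for g, vals in groups.items() if not vals]
    if empty:
        raise InputError(f"empty load quartile(s): {empty}")
    return group_compare(groups, reference="Q1", method=method)
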