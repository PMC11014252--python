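"""Synthetic fixtures emulating real circRNA-miRNA datasets.

Generates complete datasets with the statistical shape of the real
sources: mature miRNA sequences with two-condition abundances and
pri-miRNA counts, circRNA records with genomic spans, overdispersed
(negative-binomial) backsplice-junction reads and backspliced sequences
carrying planted miRNA sites of controlled architecture, linear mRNA
targets, and ENCORI-like interaction tables with CLIP/program evidence
columns plus sub-threshold decoy records.

The generative model for expression outcomes is the minimal one
consistent with a post-transcriptional stabilization effect acting in
parallel to transcription: pri-miRNA log2 fold changes are drawn from a
shared transcription law, and mature fold changes add a stabilization
term ``beta * z`` where ``z`` is the miRNA's standardized pairing
coefficient, plus independent noise.  circRNA fold changes are drawn
independently of their miRNA load (the null the circRNA-side analysis
is expected to report).

Every planted structure is recorded in a truth table so downstream
stages can be checked for exact recovery; plantings are locally
verified at generation time so the truth labels are unambiguous.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ParameterError,
    PipelineError,
    RunConfig,
    logger,
    write_expression_table,
    write_fasta,
    write_interaction_table,
)
from .pairing_metrics import (
    InteractionRecord,
    assign_quartiles,
    filter_interactions,
    join_sites_to_circrnas,
    summarize_mirna_pairing,
)
from .site_scanner import (
    CircRNARecord,
    MiRNARecord,
    align_3prime,
    circularize_sequence,
    classify_architecture,
    find_seed_matches,
    reverse_complement,
    site_footprint,
    SiteMatch,
)

_NTS = "ACGU"
TIERS = ("low", "mid", "high")
PLANT_ARCHITECTURES = ("canonical", "TDMD-like", "slicing", "seed_mutant")


class GenerationError(PipelineError):
    """The generator could not satisfy a structural constraint."""


# ---------------------------------------------------------------------------
# Simulation model
# ---------------------------------------------------------------------------

def _default_site_plan() -> dict:
    # expected planted sites per miRNA on circRNAs by pairing tier, for the
    # architecture-specific channels; the canonical channel is driven by the
    # continuous per-miRNA pairing propensity instead
    return {
        "low": {"TDMD-like": 0.08, "slicing": 0.02, "seed_mutant": 0.1},
        "mid": {"TDMD-like": 0.3, "slicing": 0.05, "seed_mutant": 0.1},
        "high": {"TDMD-like": 1.2, "slicing": 0.1, "seed_mutant": 0.1},
    }


def _default_linear_plan() -> dict:
    # expected planted sites per miRNA on linear mRNAs (tier-independent)
    return {"canonical": 1.0, "TDMD-like": 0.25, "slicing": 0.02, "seed_mutant": 0.1}


@dataclass
class SimulationModel:
    """Parameters of the synthetic cohort.

    Sizes default to a realistic cohort scale (236 analyzed miRNAs,
    dozens-to-hundreds of circRNAs).  Abundances are log-normal; junction reads are
    negative-binomial (overdispersed counts).  ``beta`` is the added
    mature-miRNA log2 fold change per standard deviation of pairing
    coefficient (0 = no post-transcriptional effect).
    """

    n_mirnas: int = 236
    n_circrnas: int = 120
    n_mrnas: int = 100
    mirna_length: int = 22
    # ln-scale (mu, sigma) abundance laws
    mirna_abundance: tuple[float, float] = (5.0, 1.2)
    pri_abundance: tuple[float, float] = (3.5, 1.0)
    mrna_abundance: tuple[float, float] = (3.5, 1.0)
    # junction reads: negative binomial mean / dispersion (size)
    junction_mean: float = 8.0
    junction_dispersion: float = 2.0
    # target lengths
    circ_length: tuple[float, float] = (6.3, 0.35)   # ln-scale, median ~545 nt
    min_circ_length: int = 150
    mrna_length: int = 500
    # per-miRNA pairing propensity (expected canonical circRNA sites),
    # ln-scale (mu, sigma): continuous and heavy-tailed like the degree
    # distribution of CLIP-supported interaction networks
    propensity: tuple[float, float] = (0.69, 1.0)
    # pairing-tier fractions (low, mid, high) over propensity quantiles,
    # and the tier-targeted architecture-planting plan
    tier_fractions: tuple[float, float, float] = (0.25, 0.5, 0.25)
    site_plan: dict = field(default_factory=_default_site_plan)
    linear_plan: dict = field(default_factory=_default_linear_plan)
    junction_span_prob: float = 0.3
    # expression-outcome model
    beta: float = 0.6
    transcription_fc: tuple[float, float] = (0.0, 1.0)  # mu, sd of pri log2fc
    noise_sd: float = 0.25
    circ_fc_sd: float = 0.5
    mrna_fc_sd: float = 1.0
    # plumbing
    plant_sequences: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 4:
            raise ParameterError("need at least 4 miRNAs")
        for tier in TIERS:
            for arch, rate in self.site_plan[tier].items():
                if rate < 0:
                    raise ParameterError(f"negative planting rate for {tier}/{arch}")
        if abs(sum(self.tier_fractions) - 1.0) > 1e-9:
            raise ParameterError("tier fractions must sum to 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PlantedSite:
    """Truth record for one planted site."""

    mirna_id: str
    target_id: str
    target_topology: str
    offset: int          # t1 position in target coordinates
    architecture: str
    spans_junction: bool = False
    planted: bool = True  # False: incidental chance site recorded for inventory


@dataclass
class Dataset:
    """One complete synthetic cohort held in memory."""

    model: SimulationModel
    mirnas: list[MiRNARecord]
    tiers: dict[str, str]                 # mirna_id -> tier
    pri_pre: dict[str, float]             # mirna_id -> pri-miRNA pre-abundance
    circrnas: list[CircRNARecord]
    linear_targets: list[tuple[str, str, str]]   # (id, seq, "linear")
    linear_regions: dict[str, str]               # target id -> 5UTR/CDS/3UTR
    linear_abundance: dict[str, float]
    propensity: dict[str, float] = field(default_factory=dict)
    interactions: list[InteractionRecord] = field(default_factory=list)
    truth_sites: list[PlantedSite] = field(default_factory=list)
    expression: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth_beta: float = 0.0

    def targets(self) -> list[tuple[str, str, str]]:
        """All scan targets, circular first, in generation order."""
        circ = [
            (c.id, c.sequence, "circular")
            for c in self.circrnas
            if c.sequence is not None
        ]
        return circ + list(self.linear_targets)


# ---------------------------------------------------------------------------
# miRNAs
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NTS[i] for i in rng.integers(0, 4, size=n))


def gen_mirnas(
    model: SimulationModel, rng: np.random.Generator
) -> tuple[list[MiRNARecord], dict[str, float], dict[str, str], dict[str, float]]:
    """Random miRNA cohort with unique seeds and log-normal abundances.

    Returns (records, pri-miRNA pre-abundances, tier labels, pairing
    propensities).  Both the seed (positions 2-8) and the scanner core
    (positions 2-7) are kept pairwise distinct so planted sites are
    attributable to one miRNA.  Tiers are quantile bins of the
    continuous pairing propensity (bottom / middle / top fractions).
    """
    mu, sigma = model.mirna_abundance
    pmu, psigma = model.pri_abundance
    seen_seeds: set[str] = set()
    seen_cores: set[str] = set()
    mirnas: list[MiRNARecord] = []
    pri_pre: dict[str, float] = {}
    width = len(str(model.n_mirnas))
    for i in range(model.n_mirnas):
        for attempt in range(1000):
            seq = _random_seq(rng, model.mirna_length)
            if seq[1:8] not in seen_seeds and seq[1:7] not in seen_cores:
                break
        else:
            raise GenerationError("could not draw a miRNA with a unique seed")
        seen_seeds.add(seq[1:8])
        seen_cores.add(seq[1:7])
        mid = f"mir-{i + 1:0{width}d}"
        ab = float(rng.lognormal(mu, sigma))
        mirnas.append(
            MiRNARecord(id=mid, sequence=seq, abundance_pre=ab, abundance_post=ab)
        )
        pri_pre[mid] = float(rng.lognormal(pmu, psigma))
    lam_mu, lam_sigma = model.propensity
    propensity = {
        m.id: float(rng.lognormal(lam_mu, lam_sigma)) for m in mirnas
    }
    n_low = int(round(model.tier_fractions[0] * model.n_mirnas))
    n_high = int(round(model.tier_fractions[2] * model.n_mirnas))
    by_propensity = sorted(propensity, key=lambda mid: (propensity[mid], mid))
    tiers: dict[str, str] = {}
    for rank, mid in enumerate(by_propensity):
        if rank < n_low:
            tiers[mid] = "low"
        elif rank >= model.n_mirnas - n_high:
            tiers[mid] = "high"
        else:
            tiers[mid] = "mid"
    return mirnas, pri_pre, tiers, propensity


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------

def plant_site(
    target_seq: str,
    mirna: MiRNARecord,
    architecture: str,
    position: int,
    rng: np.random.Generator,
    bulge_len: int = 3,
    n_mismatches: int | None = None,
    circular: bool = False,
) -> tuple[str, int]:
    """Write one binding site of the given architecture into a target.

    ``position`` is the 5' end of the written footprint in target
    coordinates (taken modulo the length for circular targets, so sites
    may span the backsplice junction).  Returns ``(mutated sequence,
    t1 offset)`` where the t1 offset is the target position opposite
    miRNA position 1.

    Constructions, all target-sense 5'->3' over the reverse complement
    ``rc`` of the miRNA: ``slicing`` writes ``rc`` verbatim;
    ``TDMD-like`` inserts a ``bulge_len``-nt random loop between the
    nucleotides opposite positions 9 and 8 and applies up to
    ``n_mismatches`` substitutions opposite positions 13-15 (keeping a
    long contiguous paired run 3' of them); ``canonical`` keeps the
    seed-region complement and randomizes the rest; ``seed_mutant``
    disrupts the seed complement at three positions.
    """
    if architecture not in PLANT_ARCHITECTURES:
        raise ParameterError(f"unknown architecture {architecture!r}")
    m = mirna.sequence
    n = len(m)
    rc = reverse_complement(m)  # rc[i] faces miRNA position n - i
    if architecture == "slicing":
        site = rc
    elif architecture == "TDMD-like":
        if not 1 <= bulge_len <= 5:
            raise ParameterError("TDMD-like bulge length must be in 1..5")
        loop = _random_seq(rng, bulge_len)
        chars = list(rc[: n - 8] + loop + rc[n - 8 :])
        nm = int(rng.integers(0, 4)) if n_mismatches is None else n_mismatches
        for k in (13, 14, 15)[:nm]:
            idx = n - k  # rc index facing miRNA position k (before the loop point)
            comp = rc[idx]
            choices = [c for c in _NTS if c != comp]
            chars[idx] = choices[int(rng.integers(0, 3))]
        site = "".join(chars)
    elif architecture == "canonical":
        site = _random_seq(rng, n - 8) + rc[n - 8 :]
    else:  # seed_mutant
        chars = list(rc)
        for k in (3, 4, 5):  # disrupt complements of seed positions 3..5
            idx = n - k
            comp = rc[idx]
            choices = [c for c in _NTS if c != comp]
            chars[idx] = choices[int(rng.integers(0, 3))]
        site = "".join(chars)

    L = len(target_seq)
    if circular:
        if len(site) > L:
            raise ParameterError("site footprint exceeds circular target length")
        chars = list(target_seq)
        for i, ch in enumerate(site):
            chars[(position + i) % L] = ch
        t1 = (position + len(site) - 1) % L
        return "".join(chars), t1
    if position < 0 or position + len(site) > L:
        raise ParameterError("site footprint exceeds linear target bounds")
    new = target_seq[:position] + site + target_seq[position + len(site) :]
    return new, position + len(site) - 1


def _verify_planted(
    seq: str,
    topology: str,
    mirna: MiRNARecord,
    t1: int,
    config: RunConfig,
) -> str | None:
    """Architecture the scanner would assign at a planted locus (or None)."""
    if topology == "circular":
        L = len(seq)
        window = min(site_footprint(len(mirna.sequence), config.bulge_max), L)
        ext = circularize_sequence(seq, window)
        q = t1 + L if t1 + L < len(ext) else t1
    else:
        ext, q = seq, t1
    for off, seed_class in find_seed_matches(ext, mirna, config.min_seed_class):
        if off != q:
            continue
        aln = align_3prime(ext, q, mirna, config.bulge_max, config.gu_wobble)
        probe = SiteMatch(
            mirna_id=mirna.id,
            target_id="",
            target_topology=topology,
            offset=t1,
            seed_class=seed_class,
            paired_3p=aln.paired_3p,
            mismatches_3p=aln.mismatches_3p,
            bulge_len=aln.bulge_len,
            paired_run_3p=aln.paired_run_3p,
            mirna_length=len(mirna.sequence),
        )
        return classify_architecture(probe, config)
    return None


# ---------------------------------------------------------------------------
# Targets with planted sites
# ---------------------------------------------------------------------------

def _overlaps(
    occupied: list[tuple[int, int]], start: int, length: int, L: int, circular: bool
) -> bool:
    if circular:
        span = {(start + i) % L for i in range(length)}
        for s, l in occupied:
            if span & {(s + i) % L for i in range(l)}:
                return True
        return False
    start = max(0, start)
    end = start + length
    return any(s < end and start < s + l for s, l in occupied)


class _Planter:
    """Places non-overlapping sites into a pool of target sequences."""

    def __init__(self, targets: dict[str, str], topology: str, config: RunConfig):
        self.seqs = dict(targets)
        self.topology = topology
        self.config = config
        self.occupied: dict[str, list[tuple[int, int]]] = {t: [] for t in targets}
        self.planted: list[PlantedSite] = []

    def try_plant(
        self,
        mirna: MiRNARecord,
        architecture: str,
        rng: np.random.Generator,
        span_junction: bool = False,
        max_attempts: int = 12,
    ) -> PlantedSite | None:
        ids = sorted(self.seqs)
        footprint = len(mirna.sequence) + (5 if architecture == "TDMD-like" else 0)
        circular = self.topology == "circular"
        for _ in range(max_attempts):
            tid = ids[int(rng.integers(0, len(ids)))]
            seq = self.seqs[tid]
            L = len(seq)
            if footprint > L:
                continue
            if circular and span_junction:
                pos = int(L - rng.integers(1, footprint))
            elif circular:
                pos = int(rng.integers(0, L))
            else:
                pos = int(rng.integers(0, L - footprint + 1))
            bulge = int(rng.integers(1, 6)) if architecture == "TDMD-like" else 3
            length = len(mirna.sequence) + (bulge if architecture == "TDMD-like" else 0)
            # reserve the worst-case alignment context (max bulge) upstream of
            # the written site so later plantings cannot change this site's
            # 3'-pairing geometry after it has been verified
            pad = self.config.bulge_max - (bulge if architecture == "TDMD-like" else 0)
            if _overlaps(self.occupied[tid], pos - pad, length + pad, L, circular):
                continue
            new_seq, t1 = plant_site(
                seq, mirna, architecture, pos, rng, bulge_len=bulge, circular=circular
            )
            if architecture == "seed_mutant":
                got = _verify_planted(new_seq, self.topology, mirna, t1, self.config)
                ok = got is None
            else:
                got = _verify_planted(new_seq, self.topology, mirna, t1, self.config)
                ok = got == architecture
            if not ok:
                continue  # ambiguous flank context: redraw position/randomness
            self.seqs[tid] = new_seq
            self.occupied[tid].append(((pos - pad) % L if circular else max(0, pos - pad), length + pad))
            crosses = circular and pos + length > L
            rec = PlantedSite(
                mirna_id=mirna.id,
                target_id=tid,
                target_topology=self.topology,
                offset=t1,
                architecture=architecture,
                spans_junction=crosses,
            )
            self.planted.append(rec)
            return rec
        return None


def gen_circrnas(
    model: SimulationModel,
    mirnas: list[MiRNARecord],
    tiers: dict[str, str],
    propensity: dict[str, float],
    rng: np.random.Generator,
    config: RunConfig | None = None,
) -> tuple[list[CircRNARecord], list[InteractionRecord], list[PlantedSite]]:
    """circRNA cohort with planted sites and an ENCORI-like interaction table.

    Every planted (non-seed-mutant) site yields one interaction record
    with genomic coordinates inside the circRNA span and evidence counts
    at or above the validation thresholds; sub-threshold decoy records
    are always added so the interaction filter is exercised.
    """
    cfg = config or RunConfig()
    chroms = ["chrS1", "chrS2", "chrS3", "chrS4"]
    regions = ["5UTR", "CDS", "3UTR", "mixed"]
    region_w = np.array([0.1, 0.45, 0.35, 0.1])
    lmu, lsigma = model.circ_length
    nb_n = model.junction_dispersion
    nb_p = nb_n / (nb_n + model.junction_mean)
    circs: list[CircRNARecord] = []
    width = len(str(model.n_circrnas))
    cursor = {ch: 1000 for ch in chroms}
    for i in range(model.n_circrnas):
        L = max(model.min_circ_length, int(rng.lognormal(lmu, lsigma)))
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor[chrom]
        cursor[chrom] = start + L + int(rng.integers(500, 5000))
        seq = _random_seq(rng, L) if model.plant_sequences else None
        reads = float(rng.negative_binomial(nb_n, nb_p))
        region = regions[int(rng.choice(len(regions), p=region_w / region_w.sum()))]
        circs.append(
            CircRNARecord(
                id=f"circ-{i + 1:0{width}d}",
                chrom=chrom,
                start=start,
                end=start + L,
                strand=strand,
                junction_reads_pre=reads,
                junction_reads_post=reads,  # post rewritten by the outcome model
                sequence=seq,
                region_of_origin=region,
                host_gene=f"HOST{i + 1}",
            )
        )
    circ_by_id = {c.id: c for c in circs}

    interactions: list[InteractionRecord] = []
    truth: list[PlantedSite] = []

    def emit_interaction(mirna_id: str, circ: CircRNARecord, seq_pos: int) -> None:
        g0 = circ.start + (seq_pos % (circ.end - circ.start))
        gstart = min(g0, circ.end - 8)
        interactions.append(
            InteractionRecord(
                mirna_id=mirna_id,
                target_id=circ.id,
                target_class="circRNA",
                chrom=circ.chrom,
                site_start=gstart,
                site_end=gstart + 8,
                strand=circ.strand,
                clip_experiments=1 + int(rng.poisson(1.5)),
                supporting_programs=2 + int(rng.poisson(1.5)),
            )
        )

    if model.plant_sequences:
        planter = _Planter({c.id: c.sequence for c in circs}, "circular", cfg)
        for mir in mirnas:
            plan = {"canonical": propensity[mir.id], **model.site_plan[tiers[mir.id]]}
            for arch in PLANT_ARCHITECTURES:
                k = int(rng.poisson(plan.get(arch, 0.0)))
                for _ in range(k):
                    span_j = bool(rng.random() < model.junction_span_prob)
                    rec = planter.try_plant(mir, arch, rng, span_junction=span_j)
                    if rec is None:
                        continue
                    truth.append(rec)
                    if arch != "seed_mutant":
                        emit_interaction(mir.id, circ_by_id[rec.target_id], rec.offset)
        for c in circs:
            c.sequence = planter.seqs[c.id]
    else:
        # counts-only mode: same planting statistics, no sequence work
        ids = [c.id for c in circs]
        for mir in mirnas:
            plan = {"canonical": propensity[mir.id], **model.site_plan[tiers[mir.id]]}
            for arch in PLANT_ARCHITECTURES:
                k = int(rng.poisson(plan.get(arch, 0.0)))
                for _ in range(k):
                    circ = circ_by_id[ids[int(rng.integers(0, len(ids)))]]
                    pos = int(rng.integers(0, circ.end - circ.start))
                    truth.append(
                        PlantedSite(mir.id, circ.id, "circular", pos, arch)
                    )
                    if arch != "seed_mutant":
                        emit_interaction(mir.id, circ, pos)

    # sub-threshold decoys: wrong evidence counts, otherwise plausible
    n_decoys = max(5, len(interactions) // 3)
    mir_ids = [m.id for m in mirnas]
    for _ in range(n_decoys):
        circ = circs[int(rng.integers(0, len(circs)))]
        gstart = circ.start + int(rng.integers(0, max(1, circ.end - circ.start - 8)))
        if rng.random() < 0.5:
            clip, prog = 0, 2 + int(rng.poisson(2.0))
        else:
            clip, prog = 1 + int(rng.poisson(1.0)), int(rng.integers(0, 2))
        interactions.append(
            InteractionRecord(
                mirna_id=mir_ids[int(rng.integers(0, len(mir_ids)))],
                target_id=circ.id,
                target_class="circRNA",
                chrom=circ.chrom,
                site_start=gstart,
                site_end=gstart + 8,
                strand=circ.strand,
                clip_experiments=clip,
                supporting_programs=prog,
            )
        )
    return circs, interactions, truth


def gen_linear_targets(
    model: SimulationModel,
    mirnas: list[MiRNARecord],
    tiers: dict[str, str],
    rng: np.random.Generator,
    config: RunConfig | None = None,
) -> tuple[list[tuple[str, str, str]], dict[str, str], dict[str, float], list[PlantedSite]]:
    """Linear mRNA segments (5'UTR / CDS / 3'UTR) with planted sites."""
    cfg = config or RunConfig()
    if model.n_mrnas == 0 or not model.plant_sequences:
        return [], {}, {}, []
    regions = ["5UTR", "CDS", "3UTR"]
    region_w = [0.2, 0.4, 0.4]
    amu, asigma = model.mrna_abundance
    targets: dict[str, str] = {}
    region_of: dict[str, str] = {}
    abundance: dict[str, float] = {}
    width = len(str(model.n_mrnas))
    for i in range(model.n_mrnas):
        tid = f"mrna-{i + 1:0{width}d}"
        targets[tid] = _random_seq(rng, model.mrna_length)
        region_of[tid] = regions[int(rng.choice(3, p=region_w))]
        abundance[tid] = float(rng.lognormal(amu, asigma))
    planter = _Planter(targets, "linear", cfg)
    truth: list[PlantedSite] = []
    for mir in mirnas:
        for arch in PLANT_ARCHITECTURES:
            k = int(rng.poisson(model.linear_plan.get(arch, 0.0)))
            for _ in range(k):
                rec = planter.try_plant(mir, arch, rng)
                if rec is not None:
                    truth.append(rec)
    out = [(tid, planter.seqs[tid], "linear") for tid in sorted(targets)]
    return out, region_of, abundance, truth


def _screen_chance_architectures(
    ds: Dataset, cfg: RunConfig, rng: np.random.Generator, max_rounds: int = 5
) -> None:
    """Disrupt chance TDMD/slicing architectures arising from background.

    Random background (and juxtaposition of planted windows belonging to
    different miRNAs) occasionally produces an unplanted site with
    TDMD-like geometry.  So that the truth table is the complete
    inventory of high-architecture sites, such chance sites are broken
    by a single seed-core substitution at a position outside every
    reserved planted-site window, then the screen repeats.
    """
    from .site_scanner import scan_pairs  # deferred: keeps module import acyclic

    truth = {
        (t.mirna_id, t.target_id, t.offset): t.architecture for t in ds.truth_sites
    }
    footprint = site_footprint(ds.model.mirna_length, cfg.bulge_max)
    reserved: dict[str, set[int]] = {}
    lengths = {c.id: len(c.sequence) for c in ds.circrnas if c.sequence}
    lengths.update({tid: len(seq) for tid, seq, _ in ds.linear_targets})
    for t in ds.truth_sites:
        L = lengths[t.target_id]
        res = reserved.setdefault(t.target_id, set())
        for i in range(footprint):
            p = t.offset - i
            res.add(p % L if t.target_topology == "circular" else p)
    mir_by_id = {m.id: m for m in ds.mirnas}

    def current_targets() -> list[tuple[str, str, str]]:
        return ds.targets()

    seqs = {tid: seq for tid, seq, _ in current_targets()}
    topo = {tid: t for tid, _, t in current_targets()}
    for _ in range(max_rounds):
        targets = [(tid, seqs[tid], topo[tid]) for tid in sorted(seqs)]
        sites = scan_pairs(targets, ds.mirnas, cfg)
        chance = [
            s
            for s in sites
            if s.architecture in ("TDMD-like", "slicing")
            and truth.get((s.mirna_id, s.target_id, s.offset)) != s.architecture
        ]
        if not chance:
            break
        for s in chance:
            L = lengths[s.target_id]
            res = reserved.get(s.target_id, set())
            seq = list(seqs[s.target_id])
            mir = mir_by_id[s.mirna_id]
            edited = False
            for k in range(2, 8):  # core positions facing miRNA 2..7
                p = s.offset - (k - 1)
                p = p % L if topo[s.target_id] == "circular" else p
                if p < 0 or p >= L or p in res:
                    continue
                comp = reverse_complement(mir.sequence[k - 1])
                choices = [c for c in _NTS if c != seq[p] and c != comp]
                seq[p] = choices[int(rng.integers(0, len(choices)))]
                seqs[s.target_id] = "".join(seq)
                edited = True
                break
            if not edited:
                # the chance site's seed core lies wholly inside reserved
                # windows: record it in the truth inventory instead
                logger.info(
                    "recording incidental %s site for %s on %s at %d",
                    s.architecture, s.mirna_id, s.target_id, s.offset,
                )
                rec = PlantedSite(
                    mirna_id=s.mirna_id,
                    target_id=s.target_id,
                    target_topology=s.target_topology,
                    offset=s.offset,
                    architecture=s.architecture,
                    planted=False,
                )
                ds.truth_sites.append(rec)
                truth[(s.mirna_id, s.target_id, s.offset)] = s.architecture
    else:
        logger.warning("chance-architecture screen did not converge")
    for c in ds.circrnas:
        if c.sequence is not None:
            c.sequence = seqs[c.id]
    ds.linear_targets = [
        (tid, seqs[tid], "linear") for tid, _, _ in ds.linear_targets
    ]


# ---------------------------------------------------------------------------
# Expression outcome
# ---------------------------------------------------------------------------

def gen_expression_outcome(
    model: SimulationModel,
    dataset: Dataset,
    summaries,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Draw post-differentiation abundances for every feature class.

    pri-miRNA log2 fold changes follow the transcription law; mature
    fold changes add ``beta`` times the standardized pairing coefficient
    plus noise (the planted stabilization effect); circRNA fold changes
    are independent of load.  Updates the records in ``dataset`` in
    place and returns the four canonical expression frames.
    """
    fmu, fsd = model.transcription_fc
    coef = {s.mirna_id: s.pairing_coefficient for s in summaries}
    vals = np.array([coef.get(m.id, 0.0) for m in dataset.mirnas])
    sd = float(vals.std())
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)

    rows_m, rows_p = [], []
    for m, zi in zip(dataset.mirnas, z):
        pri_fc = float(rng.normal(fmu, fsd))
        mature_fc = pri_fc + model.beta * float(zi) + float(rng.normal(0, model.noise_sd))
        pri_pre = dataset.pri_pre[m.id]
        m.abundance_post = m.abundance_pre * 2.0**mature_fc
        rows_m.append((m.id, "miRNA", m.abundance_pre, m.abundance_post))
        rows_p.append((m.id, "pri-miRNA", pri_pre, pri_pre * 2.0**pri_fc))

    rows_c = []
    for c in dataset.circrnas:
        fc = float(rng.normal(0.0, model.circ_fc_sd))
        c.junction_reads_post = c.junction_reads_pre * 2.0**fc
        rows_c.append((c.id, "circRNA", c.junction_reads_pre, c.junction_reads_post))

    rows_r = []
    for tid in sorted(dataset.linear_abundance):
        pre = dataset.linear_abundance[tid]
        fc = float(rng.normal(0.0, model.mrna_fc_sd))
        rows_r.append((tid, "mRNA", pre, pre * 2.0**fc))

    cols = ["feature_id", "feature_class", "abundance_pre", "abundance_post"]
    frames = {
        "mirna": pd.DataFrame(rows_m, columns=cols),
        "pri_mirna": pd.DataFrame(rows_p, columns=cols),
        "circrna": pd.DataFrame(rows_c, columns=cols),
        "mrna": pd.DataFrame(rows_r, columns=cols),
    }
    dataset.expression = frames
    dataset.truth_beta = model.beta
    return frames


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def generate_dataset(model: SimulationModel, config: RunConfig | None = None) -> Dataset:
    """Generate one full cohort in memory (deterministic per model seed)."""
    cfg = config or RunConfig(seed=model.seed)
    rng = np.random.default_rng(model.seed)
    mirnas, pri_pre, tiers, propensity = gen_mirnas(model, rng)
    circs, interactions, truth_c = gen_circrnas(model, mirnas, tiers, propensity, rng, cfg)
    linear, regions, lin_ab, truth_l = gen_linear_targets(model, mirnas, tiers, rng, cfg)
    ds = Dataset(
        model=model,
        mirnas=mirnas,
        tiers=tiers,
        pri_pre=pri_pre,
        circrnas=circs,
        linear_targets=linear,
        linear_regions=regions,
        linear_abundance=lin_ab,
        propensity=propensity,
        interactions=interactions,
        truth_sites=truth_c + truth_l,
    )
    if model.plant_sequences:
        _screen_chance_architectures(ds, cfg, rng)
    # pairing summaries on the pre-differentiation state drive the
    # planted stabilization effect
    kept = filter_interactions(
        interactions, cfg.min_clip_experiments, cfg.min_programs
    )
    counts = join_sites_to_circrnas(kept, circs)
    summaries = summarize_mirna_pairing(counts, circs, mirnas)
    if len(summaries) >= 4:
        assign_quartiles(summaries)
    gen_expression_outcome(model, ds, summaries, rng)
    return ds


def emit_dataset(model: SimulationModel, outdir: str | Path) -> Dataset:
    """Generate a cohort and write the complete file tree.

    Writes miRNA and target FASTA, a topology/region sidecar, four
    expression TSVs, the circRNA metadata table, the interaction table
    (BED-style coordinates), truth tables (planted sites, tier labels,
    true beta) and the run configuration.  Identical model + seed gives
    byte-identical trees.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(model)

    write_fasta([(m.id, m.sequence) for m in ds.mirnas], outdir / "mirnas.fasta")
    targets = ds.targets()
    if targets:
        write_fasta([(t, s) for t, s, _ in targets], outdir / "targets.fasta")
    with open(outdir / "targets.tsv", "w") as fh:
        fh.write("target_id\ttopology\tregion\n")
        for tid, _, topo in targets:
            region = ds.linear_regions.get(tid, "")
            fh.write(f"{tid}\t{topo}\t{region}\n")

    for name, df in ds.expression.items():
        write_expression_table(df, outdir / f"expression_{name}.tsv")
    write_circrna_table(ds.circrnas, outdir / "circrnas.tsv")
    write_interaction_table(ds.interactions, outdir / "interactions.tsv")

    pd.DataFrame(
        [dataclasses.asdict(t) for t in ds.truth_sites],
        columns=["mirna_id", "target_id", "target_topology", "offset",
                 "architecture", "spans_junction", "planted"],
    ).to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    with open(outdir / "truth_params.json", "w") as fh:
        json.dump(
            {"beta": ds.truth_beta, "tiers": ds.tiers,
             "propensity": ds.propensity, "model": model.to_dict()},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    RunConfig(seed=model.seed).save(outdir / "config.yaml")
    logger.info(
        "emitted synthetic dataset: %d miRNAs, %d circRNAs, %d linear targets, "
        "%d interactions, %d planted sites",
        len(ds.mirnas), len(ds.circrnas), len(ds.linear_targets),
        len(ds.interactions), len(ds.truth_sites),
    )
    return ds


def write_circrna_table(circs: list[CircRNARecord], path: str | Path) -> None:
    rows = [
        {
            "circ_id": c.id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "junction_reads_pre": c.junction_reads_pre,
            "junction_reads_post": c.junction_reads_post,
            "region_of_origin": c.region_of_origin,
            "host_gene": c.host_gene,
        }
        for c in circs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_circrna_table(path: str | Path) -> list[CircRNARecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CircRNARecord(
            id=str(r.circ_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            junction_reads_pre=float(r.junction_reads_pre),
            junction_reads_post=float(r.junction_reads_post),
            region_of_origin=str(r.region_of_origin),
            host_gene=str(r.host_gene),
        )
        for r in df.itertuples(index=False)
    ]
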