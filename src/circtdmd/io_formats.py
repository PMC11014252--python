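"""Readers, writers and run configuration for the circRNA-miRNA pipeline.

All external formats the pipeline touches pass through here: FASTA
(miRNA and target sequences), TSV expression tables (two-condition
abundances per feature class), ENCORI-style interaction tables, site
tables (TSV + optional BED6 companion), and the plain-text run
configuration (YAML or JSON).

Coordinate convention: everything is stored 0-based half-open
internally.  ENCORI-style 1-based inclusive input is converted once at
the boundary; converting an already-normalized (BED-style) table is the
identity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("circtdmd")

FEATURE_CLASSES = ("miRNA", "pri-miRNA", "circRNA", "mRNA")

EXPRESSION_COLUMNS = ["feature_id", "feature_class", "abundance_pre", "abundance_post"]

SITE_COLUMNS = [
    "mirna_id",
    "target_id",
    "target_topology",
    "offset",
    "seed_class",
    "paired_3p",
    "mismatches_3p",
    "bulge_len",
    "paired_run_3p",
    "mirna_length",
    "architecture",
]

INTERACTION_COLUMNS = [
    "mirna_id",
    "target_id",
    "target_class",
    "chrom",
    "site_start",
    "site_end",
    "strand",
    "clip_experiments",
    "supporting_programs",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PipelineError):
    """Malformed sequence file (empty record, bad alphabet...)."""


class SchemaError(PipelineError):
    """Table is missing columns or violates uniqueness constraints."""


class ValidationError(PipelineError):
    """Values present but invalid (negative abundance, bad enum...)."""


class CoordinateError(PipelineError):
    """Inconsistent genomic interval after convention conversion."""


class ParameterError(PipelineError):
    """An operation was called with out-of-range parameters."""


class InputError(PipelineError):
    """Structurally invalid input to an analysis stage."""


class ConsistencyError(PipelineError):
    """Internal fields of a record contradict each other."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

SEED_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline.

    The interaction-filter defaults (``min_clip_experiments=1``,
    ``min_programs=2``) mirror the ENCORI download parameters used to
    assemble the validated interaction set.  The site-architecture
    defaults encode the TDMD definition: seed pairing plus extensive
    3'-end complementarity with at most ``max_mismatches`` mismatches in
    addition to a central bulge.
    """

    min_seed_class: str = "6mer"
    max_mismatches: int = 3
    bulge_min: int = 1
    bulge_max: int = 5
    min_paired_3p: int = 6
    min_contiguous_paired: int = 4
    min_clip_experiments: int = 1
    min_programs: int = 2
    pseudocount: float = 1.0
    fisher_alternative: str = "greater"   # or "two-sided"
    quartile_rule: str = "lower"          # ties at a break -> lower quartile
    correlation_method: str = "spearman"  # or "pearson"
    gu_wobble: bool = False               # count G:U as 3' pairing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_seed_class not in SEED_CLASSES:
            raise ValidationError(f"unknown seed class {self.min_seed_class!r}")
        if self.bulge_min < 0 or self.bulge_max < self.bulge_min:
            raise ValidationError("bulge size range must satisfy 0 <= min <= max")
        if self.max_mismatches < 0:
            raise ValidationError("max_mismatches must be >= 0")
        if self.fisher_alternative not in ("greater", "two-sided", "less"):
            raise ValidationError(f"bad fisher_alternative {self.fisher_alternative!r}")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValidationError(f"bad correlation_method {self.correlation_method!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise SchemaError(f"config file {path} does not hold a key/value mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_VALID_RNA = set("ACGUN")
_VALID_DNA = set("ACGTN")


def read_fasta(path: str | Path, alphabet: str = "RNA") -> list[tuple[str, str]]:
    """Read a FASTA file, normalizing case and T/U to ``alphabet``.

    Returns ``[(id, sequence), ...]`` with ids taken as the first
    whitespace-delimited token of each header.  Any character outside
    ACGT/U/N raises :class:`FormatError` naming the offending record.
    """
    if alphabet not in ("DNA", "RNA"):
        raise ParameterError(f"alphabet must be DNA or RNA, got {alphabet!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "RNA":
            seq = seq.replace("T", "U")
            valid = _VALID_RNA
        else:
            seq = seq.replace("U", "T")
            valid = _VALID_DNA
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        bad = set(seq) - valid
        if bad:
            raise FormatError(
                f"invalid character(s) {sorted(bad)} in record {rec.id!r} in {path}"
            )
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path,
    feature_class: str,
    id_col: str = "feature_id",
    pre_col: str = "abundance_pre",
    post_col: str = "abundance_post",
) -> pd.DataFrame:
    """Read a two-condition expression TSV into the canonical frame.

    The returned frame has columns ``feature_id, feature_class,
    abundance_pre, abundance_post``; abundances are junction reads for
    circRNAs and normalized reads otherwise.
    """
    if feature_class not in FEATURE_CLASSES:
        raise ValidationError(f"unknown feature class {feature_class!r}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    for col in (id_col, pre_col, post_col):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    try:
        pre = pd.to_numeric(df[pre_col], errors="raise").astype(float)
        post = pd.to_numeric(df[post_col], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric abundance in {path}: {exc}") from exc
    out = pd.DataFrame(
        {
            "feature_id": df[id_col].astype(str),
            "feature_class": feature_class,
            "abundance_pre": pre,
            "abundance_post": post,
        }
    )
    validate_expression_table(out, source=str(path))
    return out


def validate_expression_table(df: pd.DataFrame, source: str = "<memory>") -> None:
    dup = df["feature_id"][df["feature_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicated feature_id {dup.iloc[0]!r} in {source}")
    for col in ("abundance_pre", "abundance_post"):
        vals = df[col]
        if not pd.api.types.is_float_dtype(vals) and not pd.api.types.is_integer_dtype(vals):
            raise ValidationError(f"column {col} is not numeric in {source}")
        if vals.isna().any() or (vals < 0).any() or ~np.isfinite(vals).all():
            bad = df.loc[vals.isna() | (vals < 0), "feature_id"]
            raise ValidationError(
                f"negative or missing abundance for {bad.iloc[0]!r} in {source}"
            )


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interaction tables
# ---------------------------------------------------------------------------

def read_interaction_table(path: str | Path, dialect: str = "encori") -> list:
    """Read a miRNA-target interaction TSV.

    ``dialect='encori'`` declares 1-based inclusive site coordinates
    (converted on read); ``dialect='bed'`` declares 0-based half-open
    coordinates (stored as-is).
    """
    from .pairing_metrics import InteractionRecord  # avoid import cycle

    if dialect not in ("encori", "bed"):
        raise ParameterError(f"unknown coordinate dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    missing = set(INTERACTION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s) {sorted(missing)} in {path}")
    offset = 1 if dialect == "encori" else 0
    records = []
    for row in df.itertuples(index=False):
        start = int(row.site_start) - offset
        end = int(row.site_end)
        if start >= end:
            raise CoordinateError(
                f"site start >= end after conversion for {row.mirna_id}:{row.target_id} "
                f"({row.chrom}:{row.site_start}-{row.site_end}, dialect={dialect})"
            )
        records.append(
            InteractionRecord(
                mirna_id=str(row.mirna_id),
                target_id=str(row.target_id),
                target_class=str(row.target_class),
                chrom=str(row.chrom),
                site_start=start,
                site_end=end,
                strand=str(row.strand),
                clip_experiments=int(row.clip_experiments),
                supporting_programs=int(row.supporting_programs),
            )
        )
    return records


def write_interaction_table(records: Sequence, path: str | Path) -> None:
    """Write interactions in BED-style (0-based half-open) coordinates."""
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

def write_site_table(sites: Sequence, path: str | Path, bed_path: str | Path | None = None) -> None:
    """Write SiteMatch records as a TSV (stable column order, input order).

    With ``bed_path``, also writes a BED6 companion where the chrom is
    the target id, the interval is the site footprint in target
    coordinates, the name is ``miRNA:target`` and the score is the
    number of paired 3' nucleotides.
    """
    rows = [dataclasses.asdict(s) for s in sites]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for s in sites:
                footprint = s.mirna_length + s.bulge_len
                start = max(0, s.offset - footprint + 1)
                fh.write(
                    f"{s.target_id}\t{start}\t{s.offset + 1}\t"
                    f"{s.mirna_id}:{s.target_id}\t{s.paired_3p}\t+\n"
                )


def read_site_table(path: str | Path) -> list:
    from .site_scanner import SiteMatch

    df = pd.read_csv(path, sep="\t")
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s) {sorted(missing)} in {path}")
    return [
        SiteMatch(
            mirna_id=str(r.mirna_id),
            target_id=str(r.target_id),
            target_topology=str(r.target_topology),
            offset=int(r.offset),
            seed_class=str(r.seed_class),
            paired_3p=int(r.paired_3p),
            mismatches_3p=int(r.mismatches_3p),
            bulge_len=int(r.bulge_len),
            paired_run_3p=int(r.paired_run_3p),
            mirna_length=int(r.mirna_length),
            architecture=str(r.architecture),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------

def setup_logging(level: int = logging.INFO) -> None:
    """Route pipeline logs to standard error (idempotent)."""
    root = logging.getLogger("circtdmd")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)
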