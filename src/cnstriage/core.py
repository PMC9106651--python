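"""Core domain types shared by every pipeline stage.

Small variants live in pandas DataFrames (schema in :data:`VARIANT_COLUMNS`);
the dataclasses here carry per-sample and per-event metadata that does not fit
naturally in a flat table: samples, depth profiles, copy-number calls,
classified findings, and the cohort bundle that ties them together.

Coordinate conventions: small variants are 1-based (VCF); genomic intervals
(BED exon maps) are 0-based half-open; CNV calls are 1-based inclusive, so
``size = end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Accepted functional-consequence labels for small variants.
CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "canonical_splice",
        "stop_loss",
        "synonymous",
        "intronic",
        "noncoding",
        "inframe_indel",
    }
)

#: Consequences counted as loss-of-function.
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "canonical_splice", "stop_loss"})

#: Five-tier clinical significance classes.
TIER_CLASSES = ("P", "LP", "VUS", "LB", "B")

#: Finding categories.
CATEGORIES = ("primary", "incidental", "secondary", "carrier", "none")

#: CNV resolution tiers, largest first.
SIZE_TIERS = ("chromosomal", "submicroscopic", "intragenic")

#: Inheritance modes.
INHERITANCE_MODES = ("AD", "AR", "XL", "XLD")

#: Canonical column order for the small-variant table.
VARIANT_COLUMNS = (
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "zygosity",
    "dp",
    "ad_alt",
    "gene",
    "consequence",
    "sift_class",
    "cadd",
    "mcap",
    "revel",
    "af_public",
    "af_inhouse",
)

#: Canonical column order for the CNV-call table.
CNV_COLUMNS = (
    "sample",
    "chrom",
    "start",
    "end",
    "copy_number",
    "size",
    "size_tier",
    "genes",
    "freq_inhouse",
    "quality",
    "label",
)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    """One fetus or control individual."""

    sample_id: str
    arm: str = "case"  # "case" or "control"
    sex: str = "F"  # chromosomal sex: "F" (XX) or "M" (XY)
    subgroup: str = ""  # e.g. "CNS_only" / "CNS_plus"
    phenotypes: tuple[str, ...] = ()  # free-text anomaly labels
    qc_flags: tuple[str, ...] = ()  # e.g. "cnv_calling_failed"

    def __post_init__(self) -> None:
        if self.arm not in ("case", "control"):
            raise ValueError(f"arm must be 'case' or 'control', got {self.arm!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclass
class DepthProfile:
    """Binned read counts for one sample's low-pass run.

    ``bins`` is a DataFrame with columns chrom, start, end, count, gc and,
    after GC correction, ``ratio`` (count / expected count given GC,
    normalised so the autosomal median is 1).
    """

    sample_id: str
    bins: pd.DataFrame
    bin_width: int

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "count", "gc"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"depth profile missing columns: {sorted(missing)}")
        if (self.bins["count"] < 0).any():
            raise ValueError("negative bin counts")
        gc = self.bins["gc"]
        if ((gc < 0) | (gc > 1)).any():
            raise ValueError("GC fraction outside [0, 1]")

    @property
    def corrected(self) -> bool:
        return "ratio" in self.bins.columns

    def copy(self) -> "DepthProfile":
        return DepthProfile(self.sample_id, self.bins.copy(), self.bin_width)


@dataclass
class CnvCall:
    """One copy-number event, any size from 50 bp upward.

    Coordinates are 1-based inclusive; ``size = end - start + 1``.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    genes: tuple[str, ...] = ()
    freq_inhouse: float = 0.0
    quality: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"CNV end < start: {self.chrom}:{self.start}-{self.end}")
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def is_deletion(self) -> bool:
        return self.copy_number < 2

    def event_string(self) -> str:
        """Cytogenetics-flavoured event string, e.g. ``del(chr5:100-200)x1``."""
        kind = "del" if self.copy_number < 2 else "dup"
        return f"{kind}({self.chrom}:{self.start}-{self.end})x{self.copy_number}"


@dataclass
class Finding:
    """A classified variant attached to a sample — the reporting unit."""

    sample_id: str
    kind: str  # aneuploidy | cnv | intragenic_cnv | snv
    gene: str  # key/critical gene, may be ""
    label: str  # HGVS or event string
    tier_class: str  # P | LP | VUS | LB | B
    category: str = "none"  # primary | incidental | secondary | carrier | none
    disease: str = ""
    inheritance: str = ""
    size_tier: str = ""  # for CNV-kind findings
    zygosity: str = ""
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tier_class not in TIER_CLASSES:
            raise ValueError(f"unknown tier class {self.tier_class!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "primary" and self.tier_class not in ("P", "LP"):
            raise ValueError("primary findings must be classified P or LP")


@dataclass
class Diagnosis:
    """Per-sample outcome of the triage cascade."""

    sample_id: str
    stage: str  # "lowpass" | "snv" | "small_cnv" | "undiagnosed"
    findings: list[Finding] = field(default_factory=list)
    qc_log: list[str] = field(default_factory=list)

    @property
    def diagnosed(self) -> bool:
        return self.stage != "undiagnosed"


# ---------------------------------------------------------------------------
# Aggregates
# ---------------------------------------------------------------------------


class FrequencyDB:
    """Population allele-frequency lookup; a missing key means frequency 0.

    Holds small-variant frequencies keyed by (chrom, pos, ref, alt) and CNV
    cohort frequencies keyed by an event key string.
    """

    def __init__(
        self,
        source: str,
        snv_freqs: Mapping[tuple[str, int, str, str], float] | None = None,
        cnv_freqs: Mapping[str, float] | None = None,
    ) -> None:
        self.source = source
        self._snv = dict(snv_freqs or {})
        self._cnv = dict(cnv_freqs or {})
        for f in list(self._snv.values()) + list(self._cnv.values()):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency outside [0, 1]: {f}")

    def snv_frequency(self, chrom: str, pos: int, ref: str, alt: str) -> float:
        return self._snv.get((chrom, int(pos), ref, alt), 0.0)

    def cnv_frequency(self, event_key: str) -> float:
        return self._cnv.get(event_key, 0.0)

    def __len__(self) -> int:
        return len(self._snv) + len(self._cnv)


@dataclass
class CohortBundle:
    """Everything the pipeline knows about one cohort."""

    samples: list[SampleRecord]
    variants: pd.DataFrame
    cnvs: pd.DataFrame
    depth_profiles: dict[str, DepthProfile] = field(default_factory=dict)
    phenotype_map: dict[str, set[str]] = field(default_factory=dict)
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.variants is None or len(self.variants) == 0:
            self.variants = empty_variant_table()
        if self.cnvs is None or len(self.cnvs) == 0:
            self.cnvs = empty_cnv_table()
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        ids = {s.sample_id for s in self.samples}
        if len(ids) != len(self.samples):
            raise ValueError("duplicate sample ids")
        for name, table in (("variants", self.variants), ("cnvs", self.cnvs)):
            if len(table):
                stray = set(table["sample"].unique()) - ids
                if stray:
                    raise ValueError(f"{name} reference unknown samples: {sorted(stray)[:5]}")
        stray = set(self.depth_profiles) - ids
        if stray:
            raise ValueError(f"depth profiles for unknown samples: {sorted(stray)[:5]}")
        if len(self.variants):
            keys = self.variants[["sample", "chrom", "pos", "ref", "alt"]]
            if keys.duplicated().any():
                raise ValueError("duplicate (sample, chrom, pos, ref, alt) variant keys")

    # -- convenience --------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def arm_ids(self, arm: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.arm == arm]

    def sample(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def empty_variant_table() -> pd.DataFrame:
    """An empty small-variant table with the canonical schema."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in VARIANT_COLUMNS})
    for col, dt in (
        ("pos", np.int64),
        ("dp", np.int64),
        ("ad_alt", np.int64),
        ("cadd", float),
        ("mcap", float),
        ("revel", float),
        ("af_public", float),
        ("af_inhouse", float),
    ):
        df[col] = df[col].astype(dt)
    return df


def empty_cnv_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in CNV_COLUMNS})
    for col in ("start", "end", "copy_number", "size"):
        df[col] = df[col].astype(np.int64)
    for col in ("freq_inhouse", "quality"):
        df[col] = df[col].astype(float)
    return df


def cnv_calls_to_table(calls: Iterable[CnvCall], size_tiers: Iterable[str] | None = None) -> pd.DataFrame:
    """Flatten CnvCall objects into the canonical CNV table."""
    calls = list(calls)
    if not calls:
        return empty_cnv_table()
    tiers = list(size_tiers) if size_tiers is not None else [""] * len(calls)
    return pd.DataFrame(
        {
            "sample": [c.sample_id for c in calls],
            "chrom": [c.chrom for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "copy_number": [c.copy_number for c in calls],
            "size": [c.size for c in calls],
            "size_tier": tiers,
            "genes": [",".join(c.genes) for c in calls],
            "freq_inhouse": [c.freq_inhouse for c in calls],
            "quality": [c.quality for c in calls],
            "label": [c.label or c.event_string() for c in calls],
        }
    )


def table_to_cnv_calls(table: pd.DataFrame) -> list[CnvCall]:
    calls = []
    for row in table.itertuples(index=False):
        genes = tuple(g for g in str(row.genes).split(",") if g) if row.genes else ()
        calls.append(
            CnvCall(
                sample_id=row.sample,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                copy_number=int(row.copy_number),
                genes=genes,
                freq_inhouse=float(row.freq_inhouse),
                quality=float(row.quality),
                label=str(row.label),
            )
        )
    return calls
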