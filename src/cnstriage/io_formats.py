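"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* small-variant tables: VCF 4.x (read, via cyvcf2) or a flat TSV dialect that
  mirrors the VCF columns plus annotation columns (read/write);
* exon/interval maps: BED, 0-based half-open (read/write);
* the packaged cohort fixture re-encoding the published study tables (load).

All coordinate conversions between the 1-based variant convention and the
0-based interval convention happen in this module and nowhere else.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import (
    CONSEQUENCES,
    VARIANT_COLUMNS,
    CohortBundle,
    Finding,
    SampleRecord,
    empty_cnv_table,
    empty_variant_table,
)

# TSV dialect header -> canonical column names
_TSV_HEADER = {
    "SAMPLE": "sample",
    "CHROM": "chrom",
    "POS": "pos",
    "REF": "ref",
    "ALT": "alt",
    "ZYGOSITY": "zygosity",
    "DP": "dp",
    "AD_ALT": "ad_alt",
    "GENE": "gene",
    "CSQ": "consequence",
    "SIFT_CLASS": "sift_class",
    "CADD": "cadd",
    "MCAP": "mcap",
    "REVEL": "revel",
    "AF_PUBLIC": "af_public",
    "AF_INHOUSE": "af_inhouse",
}
_CANON_TO_TSV = {v: k for k, v in _TSV_HEADER.items()}

_SIFT_CLASSES = {"damaging", "tolerated", "missing"}
_ZYGOSITIES = {"het", "hom", "hemi"}


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Small-variant tables
# ---------------------------------------------------------------------------


def read_variant_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a per-sample small-variant table.

    Parameters
    ----------
    path : file to read.
    dialect : ``"tsv"`` (flat annotated table) or ``"vcf"``.

    Returns a DataFrame with the canonical :data:`~cnstriage.core.VARIANT_COLUMNS`
    schema, coordinates 1-based, one row per sample-allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'vcf' or 'tsv'")


def _coerce_row(canon: dict, lineno: int) -> dict:
    """Validate and type one variant row; raise FormatError naming the line."""
    try:
        canon["pos"] = int(canon["pos"])
        canon["dp"] = int(canon["dp"])
        canon["ad_alt"] = int(canon["ad_alt"])
        for k in ("cadd", "mcap", "revel"):
            v = canon.get(k, "")
            canon[k] = float(v) if v not in ("", ".", None) else np.nan
        for k in ("af_public", "af_inhouse"):
            v = canon.get(k, "")
            canon[k] = float(v) if v not in ("", ".", None) else 0.0
    except (TypeError, ValueError) as exc:
        raise FormatError(f"line {lineno}: {exc}") from None
    if canon["pos"] < 1:
        raise FormatError(f"line {lineno}: position must be >= 1")
    if canon["ad_alt"] > canon["dp"]:
        raise FormatError(f"line {lineno}: alt depth exceeds total depth")
    csq = canon["consequence"]
    if csq not in CONSEQUENCES:
        raise FormatError(
            f"line {lineno}: unknown consequence {csq!r}; accepted: {sorted(CONSEQUENCES)}"
        )
    if canon["zygosity"] not in _ZYGOSITIES:
        raise FormatError(f"line {lineno}: unknown zygosity {canon['zygosity']!r}")
    if not canon.get("sift_class"):
        canon["sift_class"] = "missing"
    elif canon["sift_class"] not in _SIFT_CLASSES:
        raise FormatError(
            f"line {lineno}: unknown SIFT class {canon['sift_class']!r}; "
            f"accepted: {sorted(_SIFT_CLASSES)}"
        )
    for k in ("af_public", "af_inhouse"):
        if not (0.0 <= canon[k] <= 1.0):
            raise FormatError(f"line {lineno}: {k} outside [0, 1]")
    canon["gene"] = canon.get("gene") or ""
    if canon["gene"] == ".":
        canon["gene"] = ""
    return canon


def _read_variant_tsv(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file, expected a header line")
    header = lines[0].lstrip("#").split("\t")
    missing = set(_TSV_HEADER) - set(header)
    if missing:
        raise FormatError(f"{path}: missing required columns: {sorted(missing)}")
    idx = {name: header.index(name) for name in _TSV_HEADER}
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < len(header):
            raise FormatError(f"line {lineno}: expected {len(header)} fields, got {len(fields)}")
        canon = {_TSV_HEADER[name]: fields[i] for name, i in idx.items()}
        rows.append(_coerce_row(canon, lineno))
    if not rows:
        return empty_variant_table()
    return pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))


def write_variant_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical variant table in the TSV dialect (round-trip safe)."""
    out = table.loc[:, list(VARIANT_COLUMNS)].copy()
    out.columns = [_CANON_TO_TSV[c] for c in out.columns]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _read_variant_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF  # deferred: cheap import elsewhere

    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    rows = []
    for rec in vcf:
        info = dict(rec.INFO)
        gene = info.get("GENE", "") or ""
        csq = info.get("CSQ", "")
        if csq not in CONSEQUENCES:
            raise FormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} unknown consequence {csq!r}; "
                f"accepted: {sorted(CONSEQUENCES)}"
            )
        sift = info.get("SIFT_CLASS", "missing") or "missing"
        scores = {k.lower(): info.get(k, None) for k in ("CADD", "MCAP", "REVEL")}
        afs = {k.lower(): float(info.get(k, 0.0) or 0.0) for k in ("AF_PUBLIC", "AF_INHOUSE")}
        depths = rec.format("DP")
        alt_depths = rec.format("AD")
        for si, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]
            if not any(a == 1 for a in alleles):
                continue
            if all(a == 1 for a in alleles if a >= 0):
                zyg = "hemi" if len([a for a in alleles if a >= 0]) == 1 else "hom"
            else:
                zyg = "het"
            dp = int(depths[si][0]) if depths is not None else 0
            ad = int(alt_depths[si][1]) if alt_depths is not None else 0
            rows.append(
                {
                    "sample": sample_names[si],
                    "chrom": rec.CHROM,
                    "pos": int(rec.POS),
                    "ref": rec.REF,
                    "alt": rec.ALT[0],
                    "zygosity": zyg,
                    "dp": dp,
                    "ad_alt": ad,
                    "gene": gene,
                    "consequence": csq,
                    "sift_class": sift,
                    "cadd": float(scores["cadd"]) if scores["cadd"] is not None else np.nan,
                    "mcap": float(scores["mcap"]) if scores["mcap"] is not None else np.nan,
                    "revel": float(scores["revel"]) if scores["revel"] is not None else np.nan,
                    "af_public": afs["af_public"],
                    "af_inhouse": afs["af_inhouse"],
                }
            )
    if not rows:
        return empty_variant_table()
    return pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))


# ---------------------------------------------------------------------------
# Interval maps (BED)
# ---------------------------------------------------------------------------


class IntervalMap:
    """Per-chromosome interval set (0-based half-open) with overlap queries."""

    def __init__(self, intervals: list[tuple[str, int, int, str]]) -> None:
        self.intervals = sorted(intervals, key=lambda iv: (iv[0], iv[1], iv[2]))
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, label in self.intervals:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[str, int, int, str]]:
        """Intervals overlapping [start, end) on ``chrom`` (0-based half-open)."""
        tree = self._trees.get(chrom)
        if tree is None or end <= start:
            return []
        return sorted(
            (chrom, iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end)
        )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and end > start and tree.overlaps(start, end))


def read_intervals(path: str | Path) -> IntervalMap:
    """Read a BED file (0-based half-open) into an :class:`IntervalMap`."""
    path = Path(path)
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric coordinate") from None
            if start >= end:
                raise FormatError(f"line {lineno}: start >= end ({start} >= {end})")
            label = fields[3] if len(fields) > 3 else ""
            intervals.append((chrom, start, end, label))
    return IntervalMap(intervals)


def write_intervals(intervals: IntervalMap | list, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


# ---------------------------------------------------------------------------
# Cohort directories (CLI surface)
# ---------------------------------------------------------------------------


def write_cohort_dir(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write a bundle as a directory of flat text tables.

    Layout: samples.tsv, variants.tsv (TSV dialect), cnvs.tsv, truth.tsv
    (when present), and depth/<sample>.tsv per profile.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample": [s.sample_id for s in bundle.samples],
            "arm": [s.arm for s in bundle.samples],
            "sex": [s.sex for s in bundle.samples],
            "subgroup": [s.subgroup for s in bundle.samples],
            "phenotypes": [",".join(s.phenotypes) for s in bundle.samples],
            "hpo_terms": [",".join(sorted(bundle.phenotype_map.get(s.sample_id, set()))) for s in bundle.samples],
            "qc_flags": [",".join(s.qc_flags) for s in bundle.samples],
        }
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    write_variant_table(bundle.variants, outdir / "variants.tsv")
    bundle.cnvs.to_csv(outdir / "cnvs.tsv", sep="\t", index=False)
    if bundle.truth is not None and len(bundle.truth):
        bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if bundle.depth_profiles:
        depth_dir = outdir / "depth"
        depth_dir.mkdir(exist_ok=True)
        for sid, profile in bundle.depth_profiles.items():
            cols = ["chrom", "start", "end", "count", "gc"]
            profile.bins[cols].to_csv(depth_dir / f"{sid}.tsv", sep="\t", index=False)


def read_cohort_dir(indir: str | Path) -> CohortBundle:
    """Read a cohort directory written by :func:`write_cohort_dir`."""
    from .core import DepthProfile

    indir = Path(indir)
    samples_df = pd.read_csv(indir / "samples.tsv", sep="\t", keep_default_na=False)
    samples = [
        SampleRecord(
            sample_id=str(r.sample),
            arm=r.arm or "case",
            sex=r.sex or "F",
            subgroup=str(r.subgroup),
            phenotypes=tuple(str(r.phenotypes).split(",")) if r.phenotypes else (),
            qc_flags=tuple(str(r.qc_flags).split(",")) if r.qc_flags else (),
        )
        for r in samples_df.itertuples(index=False)
    ]
    phenotype_map = {
        str(r.sample): set(str(r.hpo_terms).split(",")) if r.hpo_terms else set()
        for r in samples_df.itertuples(index=False)
    }
    variants = read_variant_table(indir / "variants.tsv", "tsv")
    cnvs_path = indir / "cnvs.tsv"
    cnvs = pd.read_csv(cnvs_path, sep="\t", keep_default_na=False) if cnvs_path.exists() else empty_cnv_table()
    if len(cnvs) == 0:
        cnvs = empty_cnv_table()
    else:
        cnvs["sample"] = cnvs["sample"].astype(str)
    truth_path = indir / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t", keep_default_na=False) if truth_path.exists() else None
    depth_profiles = {}
    depth_dir = indir / "depth"
    if depth_dir.is_dir():
        for f in sorted(depth_dir.glob("*.tsv")):
            bins = pd.read_csv(f, sep="\t")
            width = int((bins["end"] - bins["start"]).mode().iloc[0])
            depth_profiles[f.stem] = DepthProfile(sample_id=f.stem, bins=bins, bin_width=width)
    return CohortBundle(
        samples=samples,
        variants=variants,
        cnvs=cnvs,
        depth_profiles=depth_profiles,
        phenotype_map=phenotype_map,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Packaged study fixture
# ---------------------------------------------------------------------------


@dataclass
class StudyFixture:
    """The packaged re-encoding of the published cohort tables.

    ``bundle`` holds the 162 case samples (variant/CNV tables empty — the
    fixture encodes curated *findings*, not raw calls); ``findings`` is the
    curated list reproducing the published variant tables; ``gene_modes`` maps
    each key gene to its disease inheritance mode; ``metadata`` records the
    cohort accountings and QC notes.
    """

    bundle: CohortBundle
    findings: list[Finding]
    gene_modes: dict[str, str]
    metadata: dict

    @property
    def findings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [f.sample_id for f in self.findings],
                "kind": [f.kind for f in self.findings],
                "gene": [f.gene for f in self.findings],
                "label": [f.label for f in self.findings],
                "tier_class": [f.tier_class for f in self.findings],
                "category": [f.category for f in self.findings],
                "disease": [f.disease for f in self.findings],
                "inheritance": [f.inheritance for f in self.findings],
                "size_tier": [f.size_tier for f in self.findings],
                "zygosity": [f.zygosity for f in self.findings],
            }
        )


def _fixture_dir():
    return resources.files("cnstriage") / "data" / "fixture"


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def load_study_fixture(verify_checksums: bool = True) -> StudyFixture:
    """Load the packaged cohort fixture.

    Raises ``FormatError`` on a checksum mismatch, guarding against silent
    edits of the packaged tables.
    """
    root = _fixture_dir()
    manifest = json.loads((root / "manifest.json").read_text())
    contents: dict[str, bytes] = {}
    for name, expected in manifest["sha256"].items():
        data = (root / name).read_bytes()
        if verify_checksums and _sha256(data) != expected:
            raise FormatError(f"fixture file {name} checksum mismatch (file edited?)")
        contents[name] = data

    samples_df = pd.read_csv(pd.io.common.BytesIO(contents["samples.tsv"]), sep="\t")
    findings_df = pd.read_csv(
        pd.io.common.BytesIO(contents["findings.tsv"]), sep="\t", keep_default_na=False
    )
    modes_df = pd.read_csv(pd.io.common.BytesIO(contents["gene_modes.tsv"]), sep="\t")

    samples = [
        SampleRecord(
            sample_id=str(r.sample),
            arm="case",
            sex=r.sex,
            subgroup=r.subgroup,
            phenotypes=tuple(str(r.phenotypes).split(",")) if r.phenotypes else (),
            qc_flags=tuple(str(r.qc_flags).split(",")) if isinstance(r.qc_flags, str) and r.qc_flags else (),
        )
        for r in samples_df.itertuples(index=False)
    ]
    phenotype_map = {
        str(r.sample): set(str(r.hpo_terms).split(",")) if isinstance(r.hpo_terms, str) and r.hpo_terms else set()
        for r in samples_df.itertuples(index=False)
    }
    bundle = CohortBundle(
        samples=samples,
        variants=empty_variant_table(),
        cnvs=empty_cnv_table(),
        phenotype_map=phenotype_map,
    )

    findings = [
        Finding(
            sample_id=str(r.sample),
            kind=r.kind,
            gene=r.gene,
            label=r.label,
            tier_class=r.tier_class,
            category=r.category,
            disease=r.disease,
            inheritance=r.inheritance,
            size_tier=r.size_tier,
            zygosity=r.zygosity,
        )
        for r in findings_df.itertuples(index=False)
    ]
    gene_modes = dict(zip(modes_df["gene"], modes_df["mode"]))
    metadata = json.loads(contents["metadata.json"])
    return StudyFixture(bundle=bundle, findings=findings, gene_modes=gene_modes, metadata=metadata)
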