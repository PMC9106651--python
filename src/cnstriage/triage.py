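"""Primary-diagnosis cascade: low-pass findings, then phenotype-driven SNV
interpretation, then small-CNV assessment.

Stage order mirrors the two-stage sequencing design: whole-chromosome and
segmental (>100 kb) read-depth findings first; if uninformative, deep-WGS
small variants filtered against a phenotype-derived candidate gene list and
classified by a reduced deterministic ACMG-style rule engine; if still
uninformative, exon-containing rare intragenic CNVs (50 bp - 100 kb).

The rule engine consumes curated evidence tags (PVS1/PS/PM/PP/BA1/BS/BP) and
applies the published combining rules deterministically; it does not generate
evidence (segregation, literature) itself — those judgments arrive as input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import CnvCall, CohortBundle, Diagnosis, Finding, LOF_CONSEQUENCES
from .io_formats import IntervalMap
from .lowpass_screen import (
    assign_size_tier,
    call_aneuploidy,
    cnv_calling_qc,
    gc_correct,
    segment_cnvs,
)

# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Thresholds:
    """All numeric cutoffs of the triage and burden analyses."""

    maf_diagnostic: float = 0.01  # MAF filter for diagnostic SNVs
    small_cnv_freq: float = 0.01  # in-house frequency cap for small CNVs
    qc_depth: int = 20  # burden QC: minimum read depth
    qc_alt_depth: int = 3  # burden QC: minimum alt-allele depth
    qc_max_len_bp: int = 5  # burden QC: max(len(ref), len(alt)) cap
    cadd: float = 20.0  # damaging-missense score cutoffs (strict >)
    mcap: float = 0.025
    revel: float = 0.5
    cnv_score_pathogenic: float = 0.99  # CNV evidence-point class bounds
    cnv_score_lp_low: float = 0.90
    cnv_score_lp_high: float = 0.98
    maf_strata: tuple[float, ...] = (0.0, 0.001, 0.01)

    def __post_init__(self) -> None:
        if not (self.cnv_score_lp_low <= self.cnv_score_lp_high < self.cnv_score_pathogenic):
            raise ValueError("CNV score bounds must satisfy lp_low <= lp_high < pathogenic")


DEFAULT_THRESHOLDS = Thresholds()


# ---------------------------------------------------------------------------
# Candidate genes from phenotype terms
# ---------------------------------------------------------------------------


def term_descendants(term: str, ontology: Mapping[str, Iterable[str]]) -> set[str]:
    """The term itself plus all descendant terms (ontology maps term -> parents)."""
    children: dict[str, list[str]] = {}
    for t, parents in ontology.items():
        for p in parents:
            children.setdefault(p, []).append(t)
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for c in children.get(t, []):
            if c not in out:
                out.add(c)
                frontier.append(c)
    return out


def build_candidate_genes(
    terms: Iterable[str],
    hpo_map: Mapping[str, Iterable[str]],
    ontology: Mapping[str, Iterable[str]],
) -> set[str]:
    """Fetus-specific candidate gene list from phenotype terms.

    Genes annotated to each query term or to any of its descendant terms
    (annotation propagation). Adding a term can only grow the result.
    """
    genes: set[str] = set()
    for term in terms:
        if term not in ontology:
            raise KeyError(f"unknown phenotype term {term!r}")
        for t in term_descendants(term, ontology):
            genes.update(hpo_map.get(t, ()))
    return genes


# ---------------------------------------------------------------------------
# SNV shortlist
# ---------------------------------------------------------------------------


def filter_snvs_for_diagnosis(
    variants: pd.DataFrame,
    candidate_genes: set[str],
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Diagnostic SNV shortlist.

    Retained iff max(public MAF, in-house MAF) <= ``maf_diagnostic`` AND the
    consequence is neither intronic nor noncoding (canonical splice-site
    variants are their own class and survive) AND the gene is on the
    candidate list. Missing frequencies count as 0.
    """
    if not len(variants):
        return variants
    maf = np.maximum(
        variants["af_public"].fillna(0.0).to_numpy(),
        variants["af_inhouse"].fillna(0.0).to_numpy(),
    )
    csq_ok = ~variants["consequence"].isin(["intronic", "noncoding"]).to_numpy()
    gene_ok = variants["gene"].isin(candidate_genes).to_numpy() & (variants["gene"] != "").to_numpy()
    return variants.loc[(maf <= th.maf_diagnostic) & csq_ok & gene_ok]


# ---------------------------------------------------------------------------
# ACMG-style rule engine
# ---------------------------------------------------------------------------

_TAG_STRENGTH = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone_benign",
    "BS": "strong_benign",
    "BP": "supporting_benign",
}


def _tag_strength(tag: str) -> str:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        rest = tag[len(prefix):]
        if tag.startswith(prefix) and (rest == "" or rest.isdigit()):
            return _TAG_STRENGTH[prefix]
    raise ValueError(
        f"unknown evidence tag {tag!r}; accepted prefixes: PVS, PS, PM, PP, BA, BS, BP"
    )


def classify_variant(evidence: Iterable[str]) -> str:
    """Five-tier class from an evidence-tag multiset.

    Deterministic application of the published combining rules; conflicting
    pathogenic- and benign-side evidence resolves to VUS, as does an empty
    tag set.
    """
    counts = {"very_strong": 0, "strong": 0, "moderate": 0, "supporting": 0,
              "stand_alone_benign": 0, "strong_benign": 0, "supporting_benign": 0}
    for tag in evidence:
        counts[_tag_strength(tag)] += 1
    vs, s, m, p = counts["very_strong"], counts["strong"], counts["moderate"], counts["supporting"]
    ba, bs, bp = counts["stand_alone_benign"], counts["strong_benign"], counts["supporting_benign"]

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    likely_pathogenic = (
        (vs >= 1 and m >= 1)
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return "VUS"
    if pathogenic:
        return "P"
    if likely_pathogenic:
        return "LP"
    if benign:
        return "B"
    if likely_benign:
        return "LB"
    return "VUS"


def score_cnv(evidence_points: float, th: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Five-tier class from a CNV evidence-point total.

    >= 0.99 pathogenic; [0.90, 0.98] likely pathogenic; the benign side
    mirrors those bounds with negated points; everything between is VUS.
    """
    x = float(evidence_points)
    if x >= th.cnv_score_pathogenic:
        return "P"
    if x >= th.cnv_score_lp_low:
        return "LP"
    if x <= -th.cnv_score_pathogenic:
        return "B"
    if x <= -th.cnv_score_lp_low:
        return "LB"
    return "VUS"


# ---------------------------------------------------------------------------
# Small-CNV assessment
# ---------------------------------------------------------------------------


def triage_small_cnvs(
    cnvs: Iterable[CnvCall],
    exon_map: IntervalMap,
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> list[CnvCall]:
    """Assessable small CNVs: exon-overlapping and rare in-house.

    Retained iff the event overlaps at least one exon interval and its
    in-house cohort frequency is strictly below ``small_cnv_freq``; the
    result is ordered by size, largest first.
    """
    kept = []
    for c in cnvs:
        if not (50 <= c.size < 100_000):
            raise ValueError(f"small-CNV triage got a {c.size} bp event outside [50 bp, 100 kb)")
        if c.freq_inhouse < th.small_cnv_freq and exon_map.overlaps(c.chrom, c.start - 1, c.end):
            kept.append(c)
    return sorted(kept, key=lambda c: c.size, reverse=True)


# ---------------------------------------------------------------------------
# Finding categories
# ---------------------------------------------------------------------------


def assign_finding_category(
    finding: Finding,
    phenotype_relevant: bool,
    sf_gene_list: set[str],
    gene_inheritance: Mapping[str, str],
) -> str:
    """primary / secondary / carrier / incidental for a classified finding.

    Only P/LP findings get a reportable category. Phenotype relevance wins;
    otherwise genes on the secondary-findings reporting list are secondary;
    heterozygous variants in recessive-disease genes are carrier findings;
    the remainder are incidental.
    """
    if finding.tier_class not in ("P", "LP"):
        return "none"
    if phenotype_relevant:
        return "primary"
    if finding.gene and finding.gene in sf_gene_list:
        return "secondary"
    mode = finding.inheritance or gene_inheritance.get(finding.gene, "")
    if mode == "AR" and finding.zygosity == "het":
        return "carrier"
    return "incidental"


# ---------------------------------------------------------------------------
# Per-sample cascade
# ---------------------------------------------------------------------------


@dataclass
class TriageResources:
    """Annotation inputs the cascade consumes (all curated or synthetic)."""

    exon_map: IntervalMap
    hpo_map: Mapping[str, set[str]]
    ontology: Mapping[str, list[str]]
    sf_gene_list: set[str] = field(default_factory=set)
    gene_inheritance: Mapping[str, str] = field(default_factory=dict)
    #: (sample, chrom, pos, ref, alt) -> evidence-tag tuple for curated SNVs
    evidence_tags: Mapping[tuple, tuple[str, ...]] = field(default_factory=dict)
    #: CNV event key (sample, chrom, start, end) -> curated evidence points
    cnv_scores: Mapping[tuple, float] = field(default_factory=dict)


def build_triage_resources(toy, bundle: CohortBundle) -> TriageResources:
    """Triage resources for a synthetic cohort: the toy annotation set plus
    evidence tags lifted from the truth table's spiked SNVs."""
    tags = {}
    if bundle.truth is not None and len(bundle.truth):
        for row in bundle.truth.itertuples(index=False):
            if row.kind == "snv" and row.evidence:
                key = None
                sub = bundle.variants
                hit = sub[(sub["sample"] == row.sample) & (sub["chrom"] == row.chrom) & (sub["pos"] == row.start)]
                for h in hit.itertuples(index=False):
                    key = (h.sample, h.chrom, h.pos, h.ref, h.alt)
                if key:
                    tags[key] = tuple(str(row.evidence).split(","))
    return TriageResources(
        exon_map=toy.exon_map,
        hpo_map=toy.hpo_gene_map,
        ontology=toy.ontology,
        sf_gene_list=toy.sf_gene_list,
        gene_inheritance=toy.gene_inheritance,
        evidence_tags=tags,
    )


def _cnv_evidence_points(call: CnvCall, exon_map: IntervalMap, resources: TriageResources) -> float:
    """Curated evidence points if supplied, else a gene-count heuristic:
    copy-changed regions hitting many genes score pathogenic, a single gene
    likely pathogenic, no genes VUS-level."""
    key = (call.sample_id, call.chrom, call.start, call.end)
    if key in resources.cnv_scores:
        return resources.cnv_scores[key]
    hits = exon_map.overlapping(call.chrom, call.start - 1, call.end)
    genes = {lab.rsplit("_exon", 1)[0] for _, _, _, lab in hits}
    if len(genes) >= 5:
        return 0.99
    if len(genes) >= 1:
        return 0.95
    return 0.0


def triage_sample(
    sample_id: str,
    bundle: CohortBundle,
    resources: TriageResources,
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> Diagnosis:
    """Run the full cascade for one sample.

    Stage 1 (low-pass): aneuploidy + segmental CNVs >= 100 kb from the depth
    profile; any primary finding stops the cascade — the sample's small
    variants are never interpreted. Stage 2 (SNV): candidate-gene filtered
    shortlist classified by the rule engine. Stage 3 (small CNV): only if
    stage 2 was uninformative. A missing depth profile skips stage 1 with a
    QC log entry; a profile failing the dispersion gate does the same.
    """
    sample = bundle.sample(sample_id)
    diagnosis = Diagnosis(sample_id=sample_id, stage="undiagnosed")

    # ---- stage 1: low-pass screen
    profile = bundle.depth_profiles.get(sample_id)
    aneuploid_chroms: set[str] = set()
    if profile is None:
        diagnosis.qc_log.append("no depth profile; low-pass stage skipped")
    else:
        corrected = gc_correct(profile)
        if not cnv_calling_qc(corrected):
            diagnosis.qc_log.append("cnv_calling_failed: depth dispersion above cap")
        else:
            for call in call_aneuploidy(corrected):
                aneuploid_chroms.add(call.chrom)
                diagnosis.findings.append(
                    Finding(
                        sample_id=sample_id,
                        kind="aneuploidy",
                        gene="",
                        label=call.label + (" (possible mosaic)" if call.possible_mosaic else ""),
                        tier_class="P",
                        category="primary",
                        size_tier="chromosomal",
                    )
                )
            for seg in segment_cnvs(profile=corrected, min_size=100_000, exclude_chroms=aneuploid_chroms):
                points = _cnv_evidence_points(seg, resources.exon_map, resources)
                cls = score_cnv(points, th)
                if cls not in ("P", "LP"):
                    continue
                diagnosis.findings.append(
                    Finding(
                        sample_id=sample_id,
                        kind="cnv",
                        gene="",
                        label=seg.event_string(),
                        tier_class=cls,
                        category="primary",
                        size_tier=assign_size_tier(seg.size),
                    )
                )
    if any(f.category == "primary" for f in diagnosis.findings):
        diagnosis.stage = "lowpass"
        return diagnosis

    # ---- stage 2: SNV interpretation
    terms = bundle.phenotype_map.get(sample_id, set())
    candidates = build_candidate_genes(terms, resources.hpo_map, resources.ontology) if terms else set()
    mine = bundle.variants[bundle.variants["sample"] == sample_id]
    shortlist = filter_snvs_for_diagnosis(mine, candidates, th)
    male = sample.sex == "M"
    for row in shortlist.itertuples(index=False):
        key = (row.sample, row.chrom, row.pos, row.ref, row.alt)
        tags = resources.evidence_tags.get(key, ())
        if not tags:
            continue  # untagged variants stay VUS and are not reportable
        cls = classify_variant(tags)
        if cls not in ("P", "LP"):
            continue
        zyg = "hemi" if (male and row.chrom == "chrX" and row.zygosity == "het") else row.zygosity
        finding = Finding(
            sample_id=sample_id,
            kind="snv",
            gene=row.gene,
            label=f"{row.gene}:{row.chrom}:{row.pos}{row.ref}>{row.alt}",
            tier_class=cls,
            zygosity=zyg,
            inheritance=resources.gene_inheritance.get(row.gene, ""),
            evidence=tags,
        )
        finding.category = assign_finding_category(
            finding, phenotype_relevant=row.gene in candidates,
            sf_gene_list=resources.sf_gene_list, gene_inheritance=resources.gene_inheritance,
        )
        diagnosis.findings.append(finding)
    if any(f.category == "primary" for f in diagnosis.findings):
        diagnosis.stage = "snv"
        return diagnosis

    # ---- stage 3: small CNVs
    small = [
        c for c in _sample_cnv_calls(bundle, sample_id) if 50 <= c.size < 100_000
    ]
    for call in triage_small_cnvs(small, resources.exon_map, th):
        points = _cnv_evidence_points(call, resources.exon_map, resources)
        cls = score_cnv(points, th)
        if cls not in ("P", "LP"):
            continue
        genes = ",".join(call.genes)
        diagnosis.findings.append(
            Finding(
                sample_id=sample_id,
                kind="intragenic_cnv",
                gene=call.genes[0] if call.genes else "",
                label=call.event_string() + (f" {genes}" if genes else ""),
                tier_class=cls,
                category="primary",
                size_tier="intragenic",
            )
        )
    if any(f.category == "primary" for f in diagnosis.findings):
        diagnosis.stage = "small_cnv"
    return diagnosis


def _sample_cnv_calls(bundle: CohortBundle, sample_id: str) -> list[CnvCall]:
    from .core import table_to_cnv_calls

    sub = bundle.cnvs[bundle.cnvs["sample"] == sample_id]
    return table_to_cnv_calls(sub) if len(sub) else []


def triage_cohort(
    bundle: CohortBundle,
    resources: TriageResources,
    th: Thresholds = DEFAULT_THRESHOLDS,
    arm: str = "case",
) -> list[Diagnosis]:
    """Cascade every sample of one arm; order follows the sample list."""
    return [triage_sample(sid, bundle, resources, th) for sid in bundle.arm_ids(arm)]
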