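"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a prenatal case--control WGS study: binned low-pass
read depth with GC bias and overdispersed count noise, background small
variants with a population-frequency spectrum concentrated near zero,
phenotype-term assignments against a toy ontology, spiked pathogenic events
(whole-chromosome aneuploidies, segmental CNVs, diagnostic SNVs, intragenic
CNVs), and a tunable excess of cohort-unique loss-of-function variants in
cases. Every spiked event is recorded in a truth table and recoverable from
the emitted data by coordinates.

The synthetic genome is a 24-chromosome model at 1/20 of human scale so that
full cohort runs finish in seconds; chromosome proportions follow the human
assembly. With ``slofv_case_excess = 0`` cases and controls are exchangeable
draws from the same background model.

Randomness: one global integer seed; each sample owns a generator stream
derived from (seed, arm, sample index), so a sample's data is reproducible
under changes of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CnvCall,
    CohortBundle,
    DepthProfile,
    SampleRecord,
    VARIANT_COLUMNS,
    cnv_calls_to_table,
    empty_cnv_table,
    empty_variant_table,
)
from .io_formats import IntervalMap
from .lowpass_screen import assign_size_tier

# ---------------------------------------------------------------------------
# Synthetic genome
# ---------------------------------------------------------------------------

_HG19_LENGTHS = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560, "chrY": 59_373_566,
}

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

PHENOTYPE_LABELS = (
    "hydrocephalus", "neural_tube_defect", "ventriculomegaly",
    "aplasia_corpus_callosum", "holoprosencephaly", "cerebellar_hypoplasia",
    "dandy_walker", "intracranial_cyst", "microcephaly",
    "destructive_lesion", "abnormal_echo",
)


class SyntheticGenome:
    """Reduced 24-chromosome genome; human proportions at 1/scale size."""

    def __init__(self, scale: float = 20.0, bin_width: int = 100_000) -> None:
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.scale = scale
        self.bin_width = int(bin_width)
        self.lengths = {
            c: max(int(L / scale) // self.bin_width * self.bin_width, 2 * self.bin_width)
            for c, L in _HG19_LENGTHS.items()
        }

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def n_bins(self, chrom: str) -> int:
        return self.lengths[chrom] // self.bin_width

    def bin_table(self) -> pd.DataFrame:
        """Bin skeleton (chrom, start, end, gc); GC is a deterministic smooth
        wave shared by every sample, so GC bias is a reproducible artefact."""
        rows = []
        offset = 0
        for chrom in self.chroms:
            n = self.n_bins(chrom)
            j = np.arange(n) + offset
            gc = 0.42 + 0.06 * np.sin(2 * np.pi * j / 53.0) + 0.03 * np.sin(2 * np.pi * j / 7.3)
            starts = np.arange(n, dtype=np.int64) * self.bin_width
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + self.bin_width,
                        "gc": np.clip(gc, 0.2, 0.7),
                    }
                )
            )
            offset += n
        return pd.concat(rows, ignore_index=True)

    def default_karyotype(self, sex: str) -> dict[str, int]:
        karyo = {c: 2 for c in AUTOSOMES}
        karyo["chrX"] = 2 if sex == "F" else 1
        karyo["chrY"] = 0 if sex == "F" else 1
        return karyo


# ---------------------------------------------------------------------------
# Toy annotation resources (exon map, ontology, gene panels)
# ---------------------------------------------------------------------------


@dataclass
class ToyResources:
    """Deterministic annotation stand-ins sized to the synthetic genome."""

    exon_map: IntervalMap  # 0-based half-open exon intervals, label = gene
    genes: list[str]
    gene_locus: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end), 0-based
    ontology: dict[str, list[str]]  # term -> parents
    hpo_gene_map: dict[str, set[str]]  # term -> annotated genes
    phenotype_terms: dict[str, str]  # phenotype label -> top-level term
    sf_gene_list: set[str]  # secondary-findings reporting panel
    gene_inheritance: dict[str, str]  # gene -> AD/AR/XL/XLD
    pcp_panel: tuple[str, ...]  # planar-cell-polarity panel genes


def make_resources(genome: SyntheticGenome, seed: int = 7) -> ToyResources:
    """Build exon map, toy ontology, and gene panels for a synthetic genome.

    Genes are laid out every 150 kb, each with 5 exons of 300 bp; each
    phenotype label owns one top-level term with three child terms, and genes
    are annotated to terms so that descendant closure matters (children carry
    genes the parent annotation does not).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E0]))
    exons: list[tuple[str, int, int, str]] = []
    genes: list[str] = []
    locus: dict[str, tuple[str, int, int]] = {}
    for ci, chrom in enumerate(genome.chroms, start=1):
        n_genes = max(genome.lengths[chrom] // 150_000, 1)
        for g in range(n_genes):
            name = f"G{ci}_{g:04d}"
            gstart = g * 150_000 + 20_000
            gend = gstart + 5 * 300 + 4 * 1_700
            if gend >= genome.lengths[chrom]:
                continue
            genes.append(name)
            locus[name] = (chrom, gstart, gend)
            for e in range(5):
                es = gstart + e * 2_000
                exons.append((chrom, es, es + 300, f"{name}_exon{e + 1}"))

    root = "T:root"
    ontology: dict[str, list[str]] = {root: []}
    hpo_gene_map: dict[str, set[str]] = {root: set()}
    phenotype_terms: dict[str, str] = {}
    for label in PHENOTYPE_LABELS:
        top = f"T:{label}"
        ontology[top] = [root]
        phenotype_terms[label] = top
        top_genes = set(rng.choice(genes, size=25, replace=False))
        hpo_gene_map[top] = top_genes
        for k in range(3):
            child = f"T:{label}:sub{k}"
            ontology[child] = [top]
            hpo_gene_map[child] = set(rng.choice(genes, size=10, replace=False))

    sf_gene_list = set(rng.choice(genes, size=40, replace=False))
    modes = rng.choice(["AD", "AR", "XL", "XLD"], size=len(genes), p=[0.6, 0.25, 0.08, 0.07])
    gene_inheritance = dict(zip(genes, modes))
    pcp_panel = tuple(sorted(rng.choice(genes, size=13, replace=False)))
    return ToyResources(
        exon_map=IntervalMap(exons),
        genes=genes,
        gene_locus=locus,
        ontology=ontology,
        hpo_gene_map=hpo_gene_map,
        phenotype_terms=phenotype_terms,
        sf_gene_list=sf_gene_list,
        gene_inheritance=gene_inheritance,
        pcp_panel=pcp_panel,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeSpec:
    """One engineered pathogenic event.

    ``kind`` is aneuploidy | cnv | snv | intragenic_cnv. ``target`` is the
    0-based index into the case arm. CNV sizes must respect their tier:
    cnv >= 100 kb, intragenic_cnv in [50 bp, 100 kb).
    """

    kind: str
    target: int
    chrom: str = ""
    start: int = 0  # 1-based inclusive for CNV kinds
    end: int = 0
    copy_number: int = 2
    gene: str = ""
    consequence: str = "frameshift"
    tier_class: str = "P"
    syndrome: str = ""
    evidence: tuple[str, ...] = ("PVS1", "PM2", "PP4")

    def __post_init__(self) -> None:
        if self.kind not in ("aneuploidy", "cnv", "snv", "intragenic_cnv"):
            raise ValueError(f"unknown spike kind {self.kind!r}")
        if self.kind in ("cnv", "intragenic_cnv"):
            size = self.end - self.start + 1
            if self.kind == "cnv" and size < 100_000:
                raise ValueError("cnv spikes must be >= 100 kb")
            if self.kind == "intragenic_cnv" and not (50 <= size < 100_000):
                raise ValueError("intragenic_cnv spikes must be in [50 bp, 100 kb)")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for cohort simulation.

    Defaults emulate the burden-analysis arm of the study design: 136 deeply
    sequenced cases against 200 population controls, background private
    variation of ~114 small variants per sample in the QC-relevant classes,
    and an excess of 4.2 cohort-unique loss-of-function variants per case
    (calibrated so case/control singleton-LoF medians land near 13.5 vs 9).
    """

    n_cases: int = 136
    n_controls: int = 200
    seed: int = 0
    bin_width: int = 100_000
    mean_reads_per_bin: float = 500.0
    nb_alpha: float = 0.005  # NB overdispersion; 0 -> Poisson
    gc_curvature: float = 30.0  # quadratic GC droop strength
    gc_optimum: float = 0.42
    background_snv_rate: float = 114.0  # expected private variants / sample
    shared_panel_size: int = 300  # polymorphic sites shared across samples
    slofv_case_excess: float = 4.2  # extra singleton LoF per case (Poisson mean)
    maf_zero_weight: float = 0.6  # P(private variant absent from references)
    maf_beta: tuple[float, float] = (0.5, 600.0)  # nonzero-MAF Beta spectrum
    spike_specs: tuple[SpikeSpec, ...] = ()
    genome_scale: float = 20.0
    make_depth: bool = True

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.slofv_case_excess < 0:
            raise ValueError("slofv_case_excess must be >= 0")
        for spike in self.spike_specs:
            if not (0 <= spike.target < max(self.n_cases, 1)):
                raise ValueError(f"spike target {spike.target} outside case arm 0..{self.n_cases - 1}")


def _sample_rng(seed: int, arm: str, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 0 if arm == "case" else 1, int(index)]))


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------


def generate_depth_profile(
    karyotype: dict[str, int],
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "S0",
    genome: SyntheticGenome | None = None,
    cnv_regions: list[tuple[str, int, int, int]] | None = None,
    gc_bias: bool = True,
) -> DepthProfile:
    """Binned low-pass read counts for one sample.

    Per-bin counts are negative-binomial with mean proportional to the local
    copy number (copies / 2) and a smooth quadratic GC-bias droop; karyotype
    copy counts must lie in {0..4}. ``cnv_regions`` is a list of
    (chrom, start_1b, end_1b, copy) segmental overrides.
    """
    if config.mean_reads_per_bin <= 0:
        raise ValueError("mean_reads_per_bin must be positive")
    for c, k in karyotype.items():
        if k not in (0, 1, 2, 3, 4):
            raise ValueError(f"copy count {k} for {c} outside 0..4")
    genome = genome or SyntheticGenome(config.genome_scale, config.bin_width)
    bins = genome.bin_table()
    copies = bins["chrom"].map(lambda c: karyotype.get(c, 2)).to_numpy(dtype=float)
    if cnv_regions:
        starts = bins["start"].to_numpy()
        ends = bins["end"].to_numpy()
        chroms = bins["chrom"].to_numpy()
        for chrom, s1, e1, cn in cnv_regions:
            mask = (chroms == chrom) & (starts >= s1 - 1) & (ends <= e1)
            copies[mask] = cn
    mu = config.mean_reads_per_bin * (copies / 2.0)
    if gc_bias:
        droop = 1.0 - config.gc_curvature * (bins["gc"].to_numpy() - config.gc_optimum) ** 2
        mu = mu * np.clip(droop, 0.2, None)
    if config.nb_alpha > 0:
        lam = np.where(mu > 0, rng.gamma(1.0 / config.nb_alpha, config.nb_alpha * np.maximum(mu, 1e-12)), 0.0)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    bins = bins.copy()
    bins["count"] = counts.astype(np.int64)
    return DepthProfile(sample_id=sample_id, bins=bins[["chrom", "start", "end", "count", "gc"]], bin_width=config.bin_width)


# ---------------------------------------------------------------------------
# Background small variants
# ---------------------------------------------------------------------------

_CSQ = np.array(
    ["missense", "synonymous", "intronic", "noncoding", "inframe_indel",
     "nonsense", "frameshift", "canonical_splice", "stop_loss"]
)
_CSQ_P = np.array([0.38, 0.20, 0.12, 0.08, 0.12, 0.03, 0.04, 0.02, 0.01])
_BASES = np.array(["A", "C", "G", "T"])
_INDEL_SPAN = np.array([2, 3, 4, 5, 7, 11])
_INDEL_SPAN_P = np.array([0.35, 0.25, 0.20, 0.10, 0.06, 0.04])


def _draw_private_variants(
    rng: np.random.Generator,
    n: int,
    sample_id: str,
    config: SimConfig,
    genome: SyntheticGenome,
    resources: ToyResources,
) -> dict[str, np.ndarray]:
    """Vectorised draw of one sample's private background variants."""
    chroms = np.array(genome.chroms)
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n, p=lens / lens.sum())
    pos = (rng.random(n) * (lens[ci] - 100)).astype(np.int64) + 1
    csq = rng.choice(_CSQ, size=n, p=_CSQ_P)

    # genes: coding-class variants get a gene near their position
    gene = np.array([""] * n, dtype=object)
    coding = csq != "noncoding"
    gene_ids = np.array(resources.genes)
    if coding.any():
        gene[coding] = gene_ids[rng.integers(0, len(gene_ids), size=int(coding.sum()))]

    ref = rng.choice(_BASES, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
    ref = ref.astype(object)
    alt = alt.astype(object)
    indel = np.isin(csq, ["frameshift", "inframe_indel"])
    if indel.any():
        spans = rng.choice(_INDEL_SPAN, size=int(indel.sum()), p=_INDEL_SPAN_P)
        is_del = rng.random(int(indel.sum())) < 0.5
        idx = np.flatnonzero(indel)
        for j, span, d in zip(idx, spans, is_del):
            if d:
                ref[j] = str(ref[j]) * int(span)
                alt[j] = str(ref[j])[0]
            else:
                alt[j] = str(alt[j]) * int(span)

    # depth / allele depth; a small fraction is shallow and fails QC
    dp = rng.poisson(42, size=n)
    shallow = rng.random(n) < 0.04
    dp[shallow] = rng.poisson(12, size=int(shallow.sum()))
    dp = np.maximum(dp, 1)
    zyg = np.where(rng.random(n) < 0.95, "het", "hom").astype(object)
    p_alt = np.where(zyg == "het", 0.5, 0.95)
    ad = rng.binomial(dp, p_alt)

    # population frequency: point mass at 0 plus a Beta spectrum near 0
    a, b = config.maf_beta
    af = np.where(rng.random(n) < config.maf_zero_weight, 0.0, rng.beta(a, b, size=n))
    af_inhouse = np.where(af > 0, np.clip(af * rng.lognormal(0, 0.3, size=n), 0, 1), 0.0)

    # in-silico scores: only missense variants get the damaging panel
    cadd = np.full(n, np.nan)
    mcap = np.full(n, np.nan)
    revel = np.full(n, np.nan)
    sift = np.array(["missing"] * n, dtype=object)
    mis = csq == "missense"
    n_mis = int(mis.sum())
    if n_mis:
        damaging = rng.random(n_mis) < 0.25
        cadd[mis] = np.where(damaging, rng.uniform(20.5, 40, n_mis), rng.uniform(0, 20, n_mis))
        mcap[mis] = np.where(damaging, rng.uniform(0.03, 0.3, n_mis), rng.uniform(0, 0.025, n_mis))
        revel[mis] = np.where(damaging, rng.uniform(0.55, 0.95, n_mis), rng.uniform(0, 0.5, n_mis))
        sift[mis] = np.where(damaging, "damaging", rng.choice(["tolerated", "missing"], size=n_mis))

    return {
        "sample": np.array([sample_id] * n, dtype=object),
        "chrom": chroms[ci].astype(object),
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "zygosity": zyg,
        "dp": dp.astype(np.int64),
        "ad_alt": ad.astype(np.int64),
        "gene": gene,
        "consequence": csq.astype(object),
        "sift_class": sift,
        "cadd": cadd,
        "mcap": mcap,
        "revel": revel,
        "af_public": af,
        "af_inhouse": af_inhouse,
    }


def _panel_sites(config: SimConfig, genome: SyntheticGenome, resources: ToyResources) -> pd.DataFrame:
    """Shared polymorphic sites (cohort-level, seed-determined)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11]))
    n = config.shared_panel_size
    chroms = np.array(genome.chroms)
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n, p=lens / lens.sum())
    pos = (rng.random(n) * (lens[ci] - 100)).astype(np.int64) + 1
    ref = rng.choice(_BASES, size=n)
    alt = _BASES[(np.searchsorted(_BASES, ref) + rng.integers(1, 4, size=n)) % 4]
    af = rng.beta(0.4, 8.0, size=n)
    csq = rng.choice(_CSQ, size=n, p=_CSQ_P)
    gene_ids = np.array(resources.genes)
    gene = gene_ids[rng.integers(0, len(gene_ids), size=n)].astype(object)
    gene[csq == "noncoding"] = ""
    return pd.DataFrame(
        {"chrom": chroms[ci], "pos": pos, "ref": ref, "alt": alt, "af": af, "consequence": csq, "gene": gene}
    )


def _draw_panel_variants(
    rng: np.random.Generator, panel: pd.DataFrame, sample_id: str
) -> dict[str, np.ndarray] | None:
    carrier = rng.random(len(panel)) < np.minimum(2 * panel["af"].to_numpy(), 1.0)
    if not carrier.any():
        return None
    sub = panel.loc[carrier]
    n = len(sub)
    dp = np.maximum(rng.poisson(42, size=n), 1)
    ad = rng.binomial(dp, 0.5)
    return {
        "sample": np.array([sample_id] * n, dtype=object),
        "chrom": sub["chrom"].to_numpy(dtype=object),
        "pos": sub["pos"].to_numpy(),
        "ref": sub["ref"].to_numpy(dtype=object),
        "alt": sub["alt"].to_numpy(dtype=object),
        "zygosity": np.array(["het"] * n, dtype=object),
        "dp": dp.astype(np.int64),
        "ad_alt": ad.astype(np.int64),
        "gene": sub["gene"].to_numpy(dtype=object),
        "consequence": sub["consequence"].to_numpy(dtype=object),
        "sift_class": np.array(["missing"] * n, dtype=object),
        "cadd": np.full(n, np.nan),
        "mcap": np.full(n, np.nan),
        "revel": np.full(n, np.nan),
        "af_public": sub["af"].to_numpy(),
        "af_inhouse": sub["af"].to_numpy(),
    }


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def generate_cohort(
    config: SimConfig, resources: ToyResources | None = None
) -> tuple[CohortBundle, ToyResources]:
    """Simulate a full case--control cohort.

    Returns the bundle (with a ``truth`` table of all spiked events) and the
    annotation resources it was generated against. Cases and controls share
    the background model; only ``slofv_case_excess`` and spikes differ.
    """
    genome = SyntheticGenome(config.genome_scale, config.bin_width)
    resources = resources or make_resources(genome)
    panel = _panel_sites(config, genome, resources) if config.shared_panel_size else None
    cohort_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))

    samples: list[SampleRecord] = []
    phenotype_map: dict[str, set[str]] = {}
    chunks: list[dict[str, np.ndarray]] = []
    truth_rows: list[dict] = []
    cnv_calls: list[CnvCall] = []
    spikes_by_target: dict[int, list[SpikeSpec]] = {}
    for spike in config.spike_specs:
        spikes_by_target.setdefault(spike.target, []).append(spike)

    used_keys: set[tuple[str, int, str, str]] = set()

    def _arm_samples(arm: str, count: int, prefix: str):
        for i in range(count):
            sid = f"{prefix}{i + 1:04d}"
            rng = _sample_rng(config.seed, arm, i)
            sex = "F" if i % 2 == 0 else "M"
            phenos: tuple[str, ...] = ()
            terms: set[str] = set()
            if arm == "case":
                k = 1 + int(rng.random() < 0.3)
                labels = cohort_rng.choice(PHENOTYPE_LABELS, size=k, replace=False)
                phenos = tuple(labels)
                terms = {resources.phenotype_terms[p] for p in phenos}
            samples.append(SampleRecord(sid, arm=arm, sex=sex, phenotypes=phenos))
            phenotype_map[sid] = terms

            n_bg = int(rng.poisson(config.background_snv_rate))
            if n_bg:
                chunks.append(_draw_private_variants(rng, n_bg, sid, config, genome, resources))
            if panel is not None:
                pv = _draw_panel_variants(rng, panel, sid)
                if pv is not None:
                    chunks.append(pv)

            karyotype = genome.default_karyotype(sex)
            cnv_regions: list[tuple[str, int, int, int]] = []
            if arm == "case":
                for spike in spikes_by_target.get(i, []):
                    _apply_spike(
                        spike, sid, rng, config, genome, resources,
                        karyotype, cnv_regions, chunks, truth_rows, cnv_calls, used_keys,
                        sample_terms=terms,
                    )
            if config.slofv_case_excess > 0 and arm == "case":
                _add_slofv(rng, sid, config, genome, resources, chunks, truth_rows, used_keys)
            if config.make_depth:
                profile = generate_depth_profile(
                    karyotype, config, rng, sample_id=sid, genome=genome, cnv_regions=cnv_regions
                )
                depth_profiles[sid] = profile

    depth_profiles: dict[str, DepthProfile] = {}
    _arm_samples("case", config.n_cases, "C")
    _arm_samples("control", config.n_controls, "K")

    variants = _assemble(chunks) if chunks else empty_variant_table()
    variants = _dedupe(variants)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "kind", "chrom", "start", "end", "gene", "consequence",
                 "copy_number", "tier_class", "label", "evidence"],
    )
    bundle = CohortBundle(
        samples=samples,
        variants=variants,
        cnvs=cnv_calls_to_table(cnv_calls, [assign_size_tier(c.size) for c in cnv_calls]),
        depth_profiles=depth_profiles,
        phenotype_map=phenotype_map,
        truth=truth,
    )
    return bundle, resources


def _assemble(chunks: list[dict[str, np.ndarray]]) -> pd.DataFrame:
    cols = {c: np.concatenate([ch[c] for ch in chunks]) for c in VARIANT_COLUMNS}
    return pd.DataFrame(cols)


def _dedupe(variants: pd.DataFrame) -> pd.DataFrame:
    return variants.drop_duplicates(subset=["sample", "chrom", "pos", "ref", "alt"], keep="first").reset_index(
        drop=True
    )


def _unique_position(
    rng: np.random.Generator,
    genome: SyntheticGenome,
    used: set[tuple[str, int, str, str]],
) -> tuple[str, int, str, str]:
    chroms = list(genome.chroms)
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    p = lens / lens.sum()
    while True:
        chrom = chroms[int(rng.choice(len(chroms), p=p))]
        pos = int(rng.integers(1, genome.lengths[chrom] - 100))
        ref = str(rng.choice(_BASES))
        alt = str(_BASES[(int(np.searchsorted(_BASES, ref)) + int(rng.integers(1, 4))) % 4])
        key = (chrom, pos, ref, alt)
        if key not in used:
            used.add(key)
            return key


def _apply_spike(
    spike: SpikeSpec,
    sid: str,
    rng: np.random.Generator,
    config: SimConfig,
    genome: SyntheticGenome,
    resources: ToyResources,
    karyotype: dict[str, int],
    cnv_regions: list,
    chunks: list,
    truth_rows: list,
    cnv_calls: list,
    used_keys: set,
    sample_terms: set[str] = frozenset(),
) -> None:
    if spike.kind == "aneuploidy":
        cn = spike.copy_number if spike.copy_number != 2 else 3
        karyotype[spike.chrom] = cn
        truth_rows.append(
            dict(sample=sid, kind="aneuploidy", chrom=spike.chrom, start=1,
                 end=genome.lengths[spike.chrom], gene="", consequence="",
                 copy_number=cn, tier_class=spike.tier_class,
                 label=("+" if cn > 2 else "-") + spike.chrom.removeprefix("chr"),
                 evidence="")
        )
    elif spike.kind == "cnv":
        cn = spike.copy_number if spike.copy_number != 2 else 1
        cnv_regions.append((spike.chrom, spike.start, spike.end, cn))
        truth_rows.append(
            dict(sample=sid, kind="cnv", chrom=spike.chrom, start=spike.start,
                 end=spike.end, gene="", consequence="", copy_number=cn,
                 tier_class=spike.tier_class, label=spike.syndrome, evidence="")
        )
    elif spike.kind == "intragenic_cnv":
        cn = spike.copy_number if spike.copy_number != 2 else 1
        genes = tuple(
            sorted({lab.rsplit("_exon", 1)[0] for _, _, _, lab in
                    resources.exon_map.overlapping(spike.chrom, spike.start - 1, spike.end)})
        )
        cnv_calls.append(
            CnvCall(sample_id=sid, chrom=spike.chrom, start=spike.start, end=spike.end,
                    copy_number=cn, genes=genes, freq_inhouse=0.0, label=spike.syndrome)
        )
        truth_rows.append(
            dict(sample=sid, kind="intragenic_cnv", chrom=spike.chrom, start=spike.start,
                 end=spike.end, gene=",".join(genes), consequence="", copy_number=cn,
                 tier_class=spike.tier_class, label=spike.syndrome, evidence="")
        )
    else:  # snv
        gene = spike.gene
        if not gene:
            # pick a gene annotated to one of the sample's phenotype terms so
            # the event survives candidate-gene filtering
            pool: set[str] = set()
            for term in sample_terms:
                pool |= resources.hpo_gene_map.get(term, set())
            if not pool:
                pool = resources.hpo_gene_map[next(iter(sorted(resources.hpo_gene_map)))]
            gene = sorted(pool)[int(rng.integers(0, len(pool)))]
        chrom, gstart, _ = resources.gene_locus[gene]
        pos = int(gstart + 1 + rng.integers(0, 300))
        ref = str(rng.choice(_BASES))
        alt = str(_BASES[(int(np.searchsorted(_BASES, ref)) + 1) % 4])
        key = (chrom, pos, ref, alt)
        used_keys.add(key)
        dp = max(int(rng.poisson(42)), 20)
        chunks.append(
            {
                "sample": np.array([sid], dtype=object),
                "chrom": np.array([chrom], dtype=object),
                "pos": np.array([pos], dtype=np.int64),
                "ref": np.array([ref], dtype=object),
                "alt": np.array([alt], dtype=object),
                "zygosity": np.array(["het"], dtype=object),
                "dp": np.array([dp], dtype=np.int64),
                "ad_alt": np.array([max(dp // 2, 3)], dtype=np.int64),
                "gene": np.array([gene], dtype=object),
                "consequence": np.array([spike.consequence], dtype=object),
                "sift_class": np.array(["missing"], dtype=object),
                "cadd": np.array([np.nan]),
                "mcap": np.array([np.nan]),
                "revel": np.array([np.nan]),
                "af_public": np.array([0.0]),
                "af_inhouse": np.array([0.0]),
            }
        )
        truth_rows.append(
            dict(sample=sid, kind="snv", chrom=chrom, start=pos, end=pos, gene=gene,
                 consequence=spike.consequence, copy_number=2, tier_class=spike.tier_class,
                 label=spike.syndrome, evidence=",".join(spike.evidence))
        )


def _add_slofv(
    rng: np.random.Generator,
    sid: str,
    config: SimConfig,
    genome: SyntheticGenome,
    resources: ToyResources,
    chunks: list,
    truth_rows: list,
    used_keys: set,
) -> None:
    n = int(rng.poisson(config.slofv_case_excess))
    if n == 0:
        return
    lof_csq = np.array(["nonsense", "frameshift", "canonical_splice", "stop_loss"])
    gene_ids = np.array(resources.genes)
    for _ in range(n):
        chrom, pos, ref, alt = _unique_position(rng, genome, used_keys)
        csq = str(rng.choice(lof_csq))
        if csq == "frameshift":  # short, QC-passing indel
            ref = ref * int(rng.integers(2, 5))
            alt = ref[0]
        dp = max(int(rng.poisson(42)), 20)
        gene = str(gene_ids[int(rng.integers(0, len(gene_ids)))])
        chunks.append(
            {
                "sample": np.array([sid], dtype=object),
                "chrom": np.array([chrom], dtype=object),
                "pos": np.array([pos], dtype=np.int64),
                "ref": np.array([ref], dtype=object),
                "alt": np.array([alt], dtype=object),
                "zygosity": np.array(["het"], dtype=object),
                "dp": np.array([dp], dtype=np.int64),
                "ad_alt": np.array([max(dp // 2, 3)], dtype=np.int64),
                "gene": np.array([gene], dtype=object),
                "consequence": np.array([csq], dtype=object),
                "sift_class": np.array(["missing"], dtype=object),
                "cadd": np.array([np.nan]),
                "mcap": np.array([np.nan]),
                "revel": np.array([np.nan]),
                "af_public": np.array([0.0]),
                "af_inhouse": np.array([0.0]),
            }
        )
        truth_rows.append(
            dict(sample=sid, kind="slofv", chrom=chrom, start=pos, end=pos, gene=gene,
                 consequence=csq, copy_number=2, tier_class="", label="slofv_excess", evidence="")
        )


def spike_slofv_excess(bundle: CohortBundle, rate: float, seed: int) -> CohortBundle:
    """Add a Poisson(``rate``) number of cohort-unique, QC-passing
    loss-of-function variants to every case sample of an existing bundle."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return bundle
    genome = SyntheticGenome()
    resources = make_resources(genome)
    cfg = SimConfig(seed=seed, slofv_case_excess=rate, make_depth=False)
    used = set(zip(bundle.variants["chrom"], bundle.variants["pos"], bundle.variants["ref"], bundle.variants["alt"]))
    chunks: list = []
    truth_rows: list = []
    for i, sid in enumerate(bundle.arm_ids("case")):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51F, i]))
        _add_slofv(rng, sid, cfg, genome, resources, chunks, truth_rows, used)
    if not chunks:
        return bundle
    new = _assemble(chunks)
    variants = pd.concat([bundle.variants, new], ignore_index=True)
    truth = pd.concat([bundle.truth, pd.DataFrame(truth_rows)], ignore_index=True) if bundle.truth is not None else pd.DataFrame(truth_rows)
    return CohortBundle(
        samples=bundle.samples,
        variants=variants,
        cnvs=bundle.cnvs,
        depth_profiles=bundle.depth_profiles,
        phenotype_map=bundle.phenotype_map,
        truth=truth,
    )
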