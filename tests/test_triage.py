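"""Candidate-gene closure, SNV filtering, the rule engine, CNV scoring,
finding categories and the cascade's stage exclusivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnstriage.core import CnvCall, Finding
from cnstriage.io_formats import IntervalMap
from cnstriage.synthetic_cohort import SimConfig, SpikeSpec, generate_cohort
from cnstriage.triage import (
    DEFAULT_THRESHOLDS,
    build_candidate_genes,
    build_triage_resources,
    assign_finding_category,
    classify_variant,
    filter_snvs_for_diagnosis,
    score_cnv,
    triage_cohort,
    triage_sample,
    triage_small_cnvs,
)

# ---------------------------------------------------------------------------
# Candidate genes
# ---------------------------------------------------------------------------


def random_ontology(rng, n_terms=100):
    terms = [f"T{i}" for i in range(n_terms)]
    ontology = {terms[0]: []}
    for i in range(1, n_terms):
        parent = terms[int(rng.integers(0, i))]
        ontology[terms[i]] = [parent]
    hpo_map = {t: {f"G{int(g)}" for g in rng.integers(0, 400, size=rng.integers(0, 6))} for t in terms}
    return terms, ontology, hpo_map


def brute_force_candidates(query, ontology, hpo_map):
    # transitive closure by repeated parent expansion
    genes = set()
    for term in query:
        closure = {term}
        changed = True
        while changed:
            changed = False
            for t, parents in ontology.items():
                if t not in closure and any(p in closure for p in parents):
                    closure.add(t)
                    changed = True
        for t in closure:
            genes |= set(hpo_map.get(t, ()))
    return genes


class TestCandidateGenes:
    def test_empty_terms_empty_genes(self):
        assert build_candidate_genes([], {}, {"T0": []}) == set()

    def test_single_term_without_descendants(self):
        ontology = {"T0": [], "T1": ["T0"]}
        hpo_map = {"T1": {"TUBA1A", "ARX"}}
        assert build_candidate_genes(["T1"], hpo_map, ontology) == {"TUBA1A", "ARX"}

    def test_matches_brute_force_union_on_random_ontology(self, rng):
        terms, ontology, hpo_map = random_ontology(rng)
        for _ in range(20):
            query = list(rng.choice(terms, size=int(rng.integers(1, 5)), replace=False))
            assert build_candidate_genes(query, hpo_map, ontology) == brute_force_candidates(
                query, ontology, hpo_map
            )

    def test_unknown_term_raises_naming_it(self):
        with pytest.raises(KeyError, match="T:nonexistent"):
            build_candidate_genes(["T:nonexistent"], {}, {"T0": []})

    def test_adding_a_term_never_shrinks_the_set(self, rng):
        terms, ontology, hpo_map = random_ontology(rng, n_terms=50)
        base = list(rng.choice(terms, size=3, replace=False))
        got = build_candidate_genes(base, hpo_map, ontology)
        for extra in terms[:10]:
            grown = build_candidate_genes(base + [extra], hpo_map, ontology)
            assert got <= grown


# ---------------------------------------------------------------------------
# SNV shortlist
# ---------------------------------------------------------------------------


def random_variant_frame(rng, n):
    csq = rng.choice(
        ["missense", "nonsense", "frameshift", "canonical_splice", "stop_loss",
         "synonymous", "intronic", "noncoding", "inframe_indel"], size=n)
    return pd.DataFrame({
        "sample": "S1",
        "chrom": "chr1",
        "pos": np.arange(1, n + 1),
        "ref": "A",
        "alt": "T",
        "gene": rng.choice(["G1", "G2", "G3", ""], size=n),
        "consequence": csq,
        "af_public": np.where(rng.random(n) < 0.4, 0.0, rng.random(n) * 0.05),
        "af_inhouse": np.where(rng.random(n) < 0.4, 0.0, rng.random(n) * 0.05),
    })


class TestSnvFilter:
    def test_common_variant_excluded(self):
        df = random_variant_frame(np.random.default_rng(0), 1)
        df.loc[0, ["af_public", "af_inhouse", "gene", "consequence"]] = [0.02, 0.0, "G1", "missense"]
        assert len(filter_snvs_for_diagnosis(df, {"G1"})) == 0

    def test_canonical_splice_survives_intron_filter(self):
        df = random_variant_frame(np.random.default_rng(0), 1)
        df.loc[0, ["af_public", "af_inhouse", "gene", "consequence"]] = [0.0, 0.0, "G1", "canonical_splice"]
        assert len(filter_snvs_for_diagnosis(df, {"G1"})) == 1

    def test_matches_brute_force_predicate_on_random_variants(self, rng):
        df = random_variant_frame(rng, 10_000)
        candidates = {"G1", "G3"}
        got = filter_snvs_for_diagnosis(df, candidates)
        expected = [
            i for i, r in df.iterrows()
            if max(r.af_public, r.af_inhouse) <= 0.01
            and r.consequence not in ("intronic", "noncoding")
            and r.gene in candidates and r.gene != ""
        ]
        assert list(got.index) == expected


# ---------------------------------------------------------------------------
# Rule engine
# ---------------------------------------------------------------------------


def brute_force_class(tags):
    """Independent re-statement of the combining table from strength counts."""
    strengths = {"PVS": 0, "PS": 0, "PM": 0, "PP": 0, "BA": 0, "BS": 0, "BP": 0}
    for t in tags:
        for pre in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
            if t.startswith(pre) and t[len(pre):].isdigit() or t == pre:
                strengths[pre] += 1
                break
    vs, s, m, p = strengths["PVS"], strengths["PS"], strengths["PM"], strengths["PP"]
    ba, bs, bp = strengths["BA"], strengths["BS"], strengths["BP"]
    path = (vs and (s or m >= 2 or (m and p) or p >= 2)) or s >= 2 or (
        s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    lp = (vs and m) or (s == 1 and 1 <= m <= 2) or (s == 1 and p >= 2) or m >= 3 or (
        m == 2 and p >= 2) or (m == 1 and p >= 4)
    ben = ba >= 1 or bs >= 2
    lb = (bs == 1 and bp >= 1) or bp >= 2
    if (path or lp) and (ben or lb):
        return "VUS"
    if path:
        return "P"
    if lp:
        return "LP"
    if ben:
        return "B"
    if lb:
        return "LB"
    return "VUS"


class TestRuleEngine:
    def test_empty_evidence_is_vus(self):
        assert classify_variant([]) == "VUS"

    @pytest.mark.parametrize("tags,expected", [
        (["PVS1", "PM2", "PP4"], "P"),      # LoF + absent-from-controls + phenotype match
        (["PVS1", "PM2"], "LP"),
        (["PS1", "PS3"], "P"),
        (["PM1", "PM2", "PM4"], "LP"),
        (["BA1"], "B"),
        (["BS1", "BP4"], "LB"),
        (["PVS1", "BA1", "PM2"], "VUS"),    # conflicting evidence
    ])
    def test_known_combinations(self, tags, expected):
        assert classify_variant(tags) == expected

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="unknown evidence tag"):
            classify_variant(["PX9"])

    @given(st.lists(st.sampled_from(
        ["PVS1", "PS1", "PS2", "PS3", "PM1", "PM2", "PM3", "PP1", "PP2", "PP3", "PP4",
         "BA1", "BS1", "BS2", "BP1", "BP2"]), max_size=7))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_brute_force_table(self, tags):
        assert classify_variant(tags) == brute_force_class(tags)


class TestCnvScore:
    @pytest.mark.parametrize("points,expected", [
        (1.1, "P"), (0.99, "P"), (0.98, "LP"), (0.95, "LP"), (0.90, "LP"),
        (0.89, "VUS"), (0.0, "VUS"), (-0.90, "LB"), (-0.99, "B"),
    ])
    def test_class_bounds(self, points, expected):
        assert score_cnv(points) == expected


# ---------------------------------------------------------------------------
# Small-CNV assessment
# ---------------------------------------------------------------------------


class TestSmallCnvTriage:
    exon_map = IntervalMap([("chr1", 1000, 1300, "G_e1"), ("chr1", 5000, 5300, "G_e2")])

    def cnv(self, start, end, freq=0.0):
        return CnvCall("S1", "chr1", start, end, 1, freq_inhouse=freq)

    def test_no_exon_overlap_excluded(self):
        assert triage_small_cnvs([self.cnv(2000, 3000)], self.exon_map) == []

    def test_rare_exon_overlapping_retained(self):
        kept = triage_small_cnvs([self.cnv(900, 5060)], self.exon_map)
        assert len(kept) == 1

    def test_common_event_excluded(self):
        assert triage_small_cnvs([self.cnv(900, 1100, freq=0.02)], self.exon_map) == []

    def test_order_is_size_descending(self):
        kept = triage_small_cnvs([self.cnv(1100, 1200), self.cnv(900, 5100)], self.exon_map)
        assert [c.size for c in kept] == sorted((c.size for c in kept), reverse=True)

    def test_out_of_range_size_rejected(self):
        with pytest.raises(ValueError, match="50 bp"):
            triage_small_cnvs([self.cnv(1000, 200_000)], self.exon_map)

    def test_matches_brute_force_on_random_events(self, rng):
        ivs = [("chr1", int(s), int(s) + 300, f"e{k}") for k, s in enumerate(rng.integers(0, 500_000, 50))]
        emap = IntervalMap(ivs)
        events = [self.cnv(int(s) + 1, int(s) + int(w), float(f))
                  for s, w, f in zip(rng.integers(0, 500_000, 500),
                                     rng.integers(50, 99_999, 500),
                                     rng.random(500) * 0.02)]
        events = [e for e in events if e.size < 100_000]
        got = {(c.start, c.end) for c in triage_small_cnvs(events, emap)}
        expected = {
            (c.start, c.end) for c in events
            if c.freq_inhouse < 0.01 and any(iv[1] < c.end and iv[2] > c.start - 1 for iv in ivs)
        }
        assert got == expected


# ---------------------------------------------------------------------------
# Categories
# ---------------------------------------------------------------------------


class TestCategories:
    def fin(self, cls="P", gene="G1", zyg="het"):
        return Finding("S1", "snv", gene, "x", cls, zygosity=zyg)

    def test_relevant_pathogenic_is_primary(self):
        assert assign_finding_category(self.fin(), True, set(), {}) == "primary"

    def test_sf_list_gene_is_secondary(self):
        assert assign_finding_category(self.fin(), False, {"G1"}, {"G1": "AD"}) == "secondary"

    def test_het_in_recessive_gene_is_carrier(self):
        assert assign_finding_category(self.fin(), False, set(), {"G1": "AR"}) == "carrier"

    def test_truncating_ad_non_candidate_is_incidental(self):
        assert assign_finding_category(self.fin("LP"), False, set(), {"G1": "AD"}) == "incidental"

    def test_vus_gets_no_category(self):
        assert assign_finding_category(self.fin("VUS"), True, set(), {}) == "none"


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def spiked_cohort(resources):
    cfg = SimConfig(
        seed=31, n_cases=10, n_controls=0, background_snv_rate=30, slofv_case_excess=0.0,
        spike_specs=(
            SpikeSpec(kind="aneuploidy", target=0, chrom="chr21", copy_number=3),
            # stage-1 sample also carries a diagnostic-grade SNV: must never be interpreted
            SpikeSpec(kind="snv", target=0, consequence="frameshift"),
            SpikeSpec(kind="cnv", target=1, chrom="chr4", start=2_000_001, end=6_000_000, copy_number=1),
            SpikeSpec(kind="snv", target=2, consequence="nonsense"),
            # stage-2 sample also carries an assessable small CNV: stage 3 must not run
            SpikeSpec(kind="snv", target=3, consequence="frameshift"),
            SpikeSpec(kind="intragenic_cnv", target=3, chrom="chr1", start=20_101, end=21_000, copy_number=1),
            SpikeSpec(kind="intragenic_cnv", target=4, chrom="chr1", start=170_101, end=171_000, copy_number=1),
        ),
    )
    bundle, res = generate_cohort(cfg, resources)
    tri = build_triage_resources(res, bundle)
    return bundle, tri, triage_cohort(bundle, tri)


class TestCascade:
    def test_stage_assignment(self, spiked_cohort):
        _, _, diagnoses = spiked_cohort
        stages = {d.sample_id: d.stage for d in diagnoses}
        assert stages["C0001"] == "lowpass"
        assert stages["C0002"] == "lowpass"
        assert stages["C0003"] == "snv"
        assert stages["C0004"] == "snv"
        assert stages["C0005"] == "small_cnv"
        assert all(stages[f"C{i:04d}"] == "undiagnosed" for i in range(6, 11))

    def test_lowpass_diagnosed_sample_has_no_snv_findings(self, spiked_cohort):
        _, _, diagnoses = spiked_cohort
        d = next(d for d in diagnoses if d.sample_id == "C0001")
        assert all(f.kind != "snv" for f in d.findings)

    def test_snv_diagnosed_sample_skips_small_cnv_assessment(self, spiked_cohort):
        _, _, diagnoses = spiked_cohort
        d = next(d for d in diagnoses if d.sample_id == "C0004")
        assert d.stage == "snv"
        assert all(f.kind != "intragenic_cnv" for f in d.findings)

    def test_each_diagnosed_sample_has_exactly_one_stage(self, spiked_cohort):
        _, _, diagnoses = spiked_cohort
        diagnosed = [d for d in diagnoses if d.diagnosed]
        assert all(d.stage in ("lowpass", "snv", "small_cnv") for d in diagnosed)
        by_stage = {s: sum(d.stage == s for d in diagnosed) for s in ("lowpass", "snv", "small_cnv")}
        assert sum(by_stage.values()) == len(diagnosed)

    def test_missing_depth_profile_logged_and_cascade_continues(self, spiked_cohort):
        bundle, tri, _ = spiked_cohort
        stripped = type(bundle)(
            samples=bundle.samples, variants=bundle.variants, cnvs=bundle.cnvs,
            depth_profiles={}, phenotype_map=bundle.phenotype_map, truth=bundle.truth,
        )
        d = triage_sample("C0003", stripped, tri)
        assert d.stage == "snv"
        assert any("depth profile" in m for m in d.qc_log)

    def test_enlarging_candidate_list_never_undiagnoses(self, spiked_cohort):
        bundle, tri, diagnoses = spiked_cohort
        # add every phenotype term to every sample: candidate sets only grow
        grown = {sid: set(tri.hpo_map) - {"T:root"} for sid in bundle.phenotype_map}
        wide = type(bundle)(
            samples=bundle.samples, variants=bundle.variants, cnvs=bundle.cnvs,
            depth_profiles=bundle.depth_profiles, phenotype_map=grown, truth=bundle.truth,
        )
        before = {d.sample_id for d in diagnoses if d.diagnosed}
        after = {d.sample_id for d in triage_cohort(wide, tri) if d.diagnosed}
        assert before <= after
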