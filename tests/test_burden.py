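"""QC/deleteriousness/singleton predicates, stratified counting, and the
rank-sum test against an exhaustive-permutation oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cnstriage.burden import (
    SlofvBurden,
    count_burden,
    find_singletons,
    is_deleterious,
    pcp_panel_screen,
    qc_filter,
    wilcoxon_two_sided,
)
from cnstriage.synthetic_cohort import SimConfig, generate_cohort


def variant_row(**kw):
    base = dict(sample="S1", chrom="chr1", pos=100, ref="A", alt="T", zygosity="het",
                dp=40, ad_alt=20, gene="G1", consequence="missense", sift_class="missing",
                cadd=np.nan, mcap=np.nan, revel=np.nan, af_public=0.0, af_inhouse=0.0)
    base.update(kw)
    return base


def frame(*rows):
    return pd.DataFrame(list(rows))


class TestQcFilter:
    @pytest.mark.parametrize("dp,ad,ref,alt,kept", [
        (19, 10, "A", "T", False),   # depth below the inclusive bound
        (20, 3, "A", "T", True),     # boundary depth and alt depth retained
        (20, 2, "A", "T", False),
        (40, 20, "AAAAAA", "A", False),  # 6 bp span
        (40, 20, "AAAAA", "A", True),    # 5 bp span retained
        (40, 20, "A", "AAAAA", True),
    ])
    def test_boundaries(self, dp, ad, ref, alt, kept):
        got = qc_filter(frame(variant_row(dp=dp, ad_alt=ad, ref=ref, alt=alt)))
        assert len(got) == (1 if kept else 0)


class TestDeleteriousness:
    def test_lof_consequences(self):
        for csq in ("nonsense", "frameshift", "canonical_splice", "stop_loss"):
            got = is_deleterious(frame(variant_row(consequence=csq)))
            assert got.iloc[0] == "lof"

    def test_fully_damaging_missense(self):
        got = is_deleterious(frame(variant_row(
            sift_class="damaging", cadd=25.0, mcap=0.03, revel=0.6)))
        assert got.iloc[0] == "damaging_missense"

    @pytest.mark.parametrize("kw", [
        dict(revel=0.5),                       # strict >: boundary fails
        dict(cadd=20.0),
        dict(mcap=0.025),
        dict(sift_class="tolerated"),
        dict(sift_class="missing"),
        dict(cadd=np.nan),                     # missing score never damaging
    ])
    def test_missense_boundaries_and_missing_scores(self, kw):
        base = dict(sift_class="damaging", cadd=25.0, mcap=0.03, revel=0.6)
        base.update(kw)
        got = is_deleterious(frame(variant_row(**base)))
        assert got.iloc[0] == "none"

    def test_synonymous_is_none(self):
        assert is_deleterious(frame(variant_row(consequence="synonymous"))).iloc[0] == "none"


class TestSingletons:
    def test_definition(self):
        df = frame(
            variant_row(sample="S1", pos=1),
            variant_row(sample="S1", pos=2),
            variant_row(sample="S2", pos=2),
        )
        flags = find_singletons(df)
        assert flags.tolist() == [True, False, False]

    def test_matches_brute_force_on_random_tables(self, rng):
        n = 5000
        df = pd.DataFrame({
            "sample": rng.choice([f"S{i}" for i in range(40)], size=n),
            "chrom": rng.choice(["chr1", "chr2"], size=n),
            "pos": rng.integers(1, 400, size=n),
            "ref": "A",
            "alt": rng.choice(["T", "G"], size=n),
        }).drop_duplicates(subset=["sample", "chrom", "pos", "ref", "alt"]).reset_index(drop=True)
        flags = find_singletons(df)
        occ = {}
        for r in df.itertuples(index=False):
            occ.setdefault((r.chrom, r.pos, r.ref, r.alt), set()).add(r.sample)
        expected = [len(occ[(r.chrom, r.pos, r.ref, r.alt)]) == 1 for r in df.itertuples(index=False)]
        assert flags.tolist() == expected


class TestCountBurden:
    def test_sample_without_variants_gets_zero_row(self):
        df = frame(variant_row(sample="S1", consequence="frameshift"))
        counts = count_burden(df, ["S1", "S2"])
        assert counts.loc["S2"].sum() == 0
        assert counts.loc["S1", "lof_maf0"] == 1

    def test_maf0_lof_increments_all_nested_strata(self):
        df = frame(variant_row(consequence="nonsense", af_public=0.0))
        counts = count_burden(df, ["S1"])
        assert counts.loc["S1", ["lof_maf0", "lof_maf0.001", "lof_maf0.01"]].tolist() == [1, 1, 1]

    def test_stratum_nesting_holds_per_sample(self, small_cohort):
        bundle, _ = small_cohort
        counts = count_burden(bundle.variants, bundle.sample_ids)
        for kind in ("lof", "damaging_missense"):
            c0 = counts[f"{kind}_maf0"]
            c1 = counts[f"{kind}_maf0.001"]
            c2 = counts[f"{kind}_maf0.01"]
            assert (c0 <= c1).all() and (c1 <= c2).all()

    def test_matches_brute_force_counting(self, rng):
        rows = []
        for i in range(2000):
            rows.append(variant_row(
                sample=f"S{rng.integers(0, 20)}", pos=int(rng.integers(1, 500)),
                consequence=str(rng.choice(["nonsense", "missense", "synonymous"])),
                sift_class="damaging", cadd=30.0, mcap=0.05,
                revel=float(rng.choice([0.4, 0.9])),
                dp=int(rng.choice([15, 40])), ad_alt=10,
                af_public=float(rng.choice([0.0, 0.0005, 0.005, 0.05])),
            ))
        df = pd.DataFrame(rows).drop_duplicates(subset=["sample", "chrom", "pos", "ref", "alt"])
        samples = sorted(df["sample"].unique())
        counts = count_burden(df, samples)

        hq = df[(df.dp >= 20) & (df.ad_alt >= 3)]
        occ = {}
        for r in hq.itertuples(index=False):
            occ.setdefault((r.chrom, r.pos, r.ref, r.alt), set()).add(r.sample)
        for s in samples:
            for bound in (0.0, 0.001, 0.01):
                exp_lof = sum(
                    1 for r in hq.itertuples(index=False)
                    if r.sample == s and r.consequence == "nonsense"
                    and len(occ[(r.chrom, r.pos, r.ref, r.alt)]) == 1 and r.af_public <= bound
                )
                exp_dmg = sum(
                    1 for r in hq.itertuples(index=False)
                    if r.sample == s and r.consequence == "missense" and r.revel > 0.5
                    and len(occ[(r.chrom, r.pos, r.ref, r.alt)]) == 1 and r.af_public <= bound
                )
                assert counts.loc[s, f"lof_maf{bound:g}"] == exp_lof
                assert counts.loc[s, f"damaging_missense_maf{bound:g}"] == exp_dmg


def permutation_pvalue(x, y):
    """Exhaustive two-sided rank-sum p over all C(n+m, n) rank allocations."""
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    w_obs = ranks[: len(x)].sum()
    n, m = len(x), len(y)
    center = n * (n + m + 1) / 2.0
    dev = abs(w_obs - center)
    total = hits = 0
    for combo in combinations(range(n + m), n):
        w = sum(ranks[list(combo)])
        total += 1
        if abs(w - center) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        _, p = wilcoxon_two_sided([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.98

    def test_separated_triples_exact_p(self):
        _, p = wilcoxon_two_sided([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            wilcoxon_two_sided([], [1.0])

    def test_matches_permutation_oracle_small_samples(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 8))
            m = int(rng.integers(2, 8))
            pooled = rng.choice(np.arange(100), size=n + m, replace=False).astype(float)
            x, y = pooled[:n], pooled[n:]
            _, p = wilcoxon_two_sided(x, y)
            assert p == pytest.approx(permutation_pvalue(x, y), abs=1e-12)

    def test_tied_large_samples_use_corrected_normal_approximation(self, rng):
        x = rng.poisson(9, 100).astype(float)
        y = rng.poisson(9, 100).astype(float)
        _, p = wilcoxon_two_sided(x, y)
        assert 0 < p <= 1


class TestPanelScreen:
    def test_spiked_panel_variant_recovered_only_in_cases(self, resources):
        cfg = SimConfig(seed=8, n_cases=10, n_controls=10, make_depth=False,
                        background_snv_rate=20, slofv_case_excess=0.0)
        bundle, _ = generate_cohort(cfg, resources)
        panel_gene = resources.pcp_panel[0]
        extra = pd.DataFrame([variant_row(sample="C0001", chrom="chr9", pos=999_983,
                                          gene=panel_gene, consequence="nonsense")])
        variants = pd.concat([bundle.variants, extra], ignore_index=True)
        arms = {s.sample_id: s.arm for s in bundle.samples}
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # some panel genes never drawn in a tiny cohort
            out = pcp_panel_screen(variants, arms, set(resources.pcp_panel),
                                   subgroup={"C0001", "C0002"})
        assert len(out["cases"]) >= 1
        assert (out["cases"]["gene"].isin(resources.pcp_panel)).all()
        assert (out["controls"]["gene"].isin(resources.pcp_panel)).all() if len(out["controls"]) else True
        hit = out["cases"][(out["cases"]["sample"] == "C0001") & (out["cases"]["pos"] == 999_983)]
        assert len(hit) == 1

    def test_output_is_subset_of_singleton_deleterious_set(self, small_cohort):
        bundle, res = small_cohort
        arms = {s.sample_id: s.arm for s in bundle.samples}
        out = pcp_panel_screen(bundle.variants, arms, set(res.pcp_panel))
        hq = qc_filter(bundle.variants)
        full = hq[(is_deleterious(hq) != "none") & find_singletons(hq)]
        keys = set(zip(full["sample"], full["chrom"], full["pos"]))
        for arm_hits in out.values():
            for r in arm_hits.itertuples(index=False):
                assert (r.sample, r.chrom, r.pos) in keys

    def test_empty_panel_rejected_and_unknown_genes_warn(self, small_cohort):
        bundle, _ = small_cohort
        arms = {s.sample_id: s.arm for s in bundle.samples}
        with pytest.raises(ValueError, match="nonempty"):
            pcp_panel_screen(bundle.variants, arms, set())
        with pytest.warns(UserWarning, match="never observed"):
            out = pcp_panel_screen(bundle.variants, arms, {"NOT_A_GENE"})
        assert len(out["cases"]) == 0 and len(out["controls"]) == 0


class TestModelSurface:
    def test_fit_summary_and_accessors(self, small_cohort):
        bundle, _ = small_cohort
        result = SlofvBurden.from_bundle(bundle).fit()
        assert result.n_cases == 30 and result.n_controls == 30
        text = result.summary()
        assert "lof" in text and "cases n=30" in text
        assert 0 < result.pvalue("lof", 0.001) <= 1

    def test_singleton_population_switch(self, small_cohort):
        bundle, _ = small_cohort
        combined = SlofvBurden.from_bundle(bundle, singleton_population="combined").fit()
        cases_only = SlofvBurden.from_bundle(bundle, singleton_population="cases").fit()
        # restricting the counting population can only add case singletons
        col = "lof_maf0.01"
        cc = combined.counts.loc[combined.counts["arm"] == "case", col]
        co = cases_only.counts.loc[cases_only.counts["arm"] == "case", col]
        assert (co >= cc).all()
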