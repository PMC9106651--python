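"""Rare singleton deleterious-variant burden analysis.

Pipeline: quality filtering (depth >= 20, alt depth >= 3, variant span
<= 5 bp), a deleteriousness predicate splitting variants into
loss-of-function and damaging-missense classes, singleton detection
(alleles seen in exactly one sample of the counting population),
MAF-stratified per-sample counts, and a two-sided Wilcoxon rank-sum
comparison of case versus control counts.

The public entry point is the model/results pair: ``SlofvBurden`` built
from a cohort bundle or a variant table, whose :meth:`SlofvBurden.fit`
returns a :class:`BurdenResult` carrying the count table, group medians,
test statistics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CohortBundle, LOF_CONSEQUENCES
from .triage import DEFAULT_THRESHOLDS, Thresholds

# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------


def qc_filter(variants: pd.DataFrame, th: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """High-quality variant subset.

    Retained iff read depth >= ``qc_depth`` AND alt-allele depth >=
    ``qc_alt_depth`` AND max(len(ref), len(alt)) <= ``qc_max_len_bp``.
    """
    if not len(variants):
        return variants
    span = np.maximum(variants["ref"].str.len().to_numpy(), variants["alt"].str.len().to_numpy())
    keep = (
        (variants["dp"].to_numpy() >= th.qc_depth)
        & (variants["ad_alt"].to_numpy() >= th.qc_alt_depth)
        & (span <= th.qc_max_len_bp)
    )
    return variants.loc[keep]


def is_deleterious(variants: pd.DataFrame, th: Thresholds = DEFAULT_THRESHOLDS) -> pd.Series:
    """Per-variant deleteriousness kind: 'lof', 'damaging_missense' or 'none'.

    LoF covers nonsense, frameshift, canonical splice-site and stop-loss
    alleles. Damaging missense needs every predictor to agree: SIFT damaging
    AND CADD > 20 AND M-CAP > 0.025 AND REVEL > 0.5 (all strict; a missing
    score never counts as damaging).
    """
    csq = variants["consequence"]
    lof = csq.isin(LOF_CONSEQUENCES)
    dmg = (
        (csq == "missense")
        & (variants["sift_class"] == "damaging")
        & (variants["cadd"].to_numpy() > th.cadd)
        & (variants["mcap"].to_numpy() > th.mcap)
        & (variants["revel"].to_numpy() > th.revel)
    )
    out = pd.Series("none", index=variants.index, dtype=object)
    out[dmg.to_numpy()] = "damaging_missense"
    out[lof.to_numpy()] = "lof"
    return out


def find_singletons(variants: pd.DataFrame) -> pd.Series:
    """Boolean per-row flag: allele observed in exactly one sample.

    The allele key is (chrom, pos, ref, alt); occurrences are counted over
    the distinct samples of the supplied table (the counting population).
    """
    if not len(variants):
        return pd.Series(dtype=bool)
    key = ["chrom", "pos", "ref", "alt"]
    n_samples = variants.groupby(key)["sample"].transform("nunique")
    n_rows = variants.groupby(key)["sample"].transform("size")
    return (n_samples == 1) & (n_rows == 1)


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------


def count_burden(
    variants: pd.DataFrame,
    sample_ids: list[str],
    th: Thresholds = DEFAULT_THRESHOLDS,
    qc: bool = True,
) -> pd.DataFrame:
    """Per-sample singleton-deleterious counts per (kind, MAF stratum).

    Strata are nested public-database MAF bounds (MAF == 0 means absent from
    every configured public source); a variant with MAF 0 therefore
    increments every stratum of its kind. Rows cover every requested sample,
    including all-zero rows; columns are ``{kind}_maf{bound}``.
    """
    hq = qc_filter(variants, th) if qc else variants
    cols: dict[str, pd.Series] = {}
    if len(hq):
        hq = hq.assign(_kind=is_deleterious(hq, th), _singleton=find_singletons(hq))
        hits = hq[(hq["_kind"] != "none") & hq["_singleton"]]
    else:
        hits = hq
    out = pd.DataFrame(index=pd.Index(sample_ids, name="sample"))
    for kind in ("damaging_missense", "lof"):
        for bound in th.maf_strata:
            name = f"{kind}_maf{bound:g}"
            if len(hits):
                sel = hits[(hits["_kind"] == kind) & (hits["af_public"] <= bound)]
                counts = sel.groupby("sample").size()
                out[name] = counts.reindex(sample_ids).fillna(0).astype(int)
            else:
                out[name] = 0
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_two_sided(
    x, y, exact_cutoff: int = 12
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Midranks for ties; the exact null distribution is used when
    min(n, m) <= ``exact_cutoff`` and the data are tie-free, otherwise the
    normal approximation with tie-corrected variance and continuity
    correction. Returns (rank-sum statistic of x, p), with p clamped to
    (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(x), len(y)) <= exact_cutoff and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank sum of x
    p = min(max(float(res.pvalue), np.nextafter(0, 1)), 1.0)
    return w, p


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------


@dataclass
class BurdenResult:
    """Fitted burden comparison.

    ``counts`` is the per-sample stratified count table with an ``arm``
    column; ``tests`` has one row per (kind, stratum) with group medians,
    the rank-sum statistic and the two-sided p-value.
    """

    counts: pd.DataFrame
    tests: pd.DataFrame
    n_cases: int
    n_controls: int

    def median(self, kind: str, bound: float, arm: str) -> float:
        col = f"{kind}_maf{bound:g}"
        return float(self.counts.loc[self.counts["arm"] == arm, col].median())

    def pvalue(self, kind: str = "lof", bound: float = 0.001) -> float:
        row = self.tests[(self.tests["kind"] == kind) & (self.tests["maf_bound"] == bound)]
        return float(row["p"].iloc[0])

    def summary(self) -> str:
        lines = [
            "Singleton deleterious variant burden",
            f"  cases n={self.n_cases}, controls n={self.n_controls}",
            f"  {'kind':<20}{'MAF bound':>10}{'case med':>10}{'ctrl med':>10}{'W':>12}{'p':>12}",
        ]
        for r in self.tests.itertuples(index=False):
            lines.append(
                f"  {r.kind:<20}{r.maf_bound:>10g}{r.median_cases:>10.1f}"
                f"{r.median_controls:>10.1f}{r.statistic:>12.1f}{r.p:>12.3g}"
            )
        return "\n".join(lines)

    def plot(self, kind: str = "lof", bound: float = 0.001, ax=None):
        """Case/control count histograms with median markers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        col = f"{kind}_maf{bound:g}"
        cases = self.counts.loc[self.counts["arm"] == "case", col]
        controls = self.counts.loc[self.counts["arm"] == "control", col]
        hi = int(max(cases.max(), controls.max())) + 2
        bins = np.arange(-0.5, hi + 0.5)
        ax.hist(cases, bins=bins, alpha=0.6, density=True, label="cases")
        ax.hist(controls, bins=bins, alpha=0.6, density=True, label="controls")
        ax.axvline(cases.median(), ls="-", color="k")
        ax.axvline(controls.median(), ls="--", color="k")
        ax.set_xlabel(f"singleton {kind} count (MAF <= {bound:g})")
        ax.set_ylabel("density")
        ax.legend()
        return ax


class SlofvBurden:
    """Case-control singleton deleterious-variant burden model.

    Parameters
    ----------
    variants : the cohort-wide small-variant table (QC applied during fit).
    arms : mapping sample id -> "case" / "control".
    th : thresholds (QC, predictor cutoffs, MAF strata).
    singleton_population : "combined" counts allele occurrences over both
        arms together (default — keeps the two arms' counts comparable);
        "cases" restricts the counting population to the case arm.
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        arms: dict[str, str],
        th: Thresholds = DEFAULT_THRESHOLDS,
        singleton_population: str = "combined",
    ) -> None:
        if singleton_population not in ("combined", "cases"):
            raise ValueError("singleton_population must be 'combined' or 'cases'")
        self.variants = variants
        self.arms = dict(arms)
        self.th = th
        self.singleton_population = singleton_population

    @classmethod
    def from_bundle(cls, bundle: CohortBundle, th: Thresholds = DEFAULT_THRESHOLDS, **kw) -> "SlofvBurden":
        arms = {s.sample_id: s.arm for s in bundle.samples}
        return cls(bundle.variants, arms, th, **kw)

    def fit(self) -> BurdenResult:
        cases = [s for s, a in self.arms.items() if a == "case"]
        controls = [s for s, a in self.arms.items() if a == "control"]
        if self.singleton_population == "combined":
            table = self.variants[self.variants["sample"].isin(self.arms)]
            counts = count_burden(table, cases + controls, self.th)
        else:
            case_tab = self.variants[self.variants["sample"].isin(cases)]
            ctrl_tab = self.variants[self.variants["sample"].isin(controls)]
            counts = pd.concat(
                [count_burden(case_tab, cases, self.th), count_burden(ctrl_tab, controls, self.th)]
            )
        counts = counts.assign(arm=[self.arms[s] for s in counts.index])

        rows = []
        for kind in ("damaging_missense", "lof"):
            for bound in self.th.maf_strata:
                col = f"{kind}_maf{bound:g}"
                xc = counts.loc[counts["arm"] == "case", col].to_numpy()
                yc = counts.loc[counts["arm"] == "control", col].to_numpy()
                w, p = wilcoxon_two_sided(xc, yc)
                rows.append(
                    dict(kind=kind, maf_bound=bound, median_cases=float(np.median(xc)),
                         median_controls=float(np.median(yc)), statistic=w, p=p)
                )
        return BurdenResult(
            counts=counts,
            tests=pd.DataFrame(rows),
            n_cases=len(cases),
            n_controls=len(controls),
        )


# ---------------------------------------------------------------------------
# Pathway panel screen
# ---------------------------------------------------------------------------


def pcp_panel_screen(
    variants: pd.DataFrame,
    arms: dict[str, str],
    panel: set[str],
    subgroup: set[str] | None = None,
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> dict[str, pd.DataFrame]:
    """Singleton deleterious variants restricted to a gene panel.

    Returns the panel hits separately for the (sub)group of cases and for
    controls. Panel gene symbols absent from the table produce a warning,
    not an error.
    """
    import warnings

    if not panel:
        raise ValueError("panel must be nonempty")
    known = set(variants["gene"].unique())
    missing = panel - known
    if missing:
        warnings.warn(f"panel genes never observed in the table: {sorted(missing)[:5]}", stacklevel=2)
    hq = qc_filter(variants[variants["sample"].isin(arms)], th)
    if len(hq):
        hq = hq.assign(_kind=is_deleterious(hq, th), _singleton=find_singletons(hq))
        hits = hq[(hq["_kind"] != "none") & hq["_singleton"] & hq["gene"].isin(panel)]
    else:
        hits = hq
    case_ids = {s for s, a in arms.items() if a == "case"}
    if subgroup is not None:
        case_ids &= set(subgroup)
    ctrl_ids = {s for s, a in arms.items() if a == "control"}
    return {
        "cases": hits[hits["sample"].isin(case_ids)].drop(columns=["_kind", "_singleton"], errors="ignore"),
        "controls": hits[hits["sample"].isin(ctrl_ids)].drop(columns=["_kind", "_singleton"], errors="ignore"),
    }
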