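"""Cohort-level summaries: diagnostic yields, resolution-tier breakdown,
recurrent key genes and inheritance-mode percentages."""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from .core import Finding

TIER_ORDER = ("chromosomal", "submicroscopic", "snv", "intragenic")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with halves away from zero (not banker's)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * n / d rounded half away from zero; NaN for an empty group."""
    if denominator == 0:
        return float("nan")
    return round_half_away(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# Yields
# ---------------------------------------------------------------------------


def diagnostic_yield(
    diagnosed: Mapping[str, bool],
    grouping: Mapping[str, Iterable[str] | str],
    overall_label: str = "overall",
) -> pd.DataFrame:
    """Yield table: one row per group label plus an overall row.

    ``diagnosed`` maps sample -> has a primary finding; ``grouping`` maps
    sample -> one label or several (samples carrying several phenotype
    labels are counted once in each group, so per-label numerators may sum
    above the overall diagnosed count).
    """
    groups: dict[str, list[str]] = {}
    for sid, labels in grouping.items():
        if isinstance(labels, str):
            labels = [labels]
        for label in labels:
            groups.setdefault(label, []).append(sid)
    rows = []
    for label in sorted(groups):
        ids = groups[label]
        d = sum(bool(diagnosed.get(s, False)) for s in ids)
        rows.append(dict(group=label, diagnosed=d, total=len(ids), percent=percent(d, len(ids))))
    d_all = sum(bool(v) for v in diagnosed.values())
    rows.append(dict(group=overall_label, diagnosed=d_all, total=len(diagnosed), percent=percent(d_all, len(diagnosed))))
    return pd.DataFrame(rows, columns=["group", "diagnosed", "total", "percent"])


def tier_breakdown(
    sample_tiers: Mapping[str, str],
    total: int,
    order: tuple[str, ...] = TIER_ORDER,
) -> pd.DataFrame:
    """Diagnosed counts per resolution tier with cascade denominators.

    ``sample_tiers`` maps each diagnosed sample to the tier of its primary
    finding. The cascade is sequential, so each tier's denominator is the
    sample count left undiagnosed by every earlier tier.
    """
    unknown = set(sample_tiers.values()) - set(order)
    if unknown:
        raise ValueError(f"findings with unknown tier: {sorted(unknown)}")
    rows = []
    remaining = total
    for tier in order:
        n = sum(1 for t in sample_tiers.values() if t == tier)
        rows.append(dict(tier=tier, diagnosed=n, total=remaining, percent=percent(n, remaining)))
        remaining -= n
    return pd.DataFrame(rows, columns=["tier", "diagnosed", "total", "percent"])


# ---------------------------------------------------------------------------
# Key genes
# ---------------------------------------------------------------------------


def recurrent_genes(findings: Iterable[Finding]) -> pd.DataFrame:
    """Tally of gene -> number of distinct diagnosed fetuses (primary
    findings only); ``recurrent`` flags genes seen in two or more."""
    seen: dict[str, set[str]] = {}
    for f in findings:
        if f.category != "primary" or not f.gene:
            continue
        seen.setdefault(f.gene, set()).add(f.sample_id)
    rows = [
        dict(gene=g, n_fetuses=len(s), recurrent=len(s) >= 2)
        for g, s in sorted(seen.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["gene", "n_fetuses", "recurrent"])


def key_gene_summary(findings: Iterable[Finding]) -> dict:
    """Key-gene accounting over primary findings.

    ``n_entries`` counts one entry per diagnostic small variant plus one per
    critical gene of a diagnostic CNV (the tally a per-variant gene frequency
    chart sums to); ``n_distinct`` collapses to unique gene symbols;
    ``snv_genes`` is the distinct small-variant gene set used for
    inheritance-mode percentages.
    """
    findings = [f for f in findings if f.category == "primary"]
    snv_entries = [f for f in findings if f.kind == "snv" and f.gene]
    cnv_critical = [f for f in findings if f.kind in ("cnv", "intragenic_cnv", "aneuploidy") and f.gene]
    tally = recurrent_genes(findings)
    return {
        "n_entries": len(snv_entries) + len(cnv_critical),
        "n_distinct": int(len(tally)),
        "snv_genes": sorted({f.gene for f in snv_entries}),
        "recurrent": list(tally.loc[tally["recurrent"], "gene"]),
    }


def inheritance_breakdown(
    key_genes: Iterable[str],
    gene_modes: Mapping[str, str],
    collapse_x: bool = True,
) -> dict[str, int]:
    """Integer percentages of inheritance modes over a key-gene set.

    X-linked and X-linked-dominant collapse into one "XL" bucket by default.
    Every gene must carry a mode annotation.
    """
    genes = sorted(set(key_genes))
    counts: dict[str, int] = {}
    for g in genes:
        if g not in gene_modes:
            raise KeyError(f"gene {g!r} has no inheritance-mode annotation")
        mode = gene_modes[g]
        if collapse_x and mode in ("XL", "XLD"):
            mode = "XL"
        counts[mode] = counts.get(mode, 0) + 1
    total = len(genes)
    return {m: int(round_half_away(100.0 * c / total, 0)) for m, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Fixture report
# ---------------------------------------------------------------------------


def fixture_report(fixture) -> dict:
    """Every published summary surface recomputed from the packaged fixture.

    Returns overall and subgroup yields, the resolution-tier table, the
    key-gene accounting and the inheritance split — all derived from the
    curated findings, not read from metadata.
    """
    findings = fixture.findings
    samples = fixture.bundle.samples
    diagnosed_ids = {f.sample_id for f in findings if f.category == "primary"}
    diagnosed = {s.sample_id: s.sample_id in diagnosed_ids for s in samples}

    overall = diagnostic_yield(diagnosed, {s.sample_id: "all" for s in samples})
    subgroup = diagnostic_yield(diagnosed, {s.sample_id: s.subgroup for s in samples})

    # tier of each diagnosed sample = the highest-resolution primary finding,
    # in cascade order (chromosomal beats submicroscopic beats snv beats intragenic)
    rank = {t: i for i, t in enumerate(TIER_ORDER)}
    sample_tiers: dict[str, str] = {}
    for f in findings:
        if f.category != "primary":
            continue
        tier = f.size_tier if f.kind != "snv" else "snv"
        prev = sample_tiers.get(f.sample_id)
        if prev is None or rank[tier] < rank[prev]:
            sample_tiers[f.sample_id] = tier
    tiers = tier_breakdown(sample_tiers, total=len(samples))

    keys = key_gene_summary(findings)
    inheritance = inheritance_breakdown(keys["snv_genes"], fixture.gene_modes)
    return {
        "overall": overall,
        "subgroup": subgroup,
        "tiers": tiers,
        "key_genes": keys,
        "inheritance": inheritance,
    }


def plot_yields(yield_table: pd.DataFrame, ax=None):
    """Bar (counts) + line (percent) chart of per-group diagnostic yield."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    sub = yield_table[yield_table["group"] != "overall"]
    x = range(len(sub))
    ax.bar(x, sub["total"], color="lightgray", label="cases")
    ax.bar(x, sub["diagnosed"], color="steelblue", label="diagnosed")
    ax2 = ax.twinx()
    ax2.plot(x, sub["percent"], "k--o", label="diagnostic rate (%)")
    ax.set_xticks(list(x))
    ax.set_xticklabels(sub["group"], rotation=45, ha="right")
    ax.set_ylabel("cases")
    ax2.set_ylabel("diagnostic rate (%)")
    ax.legend(loc="upper left")
    return ax
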