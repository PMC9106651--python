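"""Aneuploidy and CNV detection from binned low-pass WGS read depth.

The detector is deliberately simple and fully specified: GC-stratified
median normalisation of bin counts, per-chromosome robust z-scores for
whole-chromosome gains/losses, and run-merging segmentation with a ratio
threshold for segmental CNVs of 100 kb and above. Sex chromosomes are
compared against a baseline inferred from Y coverage, and intermediate
sex-chromosome states are flagged as possible mosaics rather than forced
onto an integer copy number.

A dispersion QC gate marks profiles whose normalised ratios are too noisy
for copy-number calling ("turbulent" read depth); such samples keep their
small-variant analyses but skip read-depth CNV calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CnvCall, DepthProfile

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

#: Copy-number states a sex-chromosome median ratio can snap to
#: (ratio of 1 == two copies, normalised against disomic autosomes).
_STATE_GRID = np.array([0.0, 0.5, 1.0, 1.5, 2.0])


class InsufficientBinsError(ValueError):
    pass


def _mad(x: np.ndarray) -> float:
    """Median absolute deviation scaled to the normal sd (1.4826 factor)."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------


def gc_correct(profile: DepthProfile, n_gc_bins: int = 10, min_autosomal_bins: int = 50) -> DepthProfile:
    """Normalise bin counts for GC bias.

    Expected count per bin is the median autosomal count within the bin's GC
    decile (quantile-based strata over autosomal GC); ``ratio`` is
    count / expected, rescaled so the genome-wide autosomal median ratio is
    exactly 1. Always recomputed from raw counts, so the operation is
    idempotent.
    """
    out = profile.copy()
    bins = out.bins
    auto = bins["chrom"].isin(AUTOSOMES).to_numpy()
    if int(auto.sum()) < min_autosomal_bins:
        raise InsufficientBinsError(
            f"insufficient bins: {int(auto.sum())} autosomal bins < {min_autosomal_bins}"
        )
    gc = bins["gc"].to_numpy(dtype=float)
    counts = bins["count"].to_numpy(dtype=float)

    # GC strata from autosomal quantiles; duplicate edges collapse for
    # near-constant GC, degrading gracefully to a single stratum.
    edges = np.unique(np.quantile(gc[auto], np.linspace(0, 1, n_gc_bins + 1)))
    if len(edges) < 3:
        expected = np.full(len(bins), np.median(counts[auto]))
    else:
        strata = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
        expected = np.empty(len(bins))
        global_med = np.median(counts[auto])
        for s in range(len(edges) - 1):
            in_s = strata == s
            sel = in_s & auto
            med = np.median(counts[sel]) if sel.any() else global_med
            expected[in_s] = med if med > 0 else global_med
    expected[expected <= 0] = 1.0
    ratio = counts / expected
    auto_med = np.median(ratio[auto])
    if auto_med > 0:
        ratio = ratio / auto_med
    bins["ratio"] = ratio
    return out


# ---------------------------------------------------------------------------
# QC gate
# ---------------------------------------------------------------------------


def cnv_calling_qc(profile: DepthProfile, mad_cap: float = 0.25) -> bool:
    """True if the profile is quiet enough for read-depth CNV calling.

    The gate is the robust dispersion of autosomal normalised ratios; a MAD
    above ``mad_cap`` marks the profile as failed ("turbulent" depth).
    """
    if not profile.corrected:
        profile = gc_correct(profile)
    auto = profile.bins["chrom"].isin(AUTOSOMES)
    return _mad(profile.bins.loc[auto, "ratio"].to_numpy()) <= mad_cap


# ---------------------------------------------------------------------------
# Whole-chromosome calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AneuploidyCall:
    chrom: str
    direction: str  # "gain" | "loss"
    z: float
    median_ratio: float
    possible_mosaic: bool = False

    @property
    def label(self) -> str:
        name = self.chrom.removeprefix("chr")
        return ("+" if self.direction == "gain" else "-") + name


def infer_sex(profile: DepthProfile, y_male_threshold: float = 0.25) -> str:
    """Chromosomal sex from Y coverage: 'M' if the Y median ratio >= threshold."""
    if not profile.corrected:
        profile = gc_correct(profile)
    y = profile.bins.loc[profile.bins["chrom"] == "chrY", "ratio"]
    if len(y) == 0:
        return "F"
    return "M" if float(np.median(y)) >= y_male_threshold else "F"


def call_aneuploidy(
    profile: DepthProfile,
    z_gain: float = 3.5,
    z_loss: float = 3.5,
    min_effect: float = 0.25,
    mosaic_band: float = 0.15,
) -> list[AneuploidyCall]:
    """Whole-chromosome gain/loss calls from a GC-corrected profile.

    z = (median chromosome ratio - reference) / robust spread, where the
    spread is the cross-chromosome robust deviation of autosomal medians
    floored by the chromosome's own median sampling error (so few-bin
    chromosomes are not over-called). A call additionally requires the
    median to move at least ``min_effect`` toward the next copy state;
    sex-chromosome references come from the Y-inferred sex baseline.
    Medians landing between copy states (within no ``mosaic_band`` of any
    state) are flagged as possible mosaics.
    """
    if not profile.corrected:
        profile = gc_correct(profile)
    bins = profile.bins
    med = bins.groupby("chrom", sort=False)["ratio"].median()
    nbin = bins.groupby("chrom", sort=False)["ratio"].size()
    bin_mad = bins.groupby("chrom", sort=False)["ratio"].apply(lambda x: _mad(x.to_numpy()))

    auto_meds = med[med.index.isin(AUTOSOMES)]
    spread = _mad(auto_meds.to_numpy())
    sex = infer_sex(profile)
    refs = {c: 1.0 for c in AUTOSOMES}
    refs["chrX"] = 1.0 if sex == "F" else 0.5
    refs["chrY"] = 0.0 if sex == "F" else 0.5

    calls: list[AneuploidyCall] = []
    for chrom, m in med.items():
        ref = refs.get(chrom)
        if ref is None:
            continue
        if chrom == "chrY" and sex == "F":
            continue  # absent Y in XX profiles is not an event
        # sampling error of the median: 1.2533 * sd / sqrt(n)
        se = 1.2533 * bin_mad[chrom] / np.sqrt(max(int(nbin[chrom]), 1))
        denom = max(spread, se, 1e-12)
        z = (m - ref) / denom
        dev = m - ref
        if z >= z_gain and dev >= min_effect:
            direction = "gain"
        elif z <= -z_loss and dev <= -min_effect:
            direction = "loss"
        else:
            continue
        nearest = _STATE_GRID[np.argmin(np.abs(_STATE_GRID - m))]
        mosaic = bool(abs(m - nearest) > mosaic_band)
        calls.append(AneuploidyCall(chrom, direction, float(z), float(m), mosaic))
    return calls


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(x) < window:
        return x
    s = pd.Series(x).rolling(window, center=True, min_periods=1).median()
    return s.to_numpy()


def segment_cnvs(
    profile: DepthProfile,
    min_size: int = 100_000,
    del_threshold: float = 0.75,
    dup_threshold: float = 1.25,
    smooth_window: int = 5,
    max_gap_bins: int = 1,
    exclude_chroms: set[str] | frozenset[str] = frozenset(),
) -> list[CnvCall]:
    """Segmental CNV calls >= ``min_size`` from a GC-corrected profile.

    Ratios are smoothed with a centred running median, bins beyond the
    deletion/duplication thresholds (relative to each chromosome's expected
    baseline — 1 for disomic chromosomes, 0.5 for a single X or Y) are
    grouped into same-direction runs (bridging gaps of up to
    ``max_gap_bins`` bins), and runs shorter than ``min_size`` are
    discarded. Copy number is ``round(2 * mean ratio)``.
    """
    if min_size < profile.bin_width:
        raise ValueError(f"min_size {min_size} < bin width {profile.bin_width}")
    if not profile.corrected:
        profile = gc_correct(profile)
    sex = infer_sex(profile)
    baseline = {c: 1.0 for c in AUTOSOMES}
    baseline["chrX"] = 1.0 if sex == "F" else 0.5
    baseline["chrY"] = 0.0 if sex == "F" else 0.5
    calls: list[CnvCall] = []
    for chrom, sub in profile.bins.groupby("chrom", sort=False):
        ref = baseline.get(str(chrom), 1.0)
        if chrom in exclude_chroms or ref == 0.0:
            continue
        sub = sub.sort_values("start")
        ratio = sub["ratio"].to_numpy(dtype=float) / ref
        smooth = _running_median(ratio, smooth_window)
        sign = np.zeros(len(smooth), dtype=int)
        sign[smooth < del_threshold] = -1
        sign[smooth > dup_threshold] = 1

        runs = _find_runs(sign, max_gap_bins)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i0, i1, direction in runs:
            start_1b = int(starts[i0]) + 1  # bins are 0-based half-open
            end_1b = int(ends[i1])
            size = end_1b - start_1b + 1
            if size < min_size:
                continue
            mean_ratio = float(np.mean(ratio[i0 : i1 + 1]))  # baseline-normalised
            cn = max(int(round(2 * ref * mean_ratio)), 0)
            if cn == int(round(2 * ref)):  # smoothing artefact; not a copy change
                continue
            sd = np.std(ratio[i0 : i1 + 1]) or 1e-9
            z = (mean_ratio - 1.0) / (sd / np.sqrt(i1 - i0 + 1))
            calls.append(
                CnvCall(
                    sample_id=profile.sample_id,
                    chrom=str(chrom),
                    start=start_1b,
                    end=end_1b,
                    copy_number=cn,
                    quality=float(z),
                )
            )
    return calls


def _find_runs(sign: np.ndarray, max_gap: int) -> list[tuple[int, int, int]]:
    """Runs of identical nonzero sign, merging runs split by small gaps."""
    runs: list[tuple[int, int, int]] = []
    i = 0
    n = len(sign)
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        d = sign[i]
        j = i
        while j + 1 < n:
            if sign[j + 1] == d:
                j += 1
                continue
            # try to bridge a short gap of non-matching bins
            k = j + 1
            gap = 0
            while k < n and sign[k] != d and gap < max_gap:
                gap += 1
                k += 1
            if k < n and sign[k] == d:
                j = k
            else:
                break
        runs.append((i, j, int(d)))
        i = j + 1
    return runs


# ---------------------------------------------------------------------------
# Size tiers
# ---------------------------------------------------------------------------


def assign_size_tier(size: int | CnvCall) -> str:
    """Resolution tier for a CNV size in bp.

    > 5 Mb -> "chromosomal"; 100 kb..5 Mb inclusive -> "submicroscopic";
    50 bp..<100 kb -> "intragenic". Sizes below 50 bp are rejected.
    """
    bp = size.size if isinstance(size, CnvCall) else int(size)
    if bp < 50:
        raise ValueError(f"CNV size {bp} bp below the 50 bp floor")
    if bp > 5_000_000:
        return "chromosomal"
    if bp >= 100_000:
        return "submicroscopic"
    return "intragenic"
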