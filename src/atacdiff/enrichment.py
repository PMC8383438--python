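"""GWAS-window construction, overlap counting, permutation enrichment, and
genomic feature annotation of peaks.

A GWAS region is the tag SNP position +/- a flank (100 kb by default, giving
200 kb windows on the printed coordinate scale, with the lower bound clamped
at zero).  Enrichment of a differential peak set in the windows is assessed
by drawing the same number of peaks uniformly without replacement from the
peak universe 10,000 times and recomputing the overlap statistic; the
empirical p-value uses the add-one convention (1 + #{perm >= obs}) /
(1 + n_perm), so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import multiset_overlap, validate_intervals  # noqa: F401 (re-export)

FEATURE_CATEGORIES = ("promoter", "first_exon", "utr5", "utr3", "intragenic", "intergenic")


def build_gwas_windows(snps: pd.DataFrame, flank: int = 100_000) -> pd.DataFrame:
    """Expand tag SNPs into [pos - flank, pos + flank] windows (clamped at 0).

    ``snps`` needs columns snp_id, chrom, pos (and optionally label).  Window
    arithmetic is done on the coordinate scale of the input positions.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if (snps["pos"] < 0).any():
        raise ValueError("SNP positions must be >= 0")
    out = snps.copy()
    out["window_start"] = np.maximum(out["pos"] - flank, 0)
    out["window_end"] = out["pos"] + flank
    return out


def overlap_regions(
    peaks: pd.DataFrame, regions: pd.DataFrame
) -> tuple[int, int, pd.DataFrame]:
    """Count differential sites falling in GWAS windows (>=1 bp intersection).

    Returns (number of distinct sites with >=1 hit, number of distinct
    regions hit, and the (site, region, label) pair list).
    """
    pairs = []
    if len(peaks) and len(regions):
        peaks = validate_intervals(peaks)
        for _, reg in regions.iterrows():
            same = peaks["chrom"] == reg["chrom"]
            hit = same & (peaks["start"] < reg["window_end"]) & (peaks["end"] > reg["window_start"])
            for _, pk in peaks[hit].iterrows():
                pairs.append(
                    (
                        f"{pk['chrom']}:{pk['start']}-{pk['end']}",
                        reg["snp_id"],
                        reg.get("label", ""),
                    )
                )
    pair_df = pd.DataFrame(pairs, columns=["peak_id", "snp_id", "label"])
    n_sites = pair_df["peak_id"].nunique()
    n_regions = pair_df["snp_id"].nunique()
    return n_sites, n_regions, pair_df


@dataclass
class EnrichmentResult:
    observed_sites_overlapping: int
    observed_regions_hit: int
    statistic: str
    observed: int
    n_perm: int
    perm_mean: float
    perm_sd: float
    perm_histogram: dict = field(default_factory=dict)
    empirical_p: float = 1.0
    seed: int | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["perm_histogram"] = {int(k): int(v) for k, v in self.perm_histogram.items()}
        return d


def permutation_enrichment(
    diff_peaks: pd.DataFrame,
    universe: pd.DataFrame,
    regions: pd.DataFrame,
    n_perm: int = 10_000,
    statistic: str = "regions_hit",
    seed: int | None = None,
) -> EnrichmentResult:
    """Permutation test: is the differential set unusually close to GWAS windows?

    Each permutation draws ``len(diff_peaks)`` peaks uniformly without
    replacement from ``universe`` and recomputes the statistic
    (``regions_hit``: distinct windows intersected; ``sites_overlapping``:
    distinct drawn peaks intersecting any window).
    """
    if statistic not in ("regions_hit", "sites_overlapping"):
        raise ValueError(f"unknown statistic {statistic!r}")
    n_diff = len(diff_peaks)
    universe = validate_intervals(universe).reset_index(drop=True)
    if n_diff > len(universe):
        raise ValueError(f"cannot draw {n_diff} peaks from a universe of {len(universe)}")
    obs_sites, obs_regions, _ = overlap_regions(diff_peaks, regions)
    observed = obs_regions if statistic == "regions_hit" else obs_sites

    # region-membership bitmask per universe peak (windows are few)
    n_regions = len(regions)
    masks = np.zeros(len(universe), dtype=object)
    masks[:] = 0
    for r, (_, reg) in enumerate(regions.iterrows()):
        same = universe["chrom"] == reg["chrom"]
        hit = (
            same
            & (universe["start"] < reg["window_end"])
            & (universe["end"] > reg["window_start"])
        )
        for g in np.flatnonzero(hit.to_numpy()):
            masks[g] |= 1 << r
    hits_any = np.array([m != 0 for m in masks])

    rng = np.random.default_rng(seed)
    perm_counts = np.zeros(n_perm, dtype=np.int64)
    idx_all = np.arange(len(universe))
    for b in range(n_perm):
        draw = rng.choice(idx_all, size=n_diff, replace=False)
        if statistic == "sites_overlapping":
            perm_counts[b] = int(hits_any[draw].sum())
        else:
            acc = 0
            for g in draw[hits_any[draw]]:
                acc |= masks[g]
            perm_counts[b] = bin(acc).count("1")
    empirical_p = (1 + int(np.sum(perm_counts >= observed))) / (1 + n_perm)
    hist = {int(k): int(v) for k, v in zip(*np.unique(perm_counts, return_counts=True))}
    return EnrichmentResult(
        observed_sites_overlapping=obs_sites,
        observed_regions_hit=obs_regions,
        statistic=statistic,
        observed=int(observed),
        n_perm=n_perm,
        perm_mean=float(perm_counts.mean()),
        perm_sd=float(perm_counts.std(ddof=1)) if n_perm > 1 else 0.0,
        perm_histogram=hist,
        empirical_p=float(empirical_p),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genomic feature annotation


def _promoter_span(gene) -> tuple[int, int]:
    """1 kb upstream of the TSS, TSS included (strand-aware)."""
    if gene["strand"] == "+":
        tss = int(gene["tx_start"])
        return max(tss - 1000, 0), tss + 1
    if gene["strand"] == "-":
        tss = int(gene["tx_end"]) - 1
        return tss, tss + 1001
    raise ValueError(f"gene {gene.get('gene_id', '?')} has unknown strand {gene['strand']!r}")


def classify_peaks(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Assign each peak exactly one feature category by fixed precedence.

    Precedence: promoter > first_exon > utr5 > utr3 > intragenic > intergenic;
    assignment is by >=1 bp overlap with the corresponding feature span.
    Gene tables carry strand, tx bounds, first exon and optional UTR spans.
    """
    peaks = validate_intervals(peaks)
    spans: dict[str, list[tuple[str, int, int]]] = {c: [] for c in FEATURE_CATEGORIES[:-1]}
    for _, g in genes.iterrows():
        ps, pe = _promoter_span(g)
        spans["promoter"].append((g["chrom"], ps, pe))
        spans["first_exon"].append((g["chrom"], int(g["first_exon_start"]), int(g["first_exon_end"])))
        for cat, s_col, e_col in (("utr5", "utr5_start", "utr5_end"), ("utr3", "utr3_start", "utr3_end")):
            if s_col in g and pd.notna(g[s_col]):
                spans[cat].append((g["chrom"], int(g[s_col]), int(g[e_col])))
        spans["intragenic"].append((g["chrom"], int(g["tx_start"]), int(g["tx_end"])))

    labels = []
    for _, pk in peaks.iterrows():
        label = "intergenic"
        for cat in FEATURE_CATEGORIES[:-1]:
            if any(
                c == pk["chrom"] and pk["start"] < e and pk["end"] > s
                for c, s, e in spans[cat]
            ):
                label = cat
                break
        labels.append(label)
    return pd.Series(labels, index=peaks.index, name="feature_category")


def classify_peak(peak: pd.Series, genes: pd.DataFrame) -> str:
    """Single-peak convenience wrapper around :func:`classify_peaks`."""
    return classify_peaks(pd.DataFrame([peak]), genes).iloc[0]
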