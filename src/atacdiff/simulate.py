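"""Synthetic sorted-nuclei ATAC-seq data generator with planted ground truth.

Emulates the statistical structure of a NeuN-sorted brain ATAC-seq
case-control study: negative-binomial peak counts with a cell-type main
effect, disease (LOAD) effects planted in neuronal nuclei of both sexes but
in non-neuronal nuclei only at full strength in females (males carry an
attenuated trend), technical covariates confounded with a latent factor that
also feeds the counts, per-donor pairing of the neuronal and non-neuronal
fractions, read-position streams for library-complexity metrics, and GWAS
tag-SNP regions with a controllable fraction of differential peaks planted
inside their +/-100 kb windows.

All randomness flows through one seeded :class:`numpy.random.Generator`;
each component draws from an independent child stream so partial reruns are
reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import INTERVAL_COLUMNS, merge_intervals, peak_ids

LN2 = float(np.log(2.0))

#: Group means / SDs of the neuronal (NeuN+) percentage of sorted nuclei by
#: pathology, as observed in the cohort the generator emulates.
NEURONAL_FRACTION_PARAMS = {
    "control": (35.27, 13.26),
    "mild_LOAD": (38.59, 14.70),
    "severe_LOAD": (19.16, 7.49),
}

DEFAULT_CHROM_SIZES = {
    "chr1": 60_000_000,
    "chr2": 45_000_000,
    "chr3": 35_000_000,
    "chrX": 25_000_000,
    "chrY": 10_000_000,
}

#: Technical covariates generated alongside the design, with (loading onto the
#: latent technical factor, kind, number of levels for categoricals).
DEFAULT_CONFOUNDERS = (
    ("sort_date", 0.8, "categorical", 6),
    ("nrf", 0.6, "continuous", 1),
    ("alignment_pct", 0.5, "continuous", 1),
    ("nuclei_count", 0.5, "continuous", 1),
    ("gc_pct", 0.4, "continuous", 1),
    ("normalized_peak_calls", 0.6, "continuous", 1),
)


@dataclass(frozen=True)
class SampleSpec:
    """One sequenced library: a donor's neuronal or non-neuronal fraction."""

    sample_id: str
    donor_id: str
    cell_fraction: str  # "neuronal" | "non_neuronal"
    diagnosis: str  # "control" | "mild_LOAD" | "severe_LOAD"
    sex: str  # "F" | "M"

    def __post_init__(self):
        if self.cell_fraction not in ("neuronal", "non_neuronal"):
            raise ValueError(f"unknown cell_fraction {self.cell_fraction!r}")
        if self.diagnosis not in NEURONAL_FRACTION_PARAMS:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def is_case(self) -> bool:
        return self.diagnosis != "control"


@dataclass
class ConfounderSpec:
    name: str
    loading: float
    kind: str = "continuous"  # or "categorical"
    n_levels: int = 1
    noise_sd: float = 0.5

    def __post_init__(self):
        if self.kind == "categorical" and self.n_levels < 2:
            raise ValueError(f"categorical confounder {self.name} needs >=2 levels")


@dataclass
class EnrichmentSpec:
    n_gwas_regions: int = 25
    flank: int = 100_000
    planted_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if self.flank <= 0:
            raise ValueError("flank must be positive")


@dataclass
class SimulationConfig:
    """Generative settings; defaults mirror the emulated study at desk scale."""

    n_peaks: int = 2000
    chrom_sizes: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    design: list = None  # list[SampleSpec]; None -> study_cohort_design()
    baseline_log_mean_range: tuple = (0.0, 4.0)  # natural-log relative abundance
    phi0: float = 0.1  # NB dispersion intercept: phi_i = phi0 + decay / mean_i
    phi_decay: float = 0.0
    # planted effects, log2 scale; None -> drawn from the frac_*/lfc_range knobs
    cell_type_lfc: dict | None = None
    disease_lfc_neuronal: dict | None = None
    disease_lfc_non_neuronal: dict | None = None
    frac_cell_type: float = 0.20
    frac_disease: float = 0.02
    lfc_range: tuple = (0.5, 2.0)
    male_glial_attenuation: float = 0.3  # scale on non-neuronal effects in males
    confounders: tuple = DEFAULT_CONFOUNDERS
    latent_effect_sd: float = 0.0  # per-peak weight SD of the latent factor in log-mean
    library_size_mean: float = 1e5  # desk scale; the emulated study is ~2e7
    library_size_cv: float = 0.3
    n_missing_pmi: int = 2
    enrichment: EnrichmentSpec = field(default_factory=EnrichmentSpec)
    peak_len_log_median: float = float(np.log(500.0))
    peak_len_log_sd: float = 0.5
    peak_len_bounds: tuple = (100, 5000)
    seed: int = 0

    def __post_init__(self):
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if self.phi0 <= 0 or self.phi_decay < 0:
            raise ValueError("dispersion parameters must be positive")
        if not {"chrX", "chrY"} <= set(self.chrom_sizes):
            raise ValueError("chrom_sizes must include chrX and chrY")
        if self.design is None:
            self.design = study_cohort_design()

    def rng(self, component: str) -> np.random.Generator:
        """Independent child stream for one generator component."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _COMPONENT_KEYS[component]])
        )


_COMPONENT_KEYS = {
    "peaks": 1,
    "metadata": 2,
    "counts": 3,
    "positions": 4,
    "gwas": 5,
    "genes": 6,
}


def study_cohort_design() -> list[SampleSpec]:
    """Default cohort: 40 paired donors plus 9 unpaired non-neuronal donors.

    Paired donors: 19 LOAD (16 mild, 3 severe) vs 21 controls, females
    11 case / 11 control and males 8 case / 10 control, each contributing a
    neuronal and a non-neuronal sample.  Unpaired donors contribute
    non-neuronal samples only: 3 female mild-LOAD, 2 female controls and
    4 male controls, so the extended female non-neuronal comparison is
    14 cases vs 13 controls.
    """
    specs: list[SampleSpec] = []
    donor = 0

    def add(diag, sex, fractions):
        nonlocal donor
        donor += 1
        did = f"D{donor:03d}"
        for frac in fractions:
            suffix = "N" if frac == "neuronal" else "G"
            specs.append(SampleSpec(f"{did}_{suffix}", did, frac, diag, sex))

    paired = ["neuronal", "non_neuronal"]
    # female paired: 11 cases (9 mild + 2 severe), 11 controls
    for _ in range(9):
        add("mild_LOAD", "F", paired)
    for _ in range(2):
        add("severe_LOAD", "F", paired)
    for _ in range(11):
        add("control", "F", paired)
    # male paired: 8 cases (7 mild + 1 severe), 10 controls
    for _ in range(7):
        add("mild_LOAD", "M", paired)
    add("severe_LOAD", "M", paired)
    for _ in range(10):
        add("control", "M", paired)
    # unpaired non-neuronal donors
    unpaired = ["non_neuronal"]
    for _ in range(3):
        add("mild_LOAD", "F", unpaired)
    for _ in range(2):
        add("control", "F", unpaired)
    for _ in range(4):
        add("control", "M", unpaired)
    return specs


@dataclass
class GroundTruth:
    """Planted signal bookkeeping for downstream recovery tests."""

    differential_peak_ids: dict = field(default_factory=dict)  # contrast -> list[str]
    planted_lfc: dict = field(default_factory=dict)  # contrast -> {peak_id: log2FC}
    latent_scores: pd.Series | None = None  # per-sample technical factor
    gwas_region_ids: list = field(default_factory=list)  # regions holding planted peaks


# ---------------------------------------------------------------------------
# peak universe


def simulate_peak_universe(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw ``cfg.n_peaks`` disjoint peak intervals across the genome.

    Peak lengths are log-normal (median ~500 bp by default) truncated to
    ``cfg.peak_len_bounds``; peaks are allocated to chromosomes proportionally
    to size (so chrX/chrY carry peaks and sex-chromosome exclusion is
    exercised) and placed with >=1 bp gaps, sorted by (chrom, start).
    """
    rng = cfg.rng("peaks")
    if cfg.n_peaks == 0:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    chroms = sorted(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    alloc = np.floor(cfg.n_peaks * sizes / sizes.sum()).astype(int)
    for i in np.argsort(-sizes):
        if alloc.sum() >= cfg.n_peaks:
            break
        alloc[i] += cfg.n_peaks - alloc.sum()
    rows = []
    lo, hi = cfg.peak_len_bounds
    for chrom, n in zip(chroms, alloc):
        if n == 0:
            continue
        lengths = np.exp(rng.normal(cfg.peak_len_log_median, cfg.peak_len_log_sd, n))
        lengths = np.clip(np.round(lengths), lo, hi).astype(np.int64)
        needed = lengths.sum() + n + 1  # >=1 bp gap between/around peaks
        size = cfg.chrom_sizes[chrom]
        if needed > size:
            raise ValueError(
                f"chromosome {chrom} (size {size}) cannot hold {n} peaks "
                f"totalling {lengths.sum()} bp"
            )
        slack = size - lengths.sum() - (n + 1)
        gaps = rng.multinomial(int(slack), np.full(n + 1, 1.0 / (n + 1))) + 1
        starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + lengths}))
    peaks = pd.concat(rows, ignore_index=True)
    peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    assert len(merge_intervals(peaks)) == len(peaks)
    return peaks


# ---------------------------------------------------------------------------
# metadata


def simulate_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-sample metadata with latent-factor-driven technical covariates.

    Each technical covariate equals ``loading x latent + noise`` mapped to a
    plausible unit scale; the same latent factor is injected into the counts
    (scaled by ``cfg.latent_effect_sd``) so nonzero loadings make covariates
    genuinely associated with the leading count PCs.  Severe-LOAD donors get
    lower neuronal fractions; ``n_missing_pmi`` PMI values are set missing.
    """
    if not cfg.design:
        raise ValueError("design must be non-empty")
    seen = set()
    for s in cfg.design:
        key = (s.donor_id, s.cell_fraction)
        if key in seen:
            raise ValueError(f"duplicate (donor, cell_fraction): {key}")
        seen.add(key)

    rng = cfg.rng("metadata")
    n = len(cfg.design)
    latent = rng.standard_normal(n)

    donors = sorted({s.donor_id for s in cfg.design})
    donor_rows = {}
    for d in donors:
        spec = next(s for s in cfg.design if s.donor_id == d)
        mean, sd = NEURONAL_FRACTION_PARAMS[spec.diagnosis]
        donor_rows[d] = {
            "age": float(np.clip(rng.normal(80.2, 8.5), 55, 100)),
            "pmi": float(np.clip(rng.gamma(2.0, 7.4 / 2.0), 0.5, 40)),
            "neuronal_fraction_pct": float(np.clip(rng.normal(mean, sd), 0, 100)),
        }

    records = []
    for i, s in enumerate(cfg.design):
        rec = {
            "sample_id": s.sample_id,
            "donor_id": s.donor_id,
            "cell_fraction": s.cell_fraction,
            "diagnosis": s.diagnosis,
            "is_case": s.is_case,
            "sex": s.sex,
            **donor_rows[s.donor_id],
        }
        t = latent[i]
        for name, loading, kind, n_levels in _confounder_tuples(cfg.confounders):
            noise_sd = float(np.sqrt(max(1e-12, 1.0 - min(loading**2, 1.0)))) if loading else 1.0
            raw = loading * t + noise_sd * rng.standard_normal()
            if kind == "categorical":
                rec[name] = raw  # binned into levels below
            else:
                rec[name] = _to_unit_scale(name, raw)
        records.append(rec)
    meta = pd.DataFrame.from_records(records).set_index("sample_id")

    for name, loading, kind, n_levels in _confounder_tuples(cfg.confounders):
        if kind == "categorical":
            ranks = meta[name].rank(method="first") - 1
            levels = (ranks * n_levels / len(meta)).astype(int).clip(upper=n_levels - 1)
            meta[name] = [f"{name}_{lv:02d}" for lv in levels]

    if cfg.n_missing_pmi:
        drop = rng.choice(len(donors), size=min(cfg.n_missing_pmi, len(donors)), replace=False)
        missing = {donors[j] for j in drop}
        meta.loc[meta["donor_id"].isin(missing), "pmi"] = np.nan

    meta.attrs["latent"] = pd.Series(latent, index=meta.index, name="latent")
    return meta


def _confounder_tuples(confounders):
    out = []
    for c in confounders:
        if isinstance(c, ConfounderSpec):
            out.append((c.name, c.loading, c.kind, c.n_levels))
        else:
            out.append(tuple(c))
    return out


def _to_unit_scale(name: str, x: float) -> float:
    """Map a standardized covariate draw onto the metric's natural units."""
    if name == "nrf":
        return float(np.clip(0.85 + 0.04 * x, 0.0, 1.0))
    if name == "alignment_pct":
        return float(np.clip(90.0 + 3.0 * x, 0.0, 100.0))
    if name == "nuclei_count":
        return float(3e5 * np.exp(0.25 * x))
    if name == "gc_pct":
        return float(np.clip(41.0 + 1.5 * x, 0.0, 100.0))
    if name == "normalized_peak_calls":
        return float(max(600.0 + 150.0 * x, 1.0))
    return float(x)


# ---------------------------------------------------------------------------
# counts


def _draw_effects(rng, n_peaks, frac, lfc_range):
    k = int(round(frac * n_peaks))
    idx = rng.choice(n_peaks, size=k, replace=False)
    mags = rng.uniform(*lfc_range, size=k)
    signs = rng.choice([-1.0, 1.0], size=k)
    return dict(zip(idx.tolist(), (mags * signs).tolist()))


def simulate_counts(
    cfg: SimulationConfig, peaks: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial counts with planted cell-type/disease/latent effects.

    ``log mu_ij = log s_j + baseline_i + ln2 * (planted log2 effects) +
    w_i * latent_j`` with per-sample relative abundances renormalized so
    expected column sums equal the drawn library sizes;
    ``y_ij ~ NB(mu_ij, phi_i)`` via the gamma-Poisson mixture.

    Disease effects follow the study's headline structure: neuronal effects
    in both sexes at full strength; non-neuronal effects at full strength in
    females and attenuated by ``cfg.male_glial_attenuation`` in males.
    """
    rng = cfg.rng("counts")
    G, n = len(peaks), len(metadata)
    if G == 0 or n == 0:
        raise ValueError("need at least one peak and one sample")
    ids = peak_ids(peaks)

    cell_lfc = cfg.cell_type_lfc
    dis_neu = cfg.disease_lfc_neuronal
    dis_glia = cfg.disease_lfc_non_neuronal
    if cell_lfc is None:
        cell_lfc = _draw_effects(rng, G, cfg.frac_cell_type, cfg.lfc_range)
    if dis_neu is None:
        dis_neu = _draw_effects(rng, G, cfg.frac_disease, cfg.lfc_range)
    if dis_glia is None:
        dis_glia = _draw_effects(rng, G, cfg.frac_disease, cfg.lfc_range)
    for table in (cell_lfc, dis_neu, dis_glia):
        for k in table:
            if not 0 <= int(k) < G:
                raise ValueError(f"effect table indexes peak {k} outside the universe of {G}")

    baseline = rng.uniform(*cfg.baseline_log_mean_range, size=G)
    latent = metadata.attrs.get("latent")
    if latent is None:
        latent = pd.Series(np.zeros(n), index=metadata.index)
    w = (
        rng.standard_normal(G) * cfg.latent_effect_sd
        if cfg.latent_effect_sd > 0
        else np.zeros(G)
    )

    log_rel = np.tile(baseline[:, None], (1, n))
    is_neuronal = (metadata["cell_fraction"] == "neuronal").to_numpy()
    is_case = metadata["is_case"].to_numpy()
    is_female = (metadata["sex"] == "F").to_numpy()
    for k, lfc in cell_lfc.items():
        log_rel[int(k), is_neuronal] += LN2 * lfc
    for k, lfc in dis_neu.items():
        log_rel[int(k), is_neuronal & is_case] += LN2 * lfc
    for k, lfc in dis_glia.items():
        log_rel[int(k), ~is_neuronal & is_case & is_female] += LN2 * lfc
        log_rel[int(k), ~is_neuronal & is_case & ~is_female] += (
            LN2 * lfc * cfg.male_glial_attenuation
        )
    log_rel += w[:, None] * latent.to_numpy()[None, :]

    sigma = float(np.sqrt(np.log1p(cfg.library_size_cv**2)))
    lib = cfg.library_size_mean * np.exp(
        rng.normal(-0.5 * sigma**2, sigma, size=n)
    )
    rel = np.exp(log_rel - log_rel.max(axis=0, keepdims=True))
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]

    phi = cfg.phi0 + cfg.phi_decay / np.maximum(mu.mean(axis=1), 1e-8)
    if np.all(phi < 1e-10):
        y = rng.poisson(mu)
    else:
        shape = 1.0 / phi
        lam = rng.gamma(shape[:, None], (mu * phi[:, None]))
        y = rng.poisson(lam)
    counts = pd.DataFrame(y.astype(np.int64), index=ids, columns=metadata.index)

    truth = GroundTruth(
        differential_peak_ids={
            "cell_type": [ids[int(k)] for k in sorted(cell_lfc)],
            "disease_neuronal": [ids[int(k)] for k in sorted(dis_neu)],
            "disease_non_neuronal": [ids[int(k)] for k in sorted(dis_glia)],
        },
        planted_lfc={
            "cell_type": {ids[int(k)]: v for k, v in cell_lfc.items()},
            "disease_neuronal": {ids[int(k)]: v for k, v in dis_neu.items()},
            "disease_non_neuronal": {ids[int(k)]: v for k, v in dis_glia.items()},
        },
        latent_scores=latent,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# read positions (library complexity)


def simulate_read_positions(
    depth: int,
    distinct_fraction: float | None = None,
    duplication_profile: dict[int, int] | None = None,
    rng: np.random.Generator | None = None,
    span: int = 10_000_000,
) -> np.ndarray:
    """A multiset of abstract genomic positions with controlled duplication.

    Either give ``distinct_fraction`` (distinct/total read ratio, achieved up
    to rounding by piling the surplus reads onto a minimal set of positions)
    or an explicit ``duplication_profile`` mapping multiplicity -> number of
    positions, whose total must equal ``depth`` when both are given.
    """
    rng = rng or np.random.default_rng()
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if duplication_profile is not None:
        total = sum(m * c for m, c in duplication_profile.items())
        if any(m < 1 or c < 0 for m, c in duplication_profile.items()):
            raise ValueError("duplication profile entries must be positive")
        if depth and total != depth:
            raise ValueError(
                f"duplication profile totals {total} reads but depth={depth}"
            )
        profile = dict(duplication_profile)
    else:
        if distinct_fraction is None:
            distinct_fraction = 1.0
        if not 0 < distinct_fraction <= 1:
            raise ValueError("distinct_fraction must lie in (0, 1]")
        n_distinct = max(1, int(round(depth * distinct_fraction))) if depth else 0
        surplus = depth - n_distinct
        profile = {}
        if n_distinct:
            # spread the surplus as evenly as possible over the distinct set
            extra_each, rem = divmod(surplus, n_distinct)
            base = 1 + extra_each
            if rem:
                profile[base + 1] = rem
            if n_distinct - rem:
                profile[base] = n_distinct - rem
    n_pos = sum(profile.values())
    positions = np.array([], dtype=np.int64)
    while len(positions) < n_pos:  # rejection-style unique sampling
        draw = rng.integers(0, span, size=2 * (n_pos - len(positions)) + 8)
        positions = np.unique(np.concatenate([positions, draw]))
    positions = rng.permutation(positions)[:n_pos]
    multiset = np.repeat(
        positions,
        np.concatenate([[m] * c for m, c in profile.items()]).astype(int)
        if n_pos
        else [],
    )
    return np.sort(multiset)


# ---------------------------------------------------------------------------
# GWAS regions


def plant_gwas_regions(
    cfg: SimulationConfig,
    peaks: pd.DataFrame,
    truth: GroundTruth,
    contrast: str = "disease_non_neuronal",
) -> pd.DataFrame:
    """Place tag-SNP regions; a planted fraction of differential peaks fall inside.

    A ``planted_fraction`` share of the contrast's differential peaks get a
    SNP at their midpoint (so the +/-flank window covers them); the remaining
    regions are placed so their windows avoid every differential peak.
    Updates ``truth.gwas_region_ids`` with the planted region ids.
    """
    spec = cfg.enrichment
    rng = cfg.rng("gwas")
    diff_ids = truth.differential_peak_ids.get(contrast, [])
    n_plant = int(round(spec.planted_fraction * len(diff_ids)))
    if n_plant > spec.n_gwas_regions:
        raise ValueError(
            f"planted_fraction requires {n_plant} regions but only "
            f"{spec.n_gwas_regions} are configured"
        )
    id_index = pd.Index(peak_ids(peaks))
    diff_rows = peaks.loc[id_index.get_indexer(diff_ids)] if diff_ids else peaks.iloc[:0]
    planted = (
        diff_rows.iloc[rng.choice(len(diff_rows), size=n_plant, replace=False)]
        if n_plant
        else diff_rows.iloc[:0]
    )

    records, region_ids = [], []
    for j, (_, row) in enumerate(planted.iterrows()):
        snp_id = f"rsim{j:04d}"
        pos = int((row["start"] + row["end"]) // 2)
        records.append((snp_id, row["chrom"], pos, f"planted_{j}"))
        region_ids.append(snp_id)

    chroms = sorted(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    diff_mid = {
        c: diff_rows.loc[diff_rows["chrom"] == c, ["start", "end"]].to_numpy()
        for c in chroms
    }
    j = len(records)
    attempts = 0
    while j < spec.n_gwas_regions:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place null GWAS regions away from peaks")
        ci = rng.choice(len(chroms), p=sizes / sizes.sum())
        chrom = chroms[ci]
        pos = int(rng.integers(0, cfg.chrom_sizes[chrom]))
        lo, hi = max(pos - spec.flank, 0), pos + spec.flank
        spans = diff_mid[chrom]
        if len(spans) and np.any((spans[:, 0] < hi) & (spans[:, 1] > lo)):
            continue  # window would swallow a differential peak
        records.append((f"rsim{j:04d}", chrom, pos, f"null_{j}"))
        j += 1

    truth.gwas_region_ids = region_ids
    return pd.DataFrame(records, columns=["snp_id", "chrom", "pos", "label"])


# ---------------------------------------------------------------------------
# gene models (annotation plumbing)


def random_gene_models(cfg: SimulationConfig, n_genes: int = 50) -> pd.DataFrame:
    """Small random gene table for exercising peak annotation.

    Columns: gene_id, chrom, strand, tx_start, tx_end, first_exon_start/end,
    utr5_start/end, utr3_start/end (0-based half-open).
    """
    rng = cfg.rng("genes")
    chroms = sorted(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    rows = []
    for g in range(n_genes):
        chrom = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
        length = int(rng.integers(5_000, 50_000))
        tx_start = int(rng.integers(0, max(cfg.chrom_sizes[chrom] - length, 1)))
        tx_end = tx_start + length
        strand = "+" if rng.random() < 0.5 else "-"
        exon_len = int(rng.integers(200, 1500))
        if strand == "+":
            fe_s, fe_e = tx_start, tx_start + exon_len
            utr5 = (tx_start, tx_start + exon_len // 3)
            utr3 = (tx_end - 300, tx_end)
        else:
            fe_s, fe_e = tx_end - exon_len, tx_end
            utr5 = (tx_end - exon_len // 3, tx_end)
            utr3 = (tx_start, tx_start + 300)
        rows.append(
            (f"G{g:04d}", chrom, strand, tx_start, tx_end, fe_s, fe_e, *utr5, *utr3)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "strand", "tx_start", "tx_end",
            "first_exon_start", "first_exon_end",
            "utr5_start", "utr5_end", "utr3_start", "utr3_end",
        ],
    )


# ---------------------------------------------------------------------------
# one-call convenience


def simulate_dataset(cfg: SimulationConfig):
    """Generate peaks, metadata, counts, GWAS regions and ground truth."""
    peaks = simulate_peak_universe(cfg)
    metadata = simulate_metadata(cfg)
    counts, truth = simulate_counts(cfg, peaks, metadata)
    regions = plant_gwas_regions(cfg, peaks, truth)
    return peaks, metadata, counts, regions, truth


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["design"] = [dataclasses.asdict(s) for s in cfg.design]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if d.get("design"):
        d["design"] = [SampleSpec(**s) for s in d["design"]]
    if isinstance(d.get("enrichment"), dict):
        d["enrichment"] = EnrichmentSpec(**d["enrichment"])
    for key in ("baseline_log_mean_range", "lfc_range", "peak_len_bounds"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if "confounders" in d and d["confounders"] is not None:
        d["confounders"] = tuple(tuple(c) for c in d["confounders"])
    return SimulationConfig(**d)
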