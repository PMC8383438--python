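"""Generator contracts: determinism, planted effects, cohort structure,
confounding injection, read-position profiles, GWAS planting."""

import numpy as np
import pandas as pd
import pytest

from atacdiff.enrichment import build_gwas_windows, overlap_regions
from atacdiff.intervals import is_sex_chromosome, merge_intervals, peak_ids
from atacdiff.normalize import cpm_log, tmm_factors
from atacdiff.simulate import (
    NEURONAL_FRACTION_PARAMS,
    SampleSpec,
    SimulationConfig,
    plant_gwas_regions,
    simulate_counts,
    simulate_dataset,
    simulate_metadata,
    simulate_peak_universe,
    simulate_read_positions,
    study_cohort_design,
)
from conftest import two_group_design


class TestPeakUniverse:
    def test_zero_peaks_empty(self):
        assert simulate_peak_universe(SimulationConfig(n_peaks=0)).empty

    def test_deterministic_and_disjoint(self):
        cfg = SimulationConfig(n_peaks=1000, seed=5)
        p1 = simulate_peak_universe(cfg)
        p2 = simulate_peak_universe(SimulationConfig(n_peaks=1000, seed=5))
        pd.testing.assert_frame_equal(p1, p2)
        assert len(p1) == 1000
        assert len(merge_intervals(p1)) == 1000  # already disjoint
        # pairwise check within chromosomes (sorted): no overlap, inside bounds
        for chrom, grp in p1.groupby("chrom"):
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()
            assert grp["end"].max() <= cfg.chrom_sizes[chrom]

    def test_sex_chromosomes_carry_peaks(self):
        p = simulate_peak_universe(SimulationConfig(n_peaks=1000, seed=1))
        assert is_sex_chromosome(p["chrom"]).sum() > 0

    def test_capacity_error_names_chromosome(self):
        cfg = SimulationConfig(
            n_peaks=2000,
            chrom_sizes={"chr1": 5000, "chrX": 5000, "chrY": 5000},
        )
        with pytest.raises(ValueError, match="chr"):
            simulate_peak_universe(cfg)


class TestMetadata:
    def test_duplicate_donor_fraction_rejected(self):
        dup = [
            SampleSpec("a", "d1", "neuronal", "control", "F"),
            SampleSpec("b", "d1", "neuronal", "control", "F"),
            SampleSpec("c", "d1", "non_neuronal", "control", "F"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_metadata(SimulationConfig(design=dup))

    def test_neuronal_fraction_group_means_recovered(self):
        # large synthetic cohort: per-diagnosis means within 2 SEM of the targets
        n_per = 1000
        design = []
        for diag in ("control", "mild_LOAD", "severe_LOAD"):
            for i in range(n_per):
                design.append(
                    SampleSpec(f"{diag[:2]}{i}", f"{diag[:2]}{i}", "non_neuronal", diag, "F")
                )
        meta = simulate_metadata(SimulationConfig(design=design, seed=3, n_missing_pmi=0))
        for diag, (mean, sd) in NEURONAL_FRACTION_PARAMS.items():
            got = meta.loc[meta["diagnosis"] == diag, "neuronal_fraction_pct"].mean()
            assert abs(got - mean) < 2 * sd / np.sqrt(n_per), diag

    def test_unit_loading_covariate_collinear_with_latent(self):
        cfg = SimulationConfig(
            design=two_group_design(15),
            confounders=(("latent_proxy", 1.0, "continuous", 1),),
            seed=9,
        )
        meta = simulate_metadata(cfg)
        latent = meta.attrs["latent"]
        r = np.corrcoef(meta["latent_proxy"], latent)[0, 1]
        assert r > 1 - 1e-10

    def test_missing_pmi_count(self):
        meta = simulate_metadata(SimulationConfig(seed=2, n_missing_pmi=2))
        assert meta.drop_duplicates("donor_id")["pmi"].isna().sum() == 2

    def test_study_cohort_arithmetic(self):
        meta = simulate_metadata(SimulationConfig(seed=0))
        paired = meta.groupby("donor_id")["cell_fraction"].nunique()
        assert (paired == 2).sum() == 40 and (paired == 1).sum() == 9
        glia_f = meta[(meta["cell_fraction"] == "non_neuronal") & (meta["sex"] == "F")]
        assert int(glia_f["is_case"].sum()) == 14
        assert int((~glia_f["is_case"]).sum()) == 13


class TestCounts:
    def test_null_generator_equal_group_means(self):
        cfg = SimulationConfig(
            n_peaks=300, design=two_group_design(60), seed=4,
            frac_cell_type=0.0, frac_disease=0.0, phi0=1e-12,
            library_size_cv=0.0, latent_effect_sd=0.0,
        )
        peaks = simulate_peak_universe(cfg)
        meta = simulate_metadata(cfg)
        counts, _ = simulate_counts(cfg, peaks, meta)
        case = counts.loc[:, meta["is_case"]].mean(axis=1)
        ctrl = counts.loc[:, ~meta["is_case"]].mean(axis=1)
        mu = counts.mean(axis=1)
        # Poisson MC error on the difference of group means
        se = np.sqrt(2 * mu / 60)
        frac_outside = np.mean(np.abs(case - ctrl) > 4 * se)
        assert frac_outside < 0.01

    def test_planted_lfc_recovered_by_mean_ratio(self):
        cfg = SimulationConfig(
            n_peaks=400, design=two_group_design(100), seed=8,
            frac_cell_type=0.0, disease_lfc_neuronal={},
            disease_lfc_non_neuronal={7: 2.0}, phi0=0.05,
            library_size_cv=0.0, latent_effect_sd=0.0,
        )
        peaks = simulate_peak_universe(cfg)
        meta = simulate_metadata(cfg)
        counts, truth = simulate_counts(cfg, peaks, meta)
        pid = peak_ids(peaks)[7]
        assert truth.differential_peak_ids["disease_non_neuronal"] == [pid]
        ratio = np.log2(
            counts.loc[pid, meta["is_case"]].mean() / counts.loc[pid, ~meta["is_case"]].mean()
        )
        assert abs(ratio - 2.0) < 0.25

    def test_nb_moments(self):
        # constant libraries, no effects: across-sample variance ~ mu + phi mu^2
        cfg = SimulationConfig(
            n_peaks=500, design=two_group_design(150), seed=12,
            frac_cell_type=0.0, frac_disease=0.0, phi0=0.3,
            library_size_cv=0.0, latent_effect_sd=0.0,
        )
        peaks = simulate_peak_universe(cfg)
        meta = simulate_metadata(cfg)
        counts, _ = simulate_counts(cfg, peaks, meta)
        arr = counts.to_numpy(dtype=float)
        mu = arr.mean(axis=1)
        v = arr.var(axis=1, ddof=1)
        expected = mu + cfg.phi0 * mu**2
        keep = mu > 5
        ratio = np.mean(v[keep]) / np.mean(expected[keep])
        assert abs(ratio - 1.0) < 0.1

    def test_effect_index_outside_universe_rejected(self):
        cfg = SimulationConfig(n_peaks=50, design=two_group_design(3),
                               disease_lfc_non_neuronal={200: 1.0}, cell_type_lfc={},
                               disease_lfc_neuronal={})
        peaks = simulate_peak_universe(cfg)
        meta = simulate_metadata(cfg)
        with pytest.raises(ValueError, match="outside"):
            simulate_counts(cfg, peaks, meta)

    def test_library_sums_within_3sd(self):
        cfg = SimulationConfig(n_peaks=400, seed=21)
        peaks, meta, counts, _, _ = simulate_dataset(cfg)
        colsums = counts.sum(axis=0).to_numpy(dtype=float)
        sd = cfg.library_size_mean * cfg.library_size_cv
        assert np.mean(np.abs(colsums - cfg.library_size_mean) < 3 * sd) > 0.95
        assert (counts.to_numpy() >= 0).all()

    def test_byte_identical_outputs_same_seed(self):
        a = simulate_dataset(SimulationConfig(n_peaks=200, seed=33))
        b = simulate_dataset(SimulationConfig(n_peaks=200, seed=33))
        pd.testing.assert_frame_equal(a[2], b[2])
        pd.testing.assert_frame_equal(a[3], b[3])

    def test_confounding_monotone_in_loading(self):
        corrs = []
        for loading in (0.2, 0.5, 1.0):
            vals = []
            for seed in (1, 2, 3):
                cfg = SimulationConfig(
                    n_peaks=300, design=two_group_design(25), seed=seed,
                    frac_cell_type=0.0, frac_disease=0.0,
                    confounders=(("cov", loading, "continuous", 1),),
                    latent_effect_sd=0.5,
                )
                peaks = simulate_peak_universe(cfg)
                meta = simulate_metadata(cfg)
                counts, _ = simulate_counts(cfg, peaks, meta)
                logcpm = cpm_log(counts, tmm_factors(counts))
                centered = logcpm.T - logcpm.T.mean()
                u, s, _ = np.linalg.svd(centered, full_matrices=False)
                pc1 = u[:, 0] * s[0]
                vals.append(abs(np.corrcoef(meta["cov"], pc1)[0, 1]))
            corrs.append(np.mean(vals))
        assert corrs[0] < corrs[1] < corrs[2]

    def test_zero_loading_covariate_independent_of_pc1(self):
        cfg = SimulationConfig(
            n_peaks=300, design=two_group_design(40), seed=17,
            frac_cell_type=0.0, frac_disease=0.0,
            confounders=(("cov", 0.0, "continuous", 1),),
            latent_effect_sd=0.5,
        )
        peaks = simulate_peak_universe(cfg)
        meta = simulate_metadata(cfg)
        counts, _ = simulate_counts(cfg, peaks, meta)
        logcpm = cpm_log(counts, tmm_factors(counts))
        centered = logcpm.T - logcpm.T.mean()
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        r = np.corrcoef(meta["cov"], u[:, 0])[0, 1]
        assert abs(r) < 3.5 / np.sqrt(len(meta))  # null band


class TestReadPositions:
    def test_all_distinct(self, rng):
        pos = simulate_read_positions(100, distinct_fraction=1.0, rng=rng)
        assert len(pos) == 100 and len(np.unique(pos)) == 100

    def test_all_duplicated_twice(self, rng):
        pos = simulate_read_positions(100, distinct_fraction=0.5, rng=rng)
        assert len(pos) == 100 and len(np.unique(pos)) == 50

    def test_profile_histogram_exact(self, rng):
        profile = {1: 6, 2: 2, 5: 1}
        pos = simulate_read_positions(15, duplication_profile=profile, rng=rng)
        _, counts = np.unique(pos, return_counts=True)
        got = dict(zip(*np.unique(counts, return_counts=True)))
        assert got == profile

    def test_infeasible_profile_rejected(self, rng):
        with pytest.raises(ValueError, match="depth"):
            simulate_read_positions(10, duplication_profile={2: 3}, rng=rng)


class TestGwasPlanting:
    def _dataset(self, planted_fraction, seed=6, n_regions=10):
        from atacdiff.simulate import EnrichmentSpec

        cfg = SimulationConfig(
            n_peaks=400, design=two_group_design(6), seed=seed,
            frac_cell_type=0.0, disease_lfc_neuronal={},
            disease_lfc_non_neuronal={k: 2.0 for k in range(10)},
            enrichment=EnrichmentSpec(n_gwas_regions=n_regions, flank=50_000,
                                      planted_fraction=planted_fraction),
        )
        peaks = simulate_peak_universe(cfg)
        meta = simulate_metadata(cfg)
        counts, truth = simulate_counts(cfg, peaks, meta)
        regions = plant_gwas_regions(cfg, peaks, truth)
        diff = peaks[peak_ids(peaks).isin(truth.differential_peak_ids["disease_non_neuronal"])]
        return cfg, diff, regions, truth

    def test_full_planting_forces_overlap(self):
        cfg, diff, regions, truth = self._dataset(1.0)
        windows = build_gwas_windows(regions, flank=cfg.enrichment.flank)
        n_sites, _, _ = overlap_regions(diff, windows)
        assert n_sites == 10 and len(truth.gwas_region_ids) == 10

    def test_null_placement_avoids_differential_peaks(self):
        cfg, diff, regions, truth = self._dataset(0.0)
        windows = build_gwas_windows(regions, flank=cfg.enrichment.flank)
        n_sites, _, _ = overlap_regions(diff, windows)
        assert n_sites == 0 and truth.gwas_region_ids == []

    def test_intermediate_fraction_recounts_exactly(self):
        cfg, diff, regions, truth = self._dataset(0.5)
        windows = build_gwas_windows(regions, flank=cfg.enrichment.flank)
        n_sites, _, _ = overlap_regions(diff, windows)
        assert n_sites == 5

    def test_overdemanding_fraction_rejected(self):
        with pytest.raises(ValueError, match="regions"):
            self._dataset(1.0, n_regions=4)


def test_default_design_matches_cohort_structure():
    design = study_cohort_design()
    assert len(design) == 89
    cases = sum(s.is_case for s in design if s.cell_fraction == "neuronal")
    ctrls = sum(not s.is_case for s in design if s.cell_fraction == "neuronal")
    assert (cases, ctrls) == (19, 21)
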