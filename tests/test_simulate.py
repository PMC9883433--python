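"""Synthetic-cohort generator contracts: determinism, planted effects,
relatedness, phenotype structure and config validation."""

import numpy as np
import pytest

from rdvload.cohort import write_vcf
from rdvload.simulate import (
    GeneSpec,
    RelatednessSpec,
    SimulationConfig,
    simulate_burden_replicates,
    simulate_cohort,
    simulate_tumor_phenotypes,
    write_cohort,
)

_NOREL = RelatednessSpec(0, 0, 0)


def _slim_config(**kw):
    genes = tuple(GeneSpec(f"SET{i:02d}", str(i % 22 + 1), "+-"[i % 2], 2000)
                  for i in range(8))
    defaults = dict(
        genes=genes, gene_sets={"SET": [g.name for g in genes]},
        planted_logor={"SET": float(np.log(1.5))}, phenotype_gene_set="SET",
        synonymous_rate=0.0, n_common_snps=60, related=_NOREL,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_identical_seed_gives_identical_vcf_bytes(tmp_path):
    cfg = _slim_config(n_cases=40, n_controls=40, seed=9)
    a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
    write_vcf(simulate_cohort(cfg).genotypes, a)
    write_vcf(simulate_cohort(cfg).genotypes, b)
    assert a.read_bytes() == b.read_bytes()


def test_different_seed_changes_output():
    cfg1 = _slim_config(n_cases=40, n_controls=40, seed=1)
    cfg2 = _slim_config(n_cases=40, n_controls=40, seed=2)
    assert not np.array_equal(simulate_cohort(cfg1).genotypes.gt,
                              simulate_cohort(cfg2).genotypes.gt)


def test_null_effect_carrier_frequencies_balanced():
    cfg = _slim_config(n_cases=2000, n_controls=2000, seed=3,
                       planted_logor={"SET": 0.0})
    tp = simulate_cohort(cfg).truth["participants"]
    f_case = tp.loc[tp.status == 1, "carrier_SET"].mean()
    f_ctrl = tp.loc[tp.status == 0, "carrier_SET"].mean()
    se = np.sqrt(f_ctrl * (1 - f_ctrl) * (1 / 2000 + 1 / 2000))
    assert abs(f_case - f_ctrl) < 4 * se


def test_planted_or_converges_to_target():
    """Empirical carrier OR approaches exp(planted log-odds) at n=20,000."""
    cfg = _slim_config(n_cases=10_000, n_controls=10_000, seed=7)
    tp = simulate_cohort(cfg).truth["participants"]
    a = ((tp.status == 1) & tp.carrier_SET).sum()
    b = ((tp.status == 1) & ~tp.carrier_SET).sum()
    c = ((tp.status == 0) & tp.carrier_SET).sum()
    d = ((tp.status == 0) & ~tp.carrier_SET).sum()
    lor = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert abs(lor - np.log(1.5)) < 3 * se


def test_unknown_planted_set_is_config_error():
    with pytest.raises(ValueError, match="unknown gene-set"):
        _slim_config(planted_logor={"nope": 0.5}).validate()


def test_overlapping_planted_sets_rejected():
    genes = tuple(GeneSpec(f"G{i}", "1", "+", 2000) for i in range(4))
    cfg = SimulationConfig(
        genes=genes,
        gene_sets={"A": ["G0", "G1"], "B": ["G1", "G2"]},
        planted_logor={"A": 0.4, "B": 0.4},
        phenotype_gene_set="A", related=_NOREL,
    )
    with pytest.raises(ValueError, match="disjoint"):
        cfg.validate()


def test_geneset_without_variants_warns_and_skips():
    genes = (GeneSpec("G0", "1", "+", 2000), GeneSpec("G1", "2", "+", 2000))
    cfg = SimulationConfig(
        n_cases=30, n_controls=30, genes=genes,
        gene_sets={"A": ["G0"], "B": ["G1"]},
        planted_logor={"A": 0.4, "B": 0.4},
        n_deleterious_per_gene=0,  # no qualifying variants anywhere
        phenotype_gene_set="A", related=_NOREL, synonymous_rate=0.0,
        n_common_snps=30,
    )
    with pytest.warns(UserWarning, match="no qualifying variants"):
        cohort = simulate_cohort(cfg)
    assert cohort.truth["planted_logor"] == {}


def test_related_pairs_have_expected_sharing(small_cohort):
    from rdvload.cohort_qc import estimate_kinship

    g = small_cohort.genotypes
    common = small_cohort.truth["variants"]["kind"] == "common"
    idx = np.flatnonzero(common.to_numpy())
    for row in small_cohort.truth["related_pairs"].itertuples():
        i = g.samples.index(row.id1)
        j = g.samples.index(row.id2)
        est = estimate_kinship(g.gt[idx, i], g.gt[idx, j])
        tol = {"duplicate": 1e-12, "first": 0.04, "second": 0.05}[row.degree]
        assert est.phi == pytest.approx(row.expected_phi, abs=max(tol, 1e-12))


def test_immune_fractions_normalized_and_leukocyte_bounded(small_cohort):
    tumor = small_cohort.tumor
    frac_cols = [c for c in tumor.columns if c.startswith("frac_")]
    assert len(frac_cols) == 22
    sums = tumor[frac_cols].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert tumor["leukocyte_fraction"].between(0, 1).all()
    assert (tumor["survival_time"] > 0).all()
    assert tumor["survival_event"].isin([0, 1]).all()


def test_tmb_multiplier_scales_mean_counts():
    """Load multiplier 2.0 doubles expected somatic counts (law of large numbers)."""
    cfg = _slim_config(n_cases=4000, n_controls=100, seed=13,
                       maf_range=(1e-3, 8e-3))  # enough multi-gene carriers
    cohort = simulate_cohort(cfg)
    tp = cohort.truth["participants"]
    load = tp.loc[cohort.tumor.index, "load_SET"]
    counts = cohort.tumor[["n_missense", "n_nonsense", "n_frameshift", "n_inframe"]].sum(axis=1)
    m_zero = counts[load == "zero"].mean()
    m_multi = counts[load == "multi"].mean()
    assert (load == "multi").sum() >= 20
    assert m_multi / m_zero == pytest.approx(2.0, rel=0.1)


def test_zero_phenotype_effects_leave_onset_unshifted():
    from rdvload.simulate import PhenotypeEffects

    cfg = _slim_config(
        n_cases=3000, n_controls=100, seed=14,
        phenotype_effects=PhenotypeEffects(
            onset_shift_years=(0.0, 0.0, 0.0),
            tmb_multiplier=(1.0, 1.0, 1.0),
            m1_alpha_multiplier=(1.0, 1.0, 1.0),
        ),
    )
    cohort = simulate_cohort(cfg)
    tp = cohort.truth["participants"]
    load = tp.loc[cohort.tumor.index, "load_SET"]
    onset = cohort.tumor["age_at_diagnosis"]
    from rdvload.load_phenotype import mann_whitney

    res = mann_whitney(onset[load != "zero"], onset[load == "zero"], exact_max=0)
    assert res.p_value > 0.01


def test_onset_shift_lowers_age_with_load():
    cfg = _slim_config(n_cases=3000, n_controls=100, seed=15)
    cohort = simulate_cohort(cfg)
    tp = cohort.truth["participants"]
    load = tp.loc[cohort.tumor.index, "load_SET"]
    onset = cohort.tumor["age_at_diagnosis"]
    assert onset[load == "one"].mean() < onset[load == "zero"].mean()


def test_truth_covers_every_participant_and_dimensions_match(small_cohort):
    g = small_cohort.genotypes
    tp = small_cohort.truth["participants"]
    assert list(tp.index) == g.samples
    assert len(small_cohort.annotations) == g.n_variants
    assert set(small_cohort.tumor.index) == set(tp.index[tp.status == 1])


def test_reduced_generator_matches_retrospective_model():
    rng = np.random.default_rng(30)
    y, carriers, cov = simulate_burden_replicates(20_000, 20_000, 0.05, np.log(2.0), 1, rng)
    f_case = carriers[y == 1, 0].mean()
    f_ctrl = carriers[y == 0, 0].mean()
    lor = np.log(f_case / (1 - f_case)) - np.log(f_ctrl / (1 - f_ctrl))
    assert lor == pytest.approx(np.log(2.0), abs=0.1)


def test_write_cohort_round_trip(tmp_path, small_cohort):
    paths = write_cohort(small_cohort, tmp_path)
    import json

    import pandas as pd

    from rdvload.cohort import read_vcf
    from rdvload.simulate import read_gmt

    rt = read_vcf(paths["vcf"])
    assert rt.n_samples == small_cohort.genotypes.n_samples
    assert np.array_equal(rt.gt, small_cohort.genotypes.gt)
    ann = pd.read_csv(paths["annotations"], sep="\t")
    assert len(ann) == small_cohort.genotypes.n_variants
    sets = read_gmt(paths["gene_sets"])
    assert sets.keys() == small_cohort.gene_sets.keys()
    truth = json.load(open(paths["truth"]))
    assert truth["seed"] == small_cohort.truth["seed"]


def test_tumor_phenotypes_rerunnable(small_cohort):
    cfg = SimulationConfig(n_cases=200, n_controls=200, seed=42)
    rng = np.random.default_rng(99)
    out = simulate_tumor_phenotypes(small_cohort, cfg, rng=rng)
    assert len(out) == (small_cohort.covariates["status"] == 1).sum()
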