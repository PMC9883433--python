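"""RDV classification tests, including the hand-enumerated 12-variant
fixture covering every rarity gate and deleteriousness branch."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort
from rdvload.classify import (
    build_rdv_matrix,
    classify_rdvs,
    cohort_allele_stats,
    is_deleterious,
    is_rare,
    rdv_long,
    synonymous_background,
)
from rdvload.config import RarityThresholds

TH = RarityThresholds()


def _ann(rows):
    defaults = {
        "chrom": "1", "pos": 100, "ref": "A", "alt": "T", "gene": "G1",
        "strand": "+", "cds_pos": 100.0, "consequence": "missense",
        "clinvar": "absent", "maf_exac_nfe_nontcga": 0.0,
        "maf_gnomad_asj": 0.0, "maf_exac_global": 0.0,
    }
    df = pd.DataFrame([dict(defaults, **r) for r in rows])
    df.index = [f"v{i}" for i in range(len(df))]
    return df


@pytest.mark.parametrize(
    "maf_case,maf_ctrl,exac,asj,expect",
    [
        (0.03, 0.01, 0.0, 0.0, True),    # common in one arm only -> rare
        (0.03, 0.03, 0.0, 0.0, False),   # common in both arms
        (0.02, 0.02, 0.0, 0.0, True),    # boundary: 2% is not ">2%"
        (0.0, 0.0, 0.015, 0.0, False),   # ExAC NFE above 1%
        (0.0, 0.0, 0.0, 0.02, False),    # gnomAD ASJ above 1%
        (0.0, 0.0, 0.01, 0.01, True),    # reference boundary inclusive
        (0.0, 0.0, 0.0, 0.0, True),      # absent everywhere
    ],
)
def test_rarity_cascade(maf_case, maf_ctrl, exac, asj, expect):
    ann = _ann([{"maf_exac_nfe_nontcga": exac, "maf_gnomad_asj": asj}])
    out = is_rare(np.array([maf_case]), np.array([maf_ctrl]), ann, TH)
    assert out[0] == expect


def test_absent_reference_maf_treated_as_zero_by_default():
    ann = _ann([{"maf_exac_nfe_nontcga": np.nan, "maf_gnomad_asj": np.nan}])
    assert is_rare(np.array([0.0]), np.array([0.0]), ann, TH)[0]
    strict = RarityThresholds(absent_ref_maf_is_zero=False)
    assert not is_rare(np.array([0.0]), np.array([0.0]), ann, strict)[0]


ANCHORS = pd.DataFrame(
    {
        "gene": ["G1", "G2"],
        "cds_pos": [900, 600],
        "consequence": ["frameshift", "stopgain"],
        "significance": ["pathogenic", "pathogenic"],
    }
)


@pytest.mark.parametrize(
    "row,expect",
    [
        ({"clinvar": "likely_pathogenic", "consequence": "missense"}, True),
        ({"consequence": "stopgain", "cds_pos": 120.0}, True),        # 5' of anchor 900
        ({"consequence": "stopgain", "cds_pos": 1200.0}, False),      # 3' of all anchors
        ({"gene": "G2", "strand": "-", "consequence": "frameshift", "cds_pos": 50.0}, True),
        ({"consequence": "missense", "cds_pos": 120.0}, False),       # missense not LOF
        ({"gene": "G3", "consequence": "frameshift", "cds_pos": 10.0}, False),  # no anchor
    ],
)
def test_deleteriousness_rules(row, expect):
    ann = _ann([row])
    out, _ = is_deleterious(ann, ANCHORS, TH)
    assert out[0] == expect


def test_lof_without_cds_is_skipped_and_logged():
    ann = _ann([{"consequence": "stopgain", "cds_pos": np.nan}])
    out, log = is_deleterious(ann, ANCHORS, TH)
    assert not out[0]
    assert log


def test_anchor_likely_pathogenic_configurable():
    anchors = pd.DataFrame(
        {"gene": ["G1"], "cds_pos": [900], "consequence": ["stopgain"],
         "significance": ["likely_pathogenic"]}
    )
    ann = _ann([{"consequence": "stopgain", "cds_pos": 100.0}])
    assert is_deleterious(ann, anchors, TH)[0][0]
    strict = RarityThresholds(anchor_include_likely_pathogenic=False)
    assert not is_deleterious(ann, anchors, strict)[0][0]


def _twelve_variant_fixture():
    """Hand enumeration: qualifying set is exactly {v0, v1, v3, v8, v9}."""
    rows = [
        # v0: ClinVar P/LP missense, absent everywhere -> RDV
        {"clinvar": "pathogenic"},
        # v1: stopgain at CDS 120, 5' of G1 anchor at 900 -> RDV
        {"consequence": "stopgain", "cds_pos": 120.0},
        # v2: stopgain at CDS 1200, 3' of the most-3' anchor -> no
        {"consequence": "stopgain", "cds_pos": 1200.0},
        # v3: frameshift on the minus-strand gene G2, CDS 50 < anchor 600 -> RDV
        {"gene": "G2", "strand": "-", "consequence": "frameshift", "cds_pos": 50.0},
        # v4: plain missense, no ClinVar -> no
        {"consequence": "missense"},
        # v5: P/LP but ExAC NFE 1.5% -> fails rarity
        {"clinvar": "pathogenic", "maf_exac_nfe_nontcga": 0.015},
        # v6: P/LP but gnomAD ASJ 2% -> fails rarity
        {"clinvar": "likely_pathogenic", "maf_gnomad_asj": 0.02},
        # v7: P/LP, common in BOTH arms (cohort MAF 3%/3%) -> fails rarity
        {"clinvar": "pathogenic"},
        # v8: P/LP, common in cases only (3%/1%) -> rare, RDV
        {"clinvar": "pathogenic"},
        # v9: ClinVar-benign stopgain 5' of anchor -> deleterious via rule (ii)
        {"clinvar": "benign", "consequence": "stopgain", "cds_pos": 100.0},
        # v10: frameshift in gene without any anchor -> no
        {"gene": "G3", "consequence": "frameshift", "cds_pos": 10.0},
        # v11: ultra-rare synonymous -> not an RDV (background only)
        {"consequence": "synonymous"},
    ]
    ann = _ann(rows)
    maf = pd.DataFrame(0.0, index=ann.index, columns=["maf_case", "maf_control"])
    maf.loc["v7"] = [0.03, 0.03]
    maf.loc["v8"] = [0.03, 0.01]
    return ann, maf


def test_twelve_variant_fixture_matches_hand_enumeration():
    ann, maf = _twelve_variant_fixture()
    out = classify_rdvs(ann, maf, ANCHORS, TH)
    assert set(out.index[out["is_rdv"]]) == {"v0", "v1", "v3", "v8", "v9"}


def test_classification_is_order_invariant():
    ann, maf = _twelve_variant_fixture()
    out = classify_rdvs(ann, maf, ANCHORS, TH)
    perm = ann.sample(frac=1.0, random_state=1).index
    out2 = classify_rdvs(ann.loc[perm], maf.loc[perm], ANCHORS, TH)
    assert out2["is_rdv"].reindex(out.index).equals(out["is_rdv"])


def test_sensitivity_mode_is_subset(small_cohort):
    """1% cohort-MAF mode never yields more RDVs than the 2% mode."""
    g = small_cohort.genotypes
    case_mask = (small_cohort.covariates["status"].reindex(g.samples) == 1).to_numpy()
    maf = cohort_allele_stats(g, case_mask)
    base = classify_rdvs(small_cohort.annotations, maf, small_cohort.clinvar_anchors, TH)
    sens = classify_rdvs(
        small_cohort.annotations, maf, small_cohort.clinvar_anchors,
        RarityThresholds(cohort_maf_max=0.01),
    )
    assert set(sens.index[sens["is_rdv"]]) <= set(base.index[base["is_rdv"]])


def test_rdv_matrix_carrier_conventions():
    ann, maf = _twelve_variant_fixture()
    classified = classify_rdvs(ann, maf, ANCHORS, TH)
    # 3 participants; v0 and v1 are G1 RDVs, v3 is a G2 RDV
    gt = np.zeros((12, 3), dtype=np.int8)
    gt[0, 0] = 1        # S0 het at v0
    gt[1, 0] = 1        # S0 het at v1 too -> G1 count 2
    gt[0, 1] = 2        # S1 hom-alt at v0 -> counted once
    variants = pd.DataFrame(
        {"chrom": "1", "pos": range(12), "ref": "A", "alt": "T", "qual": 100.0,
         "qd": 10.0, "mq": 60.0, "rprs": 0.0, "mqrs": 0.0, "filter": "PASS"},
        index=ann.index,
    )
    cohort = make_cohort(gt, variants=variants)
    matrix = build_rdv_matrix(cohort, classified)
    assert matrix.loc["S0", "G1"] == 2
    assert matrix.loc["S1", "G1"] == 1      # hom-alt counted once (dominant coding)
    assert (matrix.loc["S2"] == 0).all()
    long = rdv_long(matrix)
    assert long.loc[(long.participant == "S0") & (long.gene == "G1"), "carrier"].item()


def test_synonymous_background_counts_genes_not_variants():
    rows = [
        {"consequence": "synonymous", "gene": "G1"},
        {"consequence": "synonymous", "gene": "G1", "pos": 200},
        {"consequence": "synonymous", "gene": "G2", "maf_exac_global": 1e-4},  # too common in ExAC
        {"consequence": "synonymous", "gene": "G4", "chrom": "X"},             # non-autosomal
        {"consequence": "missense", "gene": "G5"},
    ]
    ann = _ann(rows)
    gt = np.zeros((5, 2), dtype=np.int8)
    gt[:, 0] = 1  # S0 carries everything
    variants = pd.DataFrame(
        {"chrom": ann["chrom"], "pos": range(5), "ref": "A", "alt": "T",
         "qual": 100.0, "qd": 10.0, "mq": 60.0, "rprs": 0.0, "mqrs": 0.0,
         "filter": "PASS"},
        index=ann.index,
    )
    cohort = make_cohort(gt, variants=variants)
    # cohort MAF of carried variants is 0.25 here, above the 0.05% gate;
    # pass an explicit ultra-rare cohort MAF to isolate the counting logic
    maf_all = pd.Series(1e-4, index=ann.index)
    out = synonymous_background(cohort, ann, maf_all, TH)
    assert out["S0"] == 1   # two qualifying variants, one gene
    assert out["S1"] == 0
    # the cohort-MAF gate excludes a 0.06% variant
    maf_all.loc["v0"] = 0.0006
    maf_all.loc["v1"] = 0.0006
    out2 = synonymous_background(cohort, ann, maf_all, TH)
    assert out2["S0"] == 0
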