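"""Rare/deleterious variant classification and the per-gene RDV matrix.

A QC-passed variant is an RDV when it is *rare* — at most 2% MAF in at
least one cohort arm and at most 1% in each reference population (ExAC
non-TCGA NFE, gnomAD ASJ) — and *deleterious*: ClinVar
pathogenic/likely-pathogenic, or a frameshift/stopgain lying 5' (in
coding-sequence coordinates, which absorb transcript strand) of a
ClinVar pathogenic loss-of-function record in the same gene.  The
synonymous background covariate counts, per participant, genes carrying
at least one ultra-rare synonymous variant on the autosomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortGenotypes
from .config import RarityThresholds

#: required columns of the variant annotation table
ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "strand", "cds_pos", "consequence",
    "clinvar", "maf_exac_nfe_nontcga", "maf_gnomad_asj", "maf_exac_global",
]

LOF_CONSEQUENCES = frozenset({"stopgain", "frameshift"})
PLP = frozenset({"pathogenic", "likely_pathogenic"})
_AUTOSOME_EXCLUDE = frozenset({"X", "Y", "chrX", "chrY", "MT", "chrM"})


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    bad = ann["cds_pos"].isna() & ann["consequence"].isin(
        {"missense", "synonymous", "stopgain", "frameshift", "inframe"}
    )
    return ann.assign(_cds_defined=~bad)


def cohort_allele_stats(cohort: CohortGenotypes, case_mask: np.ndarray) -> pd.DataFrame:
    """Per-variant minor allele frequency in cases, controls and overall,
    computed from QC-passed genotypes."""
    case_mask = np.asarray(case_mask, dtype=bool)
    return pd.DataFrame(
        {
            "maf_case": cohort.minor_allele_frequency(case_mask),
            "maf_control": cohort.minor_allele_frequency(~case_mask),
            "maf_all": cohort.minor_allele_frequency(),
        },
        index=cohort.variants.index,
    )


def is_rare(
    maf_case: np.ndarray,
    maf_control: np.ndarray,
    ann: pd.DataFrame,
    th: RarityThresholds = RarityThresholds(),
) -> np.ndarray:
    """Rarity cascade: not common (> cohort_maf_max) in *both* arms, and
    each reference-population MAF <= ref_maf_max.  Absent (NaN) reference
    frequencies count as 0 by default."""
    fill = 0.0 if th.absent_ref_maf_is_zero else np.inf
    exac = ann["maf_exac_nfe_nontcga"].to_numpy(dtype=float)
    asj = ann["maf_gnomad_asj"].to_numpy(dtype=float)
    exac = np.where(np.isfinite(exac), exac, fill)
    asj = np.where(np.isfinite(asj), asj, fill)
    common_both = (np.nan_to_num(maf_case) > th.cohort_maf_max) & (
        np.nan_to_num(maf_control) > th.cohort_maf_max
    )
    return (~common_both) & (exac <= th.ref_maf_max) & (asj <= th.ref_maf_max)


def is_deleterious(
    ann: pd.DataFrame,
    clinvar_lof_anchors: pd.DataFrame,
    th: RarityThresholds = RarityThresholds(),
) -> tuple[np.ndarray, list[str]]:
    """ClinVar P/LP, or frameshift/stopgain 5' of a ClinVar pathogenic
    LOF record in the same gene.

    ``clinvar_lof_anchors`` needs columns gene, cds_pos, consequence,
    significance.  For genes with several anchors the most 3' (largest
    CDS coordinate) defines the boundary; a coding LOF variant without a
    CDS coordinate is skipped for the 5' rule and logged.
    """
    log: list[str] = []
    plp = ann["clinvar"].isin(PLP).to_numpy()

    sig = {"pathogenic"}
    if th.anchor_include_likely_pathogenic:
        sig.add("likely_pathogenic")
    anchors = clinvar_lof_anchors[
        clinvar_lof_anchors["consequence"].isin(LOF_CONSEQUENCES)
        & clinvar_lof_anchors["significance"].isin(sig)
    ]
    boundary = anchors.groupby("gene")["cds_pos"].max()

    cds = ann["cds_pos"].to_numpy(dtype=float)
    lof = ann["consequence"].isin(LOF_CONSEQUENCES).to_numpy()
    gene_boundary = ann["gene"].map(boundary).to_numpy(dtype=float)
    no_cds = lof & ~np.isfinite(cds)
    for vid in ann.index[no_cds & np.isfinite(gene_boundary)]:
        log.append(f"{vid}: coding LOF without CDS coordinate; 5' rule skipped")
    five_prime = lof & np.isfinite(cds) & np.isfinite(gene_boundary) & (cds < gene_boundary)
    return plp | five_prime, log


def classify_rdvs(
    ann: pd.DataFrame,
    maf: pd.DataFrame,
    clinvar_lof_anchors: pd.DataFrame,
    th: RarityThresholds = RarityThresholds(),
) -> pd.DataFrame:
    """Annotate each variant with rare / deleterious / is_rdv flags.

    ``maf`` must carry maf_case and maf_control aligned to ``ann``'s index.
    Classification is pure: row order does not matter.
    """
    ann = validate_annotations(ann)
    maf = maf.reindex(ann.index)
    rare = is_rare(
        maf["maf_case"].to_numpy(), maf["maf_control"].to_numpy(), ann, th
    )
    delet, _ = is_deleterious(ann, clinvar_lof_anchors, th)
    out = ann.copy()
    out["rare"] = rare
    out["deleterious"] = delet
    out["is_rdv"] = rare & delet
    return out


def build_rdv_matrix(cohort: CohortGenotypes, classified: pd.DataFrame) -> pd.DataFrame:
    """Participants x genes matrix of qualifying-RDV site counts.

    A participant contributes 1 per RDV site at which they carry >= 1
    alternate allele (dominant carrier coding: het and hom-alt both count
    once).  Genes with no RDVs are absent from the columns.
    """
    rdv = classified[classified["is_rdv"]]
    common = cohort.variants.index.intersection(rdv.index)
    if common.empty:
        return pd.DataFrame(index=pd.Index(cohort.samples, name="participant"), dtype=int)
    pos = cohort.variants.index.get_indexer(common)
    carrier = (cohort.gt[pos] > 0).astype(np.int64)  # (n_rdv, n_samp)
    genes = rdv.loc[common, "gene"]
    counts = (
        pd.DataFrame(carrier, index=genes.to_numpy(), columns=cohort.samples)
        .groupby(level=0)
        .sum()
        .T
    )
    counts.index.name = "participant"
    return counts


def rdv_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-form RdvAssignment view: participant, gene, n_rdv_variants, carrier."""
    long = matrix.stack().rename("n_rdv_variants").reset_index()
    long.columns = ["participant", "gene", "n_rdv_variants"]
    long["carrier"] = long["n_rdv_variants"] > 0
    return long


def synonymous_background(
    cohort: CohortGenotypes,
    ann: pd.DataFrame,
    maf_all: pd.Series,
    th: RarityThresholds = RarityThresholds(),
) -> pd.Series:
    """Per-participant count of distinct autosomal genes with >= 1 carried
    ultra-rare synonymous variant (ExAC global <= syn_ref_maf_max, cohort
    MAF <= syn_cohort_maf_max)."""
    fill = 0.0 if th.absent_ref_maf_is_zero else np.inf
    exac = ann["maf_exac_global"].to_numpy(dtype=float)
    exac = np.where(np.isfinite(exac), exac, fill)
    autosomal = ~ann["chrom"].astype(str).isin(_AUTOSOME_EXCLUDE)
    qual = (
        (ann["consequence"] == "synonymous").to_numpy()
        & autosomal.to_numpy()
        & (exac <= th.syn_ref_maf_max)
        & (maf_all.reindex(ann.index).to_numpy(dtype=float) <= th.syn_cohort_maf_max)
    )
    sites = ann.index[qual]
    common = cohort.variants.index.intersection(sites)
    if common.empty:
        return pd.Series(0, index=pd.Index(cohort.samples, name="participant"), name="n_syn_genes")
    pos = cohort.variants.index.get_indexer(common)
    carrier = cohort.gt[pos] > 0
    genes = ann.loc[common, "gene"].to_numpy()
    per_gene = (
        pd.DataFrame(carrier.astype(np.int64), index=genes, columns=cohort.samples)
        .groupby(level=0)
        .max()
    )
    out = per_gene.sum(axis=0).astype(int)
    out.index.name = "participant"
    out.name = "n_syn_genes"
    return out
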