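"""Seeded synthetic case-control cohorts with planted RDV structure.

The generator emulates the statistical structure the downstream analysis
assumes: a rare-variant frequency spectrum inside gene bodies (ClinVar
P/LP records, frameshift/stopgain variants 5' and 3' of pathogenic LOF
anchors, benign/VUS background), ultra-rare synonymous variation, a
common-SNP panel with ancestry-stratified allele frequencies for PCA and
kinship, planted duplicate/1st/2nd-degree pairs, and per-gene-set
carrier effects on case status.

Planted effects are retrospective: within each planted gene-set the
case-arm allele frequencies at qualifying variants are scaled so that
the population carrier odds ratio equals ``exp(planted_logor)`` exactly;
the empirical carrier OR therefore converges to the planted value.
Planted sets must be gene-disjoint for the per-set odds to be exact.

All randomness flows from a single integer seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import SITE_COLUMNS, CohortGenotypes, write_vcf
from .classify import ANNOTATION_COLUMNS

IMMUNE_CELL_TYPES = [
    "B_cells_naive", "B_cells_memory", "Plasma_cells", "T_cells_CD8",
    "T_cells_CD4_naive", "T_cells_CD4_memory_resting",
    "T_cells_CD4_memory_activated", "T_cells_follicular_helper",
    "T_cells_regulatory", "T_cells_gamma_delta", "NK_cells_resting",
    "NK_cells_activated", "Monocytes", "Macrophages_M0", "Macrophages_M1",
    "Macrophages_M2", "Dendritic_cells_resting", "Dendritic_cells_activated",
    "Mast_cells_resting", "Mast_cells_activated", "Eosinophils", "Neutrophils",
]

CANCER_TYPES = ["BRCA", "LUAD", "LUSC", "COAD", "STAD", "KIRC", "KIRP",
                "OV", "LGG", "HNSC", "LAML"]
_CANCER_WEIGHTS = np.array([0.18, 0.12, 0.1, 0.1, 0.08, 0.09, 0.06,
                            0.08, 0.08, 0.09, 0.02])

HEMATOLOGICAL_TYPES = {"LAML"}


@dataclass(frozen=True)
class GeneSpec:
    name: str
    chrom: str
    strand: str
    cds_length: int


@dataclass(frozen=True)
class RelatednessSpec:
    n_duplicate: int = 2
    n_first_degree: int = 2
    n_second_degree: int = 2

    @property
    def total(self) -> int:
        return self.n_duplicate + self.n_first_degree + self.n_second_degree


@dataclass(frozen=True)
class AncestrySpec:
    labels: tuple[str, ...] = ("POP1", "POP2")
    weights: tuple[float, ...] = (0.8, 0.2)
    #: SD of the per-stratum allele-frequency offset on common SNPs
    offset_sd: float = 0.08
    n_reference_per_stratum: int = 80


@dataclass(frozen=True)
class PhenotypeEffects:
    """Per-load-group phenotype shifts (groups zero / one / multi)."""

    onset_shift_years: tuple[float, float, float] = (0.0, -3.0, -6.0)
    tmb_multiplier: tuple[float, float, float] = (1.0, 1.5, 2.0)
    m1_alpha_multiplier: tuple[float, float, float] = (1.0, 1.5, 2.0)
    survival_loghr_per_m1: float = 3.0
    onset_floor_years: float = 18.0


def default_genes() -> list[GeneSpec]:
    sets = {"CPD": 12, "DDR": 10, "SCD": 15, "FA": 6, "NUL": 17}
    genes = []
    i = 0
    for prefix, n in sets.items():
        for k in range(n):
            genes.append(GeneSpec(
                name=f"{prefix}{k+1:02d}",
                chrom=str((i % 22) + 1),
                strand="+" if i % 2 == 0 else "-",
                cds_length=1500 + 150 * (i % 20),
            ))
            i += 1
    return genes


def default_gene_sets() -> dict[str, list[str]]:
    genes = default_genes()
    out: dict[str, list[str]] = {}
    for prefix in ("CPD", "DDR", "SCD", "FA"):
        out[prefix] = [g.name for g in genes if g.name.startswith(prefix)]
    return out


def default_planted_logor() -> dict[str, float]:
    return {
        "CPD": float(np.log(1.5)),
        "DDR": float(np.log(1.5)),
        "SCD": float(np.log(1.4)),
        "FA": float(np.log(2.0)),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 2000
    n_controls: int = 2000
    genes: tuple[GeneSpec, ...] = tuple(default_genes())
    gene_sets: dict[str, list[str]] = field(default_factory=default_gene_sets)
    planted_logor: dict[str, float] = field(default_factory=default_planted_logor)
    #: rare deleterious-candidate population frequency range (log-uniform)
    maf_range: tuple[float, float] = (1e-4, 5e-3)
    n_deleterious_per_gene: int = 3
    clinvar_fraction: float = 0.7
    #: mean rare-synonymous genes per participant (sets the synonymous site count)
    synonymous_rate: float = 0.5
    syn_maf_range: tuple[float, float] = (5e-5, 4e-4)
    n_common_snps: int = 3000
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    ancestry: AncestrySpec = AncestrySpec()
    related: RelatednessSpec = RelatednessSpec()
    phenotype_effects: PhenotypeEffects = PhenotypeEffects()
    #: gene-set whose truth load group drives the phenotype shifts
    phenotype_gene_set: str = "CPD"
    #: fraction of deleterious candidates made reference-common (fail rarity)
    rarity_fail_fraction: float = 0.05
    #: per-call probability of an injected quality failure
    genotype_fail_rate: float = 0.01
    n_bad_sites: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        declared = {g.name for g in self.genes}
        for name, members in self.gene_sets.items():
            unknown = set(members) - declared
            if unknown:
                raise ValueError(f"gene-set {name!r} references undeclared genes {sorted(unknown)}")
        unknown_sets = set(self.planted_logor) - set(self.gene_sets)
        if unknown_sets:
            raise ValueError(f"planted_logor for unknown gene-sets: {sorted(unknown_sets)}")
        seen: dict[str, str] = {}
        for name, lo in self.planted_logor.items():
            if lo == 0.0:
                continue
            for g in self.gene_sets[name]:
                if g in seen:
                    raise ValueError(
                        f"planted gene-sets must be gene-disjoint: {g} in {seen[g]} and {name}"
                    )
                seen[g] = name
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0.0 <= self.clinvar_fraction <= 1.0):
            raise ValueError("clinvar_fraction must lie in [0, 1]")
        if abs(sum(self.ancestry.weights) - 1.0) > 1e-9:
            raise ValueError("ancestry weights must sum to 1")
        if self.phenotype_gene_set not in self.gene_sets:
            raise ValueError(f"unknown phenotype gene-set {self.phenotype_gene_set!r}")


@dataclass
class SyntheticCohort:
    genotypes: CohortGenotypes
    annotations: pd.DataFrame
    clinvar_anchors: pd.DataFrame
    covariates: pd.DataFrame          # participant-indexed: status, gender, age, stratum, cancer_type
    tumor: pd.DataFrame               # case-indexed phenotype table
    reference: CohortGenotypes        # labeled reference panel on the common SNPs
    reference_labels: pd.Series
    gene_sets: dict[str, list[str]]
    truth: dict


def _loguniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _carrier_freq(q: np.ndarray) -> float:
    """Population carrier probability of >= 1 alt allele across variants (HWE)."""
    return 1.0 - float(np.prod((1.0 - q) ** 2))


def _case_scale(q: np.ndarray, logor: float) -> float:
    """Scale s on case-arm frequencies so carrier odds shift by exp(logor)."""
    f0 = _carrier_freq(q)
    if f0 <= 0.0 or f0 >= 1.0:
        raise ValueError("degenerate baseline carrier frequency")
    odds1 = f0 / (1.0 - f0) * np.exp(logor)
    f1 = odds1 / (1.0 + odds1)
    s_max = 0.999 / float(q.max())

    def g(s):
        return _carrier_freq(np.minimum(s * q, 0.999)) - f1

    if g(s_max) < 0:
        raise ValueError("planted log-odds unreachable for this variant set")
    return float(brentq(g, 0.0, s_max, xtol=1e-12))


def _build_variant_tables(cfg: SimulationConfig, rng):
    """Variant annotation rows, ClinVar anchors, and per-variant metadata."""
    ann_rows, anchor_rows = [], []
    meta = []  # dicts: q, kind, gene, qualifies
    pos_counter: dict[str, int] = {}

    def next_pos(chrom, step):
        pos_counter[chrom] = pos_counter.get(chrom, 10_000) + step
        return pos_counter[chrom]

    n_genes = len(cfg.genes)
    n_syn_total = 0
    if cfg.synonymous_rate > 0 and n_genes > 0:
        mean_q = (cfg.syn_maf_range[1] - cfg.syn_maf_range[0]) / np.log(
            cfg.syn_maf_range[1] / cfg.syn_maf_range[0]
        )
        n_syn_total = int(np.ceil(cfg.synonymous_rate / (2.0 * mean_q)))
    syn_per_gene = np.diff(np.linspace(0, n_syn_total, n_genes + 1).astype(int)) if n_genes else []

    bases = np.array(["A", "C", "G", "T"])
    for gi, gene in enumerate(cfg.genes):
        anchor_cds = int(0.6 * gene.cds_length)
        anchor_rows.append({
            "gene": gene.name, "cds_pos": anchor_cds,
            "consequence": "stopgain" if gi % 2 == 0 else "frameshift",
            "significance": "pathogenic",
        })

        def add(kind, consequence, clinvar, cds, q, qualifies,
                exac_nfe=0.0, asj=0.0, exac_global=0.0):
            pos = next_pos(gene.chrom, int(rng.integers(50, 500)))
            ref, alt = rng.choice(bases, size=2, replace=False)
            ann_rows.append({
                "chrom": gene.chrom, "pos": pos, "ref": ref, "alt": alt,
                "gene": gene.name, "strand": gene.strand, "cds_pos": cds,
                "consequence": consequence, "clinvar": clinvar,
                "maf_exac_nfe_nontcga": exac_nfe, "maf_gnomad_asj": asj,
                "maf_exac_global": exac_global,
            })
            meta.append({"q": q, "kind": kind, "gene": gene.name, "qualifies": qualifies})

        for _ in range(cfg.n_deleterious_per_gene):
            q = float(_loguniform(rng, *cfg.maf_range, size=1)[0])
            ref_common = rng.random() < cfg.rarity_fail_fraction
            exac_nfe = float(rng.uniform(0.012, 0.03)) if ref_common else float(rng.uniform(0, 0.002))
            if rng.random() < cfg.clinvar_fraction:
                clinvar = "pathogenic" if rng.random() < 0.5 else "likely_pathogenic"
                consequence = str(rng.choice(["missense", "stopgain", "frameshift"]))
                cds = int(rng.integers(1, gene.cds_length + 1))
            else:
                clinvar = "absent"
                consequence = str(rng.choice(["stopgain", "frameshift"]))
                cds = int(rng.integers(1, anchor_cds))  # strictly 5' of the anchor
            add("deleterious", consequence, clinvar, cds, q,
                qualifies=not ref_common, exac_nfe=exac_nfe)
        # a 3'-of-anchor LOF that must NOT qualify
        add("lof_3prime", "stopgain", "absent",
            int(rng.integers(anchor_cds + 1, gene.cds_length + 1)),
            float(_loguniform(rng, *cfg.maf_range, size=1)[0]), qualifies=False)
        add("benign", "missense", "benign",
            int(rng.integers(1, gene.cds_length + 1)),
            float(_loguniform(rng, *cfg.maf_range, size=1)[0]), qualifies=False)
        add("vus", "missense", "VUS",
            int(rng.integers(1, gene.cds_length + 1)),
            float(_loguniform(rng, *cfg.maf_range, size=1)[0]), qualifies=False)
        for _ in range(int(syn_per_gene[gi]) if len(syn_per_gene) else 0):
            add("synonymous", "synonymous", "absent",
                int(rng.integers(1, gene.cds_length + 1)),
                float(_loguniform(rng, *cfg.syn_maf_range, size=1)[0]),
                qualifies=False,
                exac_global=float(rng.uniform(0, 4e-5)))

    for k in range(cfg.n_common_snps):
        chrom = str((k % 22) + 1)
        pos = next_pos(chrom, int(rng.integers(500, 5000)))
        ref, alt = rng.choice(bases, size=2, replace=False)
        q = float(rng.uniform(*cfg.common_maf_range))
        ann_rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": "intergenic", "strand": "+", "cds_pos": np.nan,
            "consequence": "other", "clinvar": "absent",
            "maf_exac_nfe_nontcga": q, "maf_gnomad_asj": q, "maf_exac_global": q,
        })
        meta.append({"q": q, "kind": "common", "gene": "intergenic", "qualifies": False})

    ann = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    ann.index = (
        ann["chrom"].astype(str) + ":" + ann["pos"].astype(str)
        + ":" + ann["ref"] + ":" + ann["alt"]
    )
    if ann.index.duplicated().any():
        raise RuntimeError("variant id collision in simulation")
    anchors = pd.DataFrame(anchor_rows)
    meta = pd.DataFrame(meta, index=ann.index)
    return ann, anchors, meta


def _site_stats(cfg: SimulationConfig, rng, ann: pd.DataFrame,
                meta: pd.DataFrame) -> pd.DataFrame:
    n = len(ann)
    site = pd.DataFrame(index=ann.index)
    site["chrom"] = ann["chrom"]
    site["pos"] = ann["pos"]
    site["ref"] = ann["ref"]
    site["alt"] = ann["alt"]
    site["qual"] = rng.uniform(100, 2000, n)
    site["qd"] = rng.uniform(5, 30, n)
    site["mq"] = rng.normal(60, 1.0, n)
    site["rprs"] = np.where(rng.random(n) < 0.1, np.nan, rng.normal(0, 0.8, n))
    site["mqrs"] = np.where(rng.random(n) < 0.1, np.nan, rng.normal(0, 0.8, n))
    site["filter"] = "PASS"

    eligible = np.flatnonzero(~meta["qualifies"].to_numpy())
    n_bad = min(cfg.n_bad_sites, len(eligible))
    bad = rng.choice(eligible, size=n_bad, replace=False)
    fail_modes = [
        ("qual", 30.0), ("qd", 1.0), ("mq", 30.0), ("rprs", -5.0), ("mqrs", -15.0),
        ("filter", "VQSRTrancheSNP99.00to99.90"),
    ]
    for k, idx in enumerate(bad):
        col, val = fail_modes[k % len(fail_modes)]
        site.iloc[idx, site.columns.get_loc(col)] = val
    return site[SITE_COLUMNS]


def _draw_quality(rng, gt: np.ndarray, fail_rate: float):
    n_var, n_samp = gt.shape
    dp = (rng.poisson(60, size=gt.shape) + 1).astype(np.int16)
    p_alt = np.select([gt == 1, gt == 2], [0.5, 0.98], default=0.01)
    ad = rng.binomial(dp, p_alt).astype(np.int16)
    gq = np.clip(rng.normal(75, 12, size=gt.shape), 0, 99).astype(np.int16)
    if fail_rate > 0:
        r = rng.random(gt.shape)
        m = r < fail_rate / 3
        gq[m] = rng.integers(0, 20, size=int(m.sum()))
        m = (r >= fail_rate / 3) & (r < 2 * fail_rate / 3)
        dp[m] = rng.integers(1, 10, size=int(m.sum()))
        m = (r >= 2 * fail_rate / 3) & (r < fail_rate) & (gt == 1)
        ad[m] = np.maximum((0.12 * dp[m]).astype(np.int16), 0)
    return gq, dp, ad


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under the configured conditions."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    ann, anchors, meta = _build_variant_tables(cfg, rng)
    n_var = len(ann)
    q = meta["q"].to_numpy()

    # variant-level qualifying truth (rare + deleterious by construction)
    true_rdv = meta["qualifies"].to_numpy() & (meta["kind"] == "deleterious").to_numpy()

    # per-stratum frequencies on the common panel
    n_strata = len(cfg.ancestry.labels)
    freq_by_stratum = np.tile(q[:, None], (1, n_strata))
    common_mask = (meta["kind"] == "common").to_numpy()
    for s in range(1, n_strata):
        off = rng.normal(0, cfg.ancestry.offset_sd, size=int(common_mask.sum()))
        freq_by_stratum[common_mask, s] = np.clip(q[common_mask] + off, 0.01, 0.99)

    # case-arm inflation per planted set
    case_freq = q.copy()
    skipped_sets = []
    for name, logor in cfg.planted_logor.items():
        members = set(cfg.gene_sets[name])
        vmask = true_rdv & meta["gene"].isin(members).to_numpy()
        if vmask.sum() == 0:
            warnings.warn(f"gene-set {name!r} has no qualifying variants; planted effect skipped")
            skipped_sets.append(name)
            continue
        if logor != 0.0:
            s = _case_scale(q[vmask], logor)
            case_freq[vmask] = np.minimum(s * q[vmask], 0.999)

    # participants
    case_ids = [f"CASE{i+1:05d}" for i in range(cfg.n_cases)]
    ctrl_ids = [f"CTRL{i+1:05d}" for i in range(cfg.n_controls)]
    samples = case_ids + ctrl_ids
    status = np.array([1] * cfg.n_cases + [0] * cfg.n_controls)
    stratum = rng.choice(n_strata, size=len(samples), p=np.array(cfg.ancestry.weights))

    gt = np.empty((n_var, len(samples)), dtype=np.int8)
    for s in range(n_strata):
        for arm in (1, 0):
            cols = np.flatnonzero((stratum == s) & (status == arm))
            if cols.size == 0:
                continue
            f = freq_by_stratum[:, s].copy()
            rare = ~common_mask
            f[rare] = case_freq[rare] if arm == 1 else q[rare]
            gt[:, cols] = rng.binomial(2, f[:, None], size=(n_var, cols.size)).astype(np.int8)

    # planted relatives among controls (overwrite trailing controls)
    related_rows = []
    rel = cfg.related
    needed = 2 * rel.total
    if needed > 0:
        if needed > cfg.n_controls:
            raise ValueError("not enough controls to plant the requested related pairs")
        pool = [len(case_ids) + i for i in range(cfg.n_controls)]
        take = pool[-needed:]
        k = 0
        for degree, count in (("duplicate", rel.n_duplicate),
                              ("first", rel.n_first_degree),
                              ("second", rel.n_second_degree)):
            for _ in range(count):
                a, b = take[k], take[k + 1]
                k += 2
                f = freq_by_stratum[:, stratum[a]].copy()
                f[~common_mask] = q[~common_mask]
                stratum[b] = stratum[a]
                if degree == "duplicate":
                    gt[:, b] = gt[:, a]
                elif degree == "first":
                    shared = rng.binomial(1, gt[:, a] / 2.0)
                    gt[:, b] = (shared + rng.binomial(1, f)).astype(np.int8)
                else:
                    grand = rng.binomial(1, gt[:, a] / 2.0)
                    passed = np.where(rng.random(n_var) < 0.5, grand, rng.binomial(1, f))
                    gt[:, b] = (passed + rng.binomial(1, f)).astype(np.int8)
                related_rows.append({
                    "id1": samples[a], "id2": samples[b], "degree": degree,
                    "expected_phi": {"duplicate": 0.5, "first": 0.25, "second": 0.125}[degree],
                })

    gq, dp, ad = _draw_quality(rng, gt, cfg.genotype_fail_rate)
    site = _site_stats(cfg, rng, ann, meta)
    genotypes = CohortGenotypes(samples=samples, variants=site, gt=gt,
                                gq=gq, dp=dp, ad_alt=ad)

    # reference panel on the common SNPs
    n_ref = cfg.ancestry.n_reference_per_stratum
    ref_ids, ref_labels, ref_cols = [], [], []
    for s, label in enumerate(cfg.ancestry.labels):
        f = freq_by_stratum[common_mask, s]
        block = rng.binomial(2, f[:, None], size=(int(common_mask.sum()), n_ref)).astype(np.int8)
        ref_cols.append(block)
        ref_ids += [f"REF_{label}_{i+1:03d}" for i in range(n_ref)]
        ref_labels += [label] * n_ref
    ref_gt = np.hstack(ref_cols) if ref_cols else np.empty((0, 0), np.int8)
    ref_site = site.loc[common_mask].copy()
    ref_shape = ref_gt.shape
    reference = CohortGenotypes(
        samples=ref_ids, variants=ref_site, gt=ref_gt,
        gq=np.full(ref_shape, 99, np.int16), dp=np.full(ref_shape, 60, np.int16),
        ad_alt=np.where(ref_gt == 1, 30, np.where(ref_gt == 2, 59, 0)).astype(np.int16),
    )

    # participant-level truth per gene-set
    truth_part = pd.DataFrame(index=pd.Index(samples, name="participant"))
    truth_part["status"] = status
    truth_part["stratum"] = [cfg.ancestry.labels[s] for s in stratum]
    carrier_gt = gt > 0
    for name, members in cfg.gene_sets.items():
        vmask = true_rdv & meta["gene"].isin(set(members)).to_numpy()
        if vmask.sum() == 0:
            truth_part[f"n_rdv_genes_{name}"] = 0
        else:
            genes_arr = meta.loc[vmask, "gene"].to_numpy()
            sub = carrier_gt[vmask]
            per_gene = (
                pd.DataFrame(sub.astype(int), index=genes_arr, columns=samples)
                .groupby(level=0).max()
            )
            truth_part[f"n_rdv_genes_{name}"] = per_gene.sum(axis=0).to_numpy()
        n = truth_part[f"n_rdv_genes_{name}"]
        truth_part[f"carrier_{name}"] = n > 0
        truth_part[f"load_{name}"] = np.select([n == 0, n == 1], ["zero", "one"], "multi")

    # covariates
    gender = rng.choice(["M", "F"], size=len(samples), p=[0.5, 0.5]).astype(object)
    gender[rng.random(len(samples)) < 0.004] = ""
    cancer_type = np.array([""] * len(samples), dtype=object)
    cancer_type[status == 1] = rng.choice(
        CANCER_TYPES, size=int(status.sum()), p=_CANCER_WEIGHTS / _CANCER_WEIGHTS.sum()
    )
    covariates = pd.DataFrame(
        {
            "status": status,
            "gender": gender,
            "stratum": truth_part["stratum"].to_numpy(),
            "cancer_type": cancer_type,
            "age": np.round(np.clip(rng.normal(58, 12, len(samples)), 20, 90), 1),
        },
        index=truth_part.index,
    )

    truth = {
        "participants": truth_part,
        "variants": pd.DataFrame({"true_rdv": true_rdv, "kind": meta["kind"],
                                  "gene": meta["gene"], "pop_maf": q}, index=ann.index),
        "related_pairs": pd.DataFrame(related_rows),
        "planted_logor": {k: v for k, v in cfg.planted_logor.items() if k not in skipped_sets},
        "seed": cfg.seed,
    }

    cohort = SyntheticCohort(
        genotypes=genotypes, annotations=ann, clinvar_anchors=anchors,
        covariates=covariates, tumor=pd.DataFrame(), reference=reference,
        reference_labels=pd.Series(ref_labels, index=ref_ids, name="label"),
        gene_sets=dict(cfg.gene_sets), truth=truth,
    )
    # tumor phenotypes use a child generator so cohort simulation stays
    # reproducible if phenotype simulation is re-run
    pheno_rng = np.random.default_rng(rng.integers(2**31))
    cohort.tumor = simulate_tumor_phenotypes(cohort, cfg, rng=pheno_rng)
    # age at diagnosis in the covariate table mirrors the tumor table for cases
    covariates.loc[cohort.tumor.index, "age"] = cohort.tumor["age_at_diagnosis"]
    return cohort


_BASE_SOMATIC = {"missense": 100.0, "nonsense": 10.0, "frameshift": 8.0,
                 "inframe": 4.0, "synonymous": 40.0}


def simulate_tumor_phenotypes(
    cohort: SyntheticCohort, config: SimulationConfig, rng=None
) -> pd.DataFrame:
    """Tumor phenotype table for the cases, shifted by truth RDV load.

    Onset ages shift down by the configured years per load group (clipped
    at the floor, clip count logged in the table attrs); somatic counts
    are Poisson with a per-group multiplier; 22 relative immune fractions
    are Dirichlet with the M1 concentration scaled per group and sum to
    1; survival is exponential with a log-hazard proportional to the
    absolute M1 fraction, with uniform censoring.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    eff = config.phenotype_effects
    tp = cohort.truth["participants"]
    cases = tp.index[tp["status"] == 1]
    if len(cases) == 0:
        return pd.DataFrame()
    load = tp.loc[cases, f"load_{config.phenotype_gene_set}"]
    gidx = load.map({"zero": 0, "one": 1, "multi": 2}).to_numpy()

    onset = rng.normal(62, 11, len(cases)) + np.array(eff.onset_shift_years)[gidx]
    n_clipped = int((onset < eff.onset_floor_years).sum())
    onset = np.clip(onset, eff.onset_floor_years, None)

    mult = np.array(eff.tmb_multiplier)[gidx]
    counts = {
        f"n_{cons}": rng.poisson(base * (mult if cons != "synonymous" else 1.0))
        for cons, base in _BASE_SOMATIC.items()
    }

    alpha = np.ones((len(cases), len(IMMUNE_CELL_TYPES)))
    m1 = IMMUNE_CELL_TYPES.index("Macrophages_M1")
    alpha[:, m1] = np.array(eff.m1_alpha_multiplier)[gidx]
    # per-row-alpha Dirichlet via the gamma construction
    gammas = rng.gamma(shape=alpha, scale=1.0)
    fractions = gammas / gammas.sum(axis=1, keepdims=True)
    leukocyte = rng.beta(2, 3, size=len(cases))
    abs_m1 = fractions[:, m1] * leukocyte

    loghaz = eff.survival_loghr_per_m1 * (abs_m1 - abs_m1.mean())
    t = rng.exponential(scale=48.0 * np.exp(-loghaz))
    c = rng.uniform(1.0, 72.0, len(cases))
    time = np.minimum(t, c)
    event = (t <= c).astype(int)

    out = pd.DataFrame(index=pd.Index(cases, name="participant"))
    out["cancer_type"] = cohort.covariates.loc[cases, "cancer_type"]
    out["age_at_diagnosis"] = np.round(onset, 1)
    for k, v in counts.items():
        out[k] = v
    for j, name in enumerate(IMMUNE_CELL_TYPES):
        out[f"frac_{name}"] = fractions[:, j]
    out["leukocyte_fraction"] = leukocyte
    out["survival_time"] = np.round(np.maximum(time, 1e-3), 4)
    out["survival_event"] = event
    out.attrs["n_onset_clipped"] = n_clipped
    return out


def simulate_burden_replicates(
    n_cases: int,
    n_controls: int,
    carrier_freq,
    logor: float,
    n_units: int,
    rng,
    syn_rate: float = 0.5,
):
    """Reduced generator: carrier indicators and covariates drawn directly
    from the retrospective carrier model (control carrier probability f,
    case carrier odds f/(1-f) * exp(logor)) without per-variant genotypes.

    ``carrier_freq`` may be a scalar or an array of per-unit control
    carrier probabilities.  Returns (y, carriers[n x n_units], covariates).
    """
    n = n_cases + n_controls
    y = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    f0 = np.broadcast_to(np.asarray(carrier_freq, dtype=float), (n_units,))
    odds1 = f0 / (1.0 - f0) * np.exp(logor)
    f1 = odds1 / (1.0 + odds1)
    p = np.where(y[:, None] == 1, f1[None, :], f0[None, :])
    carriers = (rng.random((n, n_units)) < p).astype(np.int8)
    covariates = pd.DataFrame({
        "n_syn_genes": rng.poisson(syn_rate, n),
        "PC1": rng.normal(0, 1, n),
        "PC2": rng.normal(0, 1, n),
    })
    return y, carriers, covariates


# ---------------------------------------------------------------------------
# on-disk mirror

def write_gene_sets_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = parts[2:]
    return out


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the full synthetic-cohort bundle as plain-text artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "reference_vcf": outdir / "reference.vcf",
        "annotations": outdir / "annotations.tsv",
        "clinvar_anchors": outdir / "clinvar_anchors.tsv",
        "covariates": outdir / "covariates.tsv",
        "tumor": outdir / "tumor.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    write_vcf(cohort.reference, paths["reference_vcf"])
    cohort.annotations.to_csv(paths["annotations"], sep="\t", index_label="variant_id")
    cohort.clinvar_anchors.to_csv(paths["clinvar_anchors"], sep="\t", index=False)
    cohort.covariates.to_csv(paths["covariates"], sep="\t", index_label="participant")
    cohort.tumor.to_csv(paths["tumor"], sep="\t", index_label="participant")
    write_gene_sets_gmt(cohort.gene_sets, paths["gene_sets"])
    truth = {
        "participants": cohort.truth["participants"].reset_index().to_dict(orient="list"),
        "variants": cohort.truth["variants"].reset_index().to_dict(orient="list"),
        "related_pairs": cohort.truth["related_pairs"].to_dict(orient="list"),
        "planted_logor": cohort.truth["planted_logor"],
        "reference_labels": cohort.reference_labels.to_dict(),
        "seed": cohort.truth["seed"],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh)
    return {k: str(v) for k, v in paths.items()}
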