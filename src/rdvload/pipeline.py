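"""End-to-end orchestration of the RDV burden / load analysis.

Fixed stage order: sample-missingness -> genotype QC -> site QC ->
kinship pruning -> PCA gating -> RDV classification -> synonymous
background -> burden tests (targeted sets, gene scan, optional catalog
scan) -> load groups -> phenotype associations.  Every stage logs its
input/output record counts into a run manifest; any stage failure aborts
with the stage name.  Intermediate artifacts are plain tab-separated
tables so any stage can be inspected or rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import burden_test_geneset, scan_units
from .classify import (
    build_rdv_matrix,
    classify_rdvs,
    cohort_allele_stats,
    synonymous_background,
)
from .cohort import CohortGenotypes, read_vcf
from .cohort_qc import (
    build_common_panel,
    compute_ancestry_pcs,
    gate_ancestry,
    kinship_table,
    prune_relatives,
    resolve_gate,
)
from .config import AnalysisConfig
from .load_phenotype import (
    absolute_immune_fraction,
    assign_load_groups,
    compute_tmb,
    cox_survival,
    load_dose_association,
    load_phenotype_report,
)
from .simulate import HEMATOLOGICAL_TYPES, IMMUNE_CELL_TYPES, read_gmt

logger = logging.getLogger("rdvload")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    vcf: str
    annotations: str
    clinvar_anchors: str
    covariates: str
    gene_sets: str
    outdir: str
    tumor: str | None = None
    reference_vcf: str | None = None
    reference_labels: str | None = None
    catalog: str | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    targeted_sets: list[str] | None = None
    run_gene_scan: bool = True
    skip_sample_qc: bool = False
    exclude_hematological: bool = True
    seed: int = 0


def _read_table(path: str, index_col: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_col not in df.columns:
        raise ValueError(f"{path}: missing column {index_col!r}")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = df[index_col].duplicated()
    if bad.any():
        raise ValueError(f"{path}: duplicate {index_col} at row {int(np.flatnonzero(bad)[0])}")
    return df.set_index(index_col)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline from files on disk; returns the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    cfg_repr = json.dumps(
        {k: str(v) for k, v in vars(cfg).items() if k != "analysis"}, sort_keys=True
    )
    manifest["config_hash"] = hashlib.sha256(cfg_repr.encode()).hexdigest()[:16]

    stage = "load_inputs"
    try:
        cohort = read_vcf(cfg.vcf)
        ann = _read_table(cfg.annotations, "variant_id",
                          ["gene", "consequence", "clinvar"]).copy()
        anchors = pd.read_csv(cfg.clinvar_anchors, sep="\t")
        cov_table = _read_table(cfg.covariates, "participant", ["status"])
        gene_sets = read_gmt(cfg.gene_sets)
        tumor = _read_table(cfg.tumor, "participant", []) if cfg.tumor else None
        reference = read_vcf(cfg.reference_vcf) if cfg.reference_vcf else None
        ref_labels = None
        if cfg.reference_labels:
            ref_labels = _read_table(cfg.reference_labels, "sample", ["label"])["label"]
        manifest["stages"][stage] = {
            "n_samples": cohort.n_samples, "n_variants": cohort.n_variants,
            "n_gene_sets": len(gene_sets),
        }
    except Exception as e:  # noqa: BLE001 - abort with stage name
        raise PipelineError(stage, e) from e

    results = run_analysis(
        cohort, ann, anchors, cov_table, gene_sets,
        tumor=tumor, reference=reference, reference_labels=ref_labels,
        analysis=cfg.analysis, targeted_sets=cfg.targeted_sets,
        catalog=read_gmt(cfg.catalog) if cfg.catalog else None,
        run_gene_scan=cfg.run_gene_scan, skip_sample_qc=cfg.skip_sample_qc,
        exclude_hematological=cfg.exclude_hematological,
        manifest=manifest,
    )
    _write_outputs(results, outdir)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def run_analysis(
    cohort: CohortGenotypes,
    ann: pd.DataFrame,
    anchors: pd.DataFrame,
    cov_table: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    tumor: pd.DataFrame | None = None,
    reference: CohortGenotypes | None = None,
    reference_labels: pd.Series | None = None,
    analysis: AnalysisConfig = AnalysisConfig(),
    targeted_sets: list[str] | None = None,
    catalog: dict[str, list[str]] | None = None,
    run_gene_scan: bool = True,
    skip_sample_qc: bool = False,
    exclude_hematological: bool = True,
    manifest: dict | None = None,
) -> dict:
    """In-memory pipeline; see :func:`run_pipeline` for the file surface."""
    from .variant_qc import (
        apply_genotype_filters,
        apply_site_filters,
        case_control_site_screen,
        filter_sample_missingness,
    )

    manifest = manifest if manifest is not None else {"stages": {}}
    stages = manifest.setdefault("stages", {})
    results: dict = {"qc_reports": []}

    def record(stage: str, **counts):
        stages[stage] = counts
        logger.info("stage %s: %s", stage, counts)

    def run_stage(stage, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    # --- variant-level QC ---------------------------------------------------
    def _sample_miss():
        if skip_sample_qc:
            return cohort, None
        out, rep = filter_sample_missingness(cohort, analysis.qc)
        results["qc_reports"].append(rep)
        return out, rep

    ch, _ = run_stage("sample_missingness", _sample_miss)
    record("sample_missingness", n_samples=ch.n_samples)

    def _geno():
        out, rep = apply_genotype_filters(ch, analysis.qc)
        results["qc_reports"].append(rep)
        return out

    ch = run_stage("genotype_qc", _geno)
    record("genotype_qc", n_samples=ch.n_samples, n_variants=ch.n_variants)

    def _site():
        keep, _ = apply_site_filters(ch.variants, analysis.qc)
        return ch.subset_variants(keep)

    ch = run_stage("site_qc", _site)
    record("site_qc", n_variants=ch.n_variants)

    labels = cov_table["status"].reindex(ch.samples)
    if labels.isna().any():
        raise PipelineError("labels", ValueError("participants missing case/control status"))

    def _screen():
        keep, _ = case_control_site_screen(ch, labels.to_numpy() == 1, analysis.qc)
        return ch.subset_variants(keep)

    ch = run_stage("case_control_screen", _screen)
    record("case_control_screen", n_variants=ch.n_variants)

    # --- sample-level QC ----------------------------------------------------
    removed: set[str] = set()
    if not skip_sample_qc:
        def _kinship():
            panel = build_common_panel(ch, analysis.pca)
            kin = kinship_table(panel, analysis.kinship)
            rem, _ = prune_relatives(kin, ch.sample_missingness(), analysis.kinship)
            return panel, kin, rem

        panel, kin, removed = run_stage("kinship_pruning", _kinship)
        results["kinship"] = kin
        record("kinship_pruning", n_pairs_flagged=int(kin["related"].sum()),
               n_removed=len(removed))
        ch = ch.subset_samples([s for s in ch.samples if s not in removed])

        def _pca_gate():
            panel_kept = build_common_panel(ch, analysis.pca)
            model = compute_ancestry_pcs(
                panel_kept, reference, reference_labels,
                k=min(analysis.pca.n_components, panel_kept.n_variants,
                      panel_kept.n_samples),
            )
            region = resolve_gate(model, analysis.gate)
            retained, counts = gate_ancestry(
                model, region, cov_table["status"]
            )
            return model, retained, counts

        model, retained, counts = run_stage("pca_gating", _pca_gate)
        results["pca_pregate"] = model.scores
        record("pca_gating", **counts)
        ch = ch.subset_samples(retained)
    labels = cov_table["status"].reindex(ch.samples)

    # covariate PCs are recomputed on the gated participants
    def _pca_covars():
        panel = build_common_panel(ch, analysis.pca)
        k = min(2, panel.n_variants, panel.n_samples)
        model = compute_ancestry_pcs(panel, k=k)
        return model.scores.loc[ch.samples, [f"PC{i+1}" for i in range(k)]]

    pc_scores = run_stage("pca_covariates", _pca_covars)
    results["pc_scores"] = pc_scores
    record("pca_covariates", n_samples=len(pc_scores))

    # --- RDV classification -------------------------------------------------
    def _classify():
        maf = cohort_allele_stats(ch, labels.to_numpy() == 1)
        ann_qc = ann.reindex(ch.variants.index).dropna(subset=["gene"])
        classified = classify_rdvs(ann_qc, maf.loc[ann_qc.index], anchors, analysis.rarity)
        matrix = build_rdv_matrix(ch, classified)
        syn = synonymous_background(ch, ann_qc, maf["maf_all"], analysis.rarity)
        return classified, matrix, syn

    classified, rdv_matrix, syn = run_stage("rdv_classification", _classify)
    results.update(classified=classified, rdv_matrix=rdv_matrix, syn_background=syn)
    record(
        "rdv_classification",
        n_rdvs=int(classified["is_rdv"].sum()),
        n_rdv_genes=int(classified.loc[classified["is_rdv"], "gene"].nunique()),
    )

    # --- burden -------------------------------------------------------------
    covars = pd.DataFrame({"n_syn_genes": syn.reindex(ch.samples)}, index=ch.samples)
    covars["PC1"] = pc_scores["PC1"] if "PC1" in pc_scores else 0.0
    covars["PC2"] = pc_scores["PC2"] if "PC2" in pc_scores else 0.0
    if analysis.burden.include_gender and "gender" in cov_table:
        g = cov_table["gender"].reindex(ch.samples).replace("", np.nan)
        keep = g.notna()
        covars = covars[keep]
        covars["gender"] = (g[keep] == "F").astype(float)
        labels = labels[keep]
        rdv_matrix = rdv_matrix.reindex(covars.index)
    use_covars = covars[[c for c in analysis.burden.covariates if c in covars]
                        + (["gender"] if "gender" in covars else [])]
    constant = [c for c in use_covars.columns if use_covars[c].nunique() <= 1]
    if constant:
        # degenerate in this cohort (e.g. nobody carries an ultra-rare
        # synonymous variant at small n); keep the model full rank
        logger.warning("dropping constant covariates: %s", constant)
        use_covars = use_covars.drop(columns=constant)

    sets_to_test = targeted_sets or list(gene_sets)

    def _burden():
        rows = {}
        for name in sets_to_test:
            if name not in gene_sets:
                raise KeyError(f"unknown gene-set {name!r}")
            rows[name] = burden_test_geneset(
                rdv_matrix, labels, gene_sets[name], use_covars,
                unit=name, classified=classified, settings=analysis.burden,
            )
        return rows

    targeted = run_stage("burden_targeted", _burden)
    results["burden_targeted"] = targeted
    record("burden_targeted", n_sets=len(targeted))

    if run_gene_scan and rdv_matrix.shape[1] > 0:
        gene_units = {g: [g] for g in rdv_matrix.columns}
        results["burden_gene_scan"] = run_stage(
            "burden_gene_scan",
            lambda: scan_units(rdv_matrix, labels, gene_units, use_covars,
                               classified=classified, settings=analysis.burden),
        )
        record("burden_gene_scan", n_genes=len(results["burden_gene_scan"]))
    if catalog:
        results["burden_catalog"] = run_stage(
            "burden_catalog",
            lambda: scan_units(rdv_matrix, labels, catalog, use_covars,
                               classified=classified, settings=analysis.burden),
        )
        record("burden_catalog", n_units=len(results["burden_catalog"]))

    # --- load groups and dose response -------------------------------------
    def _load():
        loads, doses = {}, {}
        for name in sets_to_test:
            lg = assign_load_groups(rdv_matrix, gene_sets[name], name)
            loads[name] = lg
            doses[name] = load_dose_association(lg, labels, use_covars, analysis.burden)
        return loads, doses

    loads, doses = run_stage("load_groups", _load)
    results.update(load_groups=loads, dose_association=doses)
    record("load_groups", n_sets=len(loads))

    # --- phenotype associations ---------------------------------------------
    if tumor is not None and not tumor.empty:
        def _pheno():
            return phenotype_associations(
                tumor, loads, exclude_hematological=exclude_hematological
            )

        results["phenotype"] = run_stage("phenotype_associations", _pheno)
        record("phenotype_associations", n_sets=len(results["phenotype"]))
    return results


def phenotype_associations(
    tumor: pd.DataFrame,
    loads: dict[str, pd.DataFrame],
    exclude_hematological: bool = True,
) -> dict:
    """Onset-age, TMB and M1-fraction contrasts per gene-set plus the
    M1-vs-survival Cox model (stratified by cancer type)."""
    tme = tumor
    if exclude_hematological and "cancer_type" in tumor:
        tme = tumor[~tumor["cancer_type"].isin(HEMATOLOGICAL_TYPES)]
    count_cols = {"missense": "n_missense", "nonsense": "n_nonsense",
                  "frameshift": "n_frameshift", "inframe": "n_inframe"}
    tmb = compute_tmb(tumor[list(count_cols.values())].rename(
        columns={v: k for k, v in count_cols.items()}))
    rel = tme[[f"frac_{c}" for c in IMMUNE_CELL_TYPES]].copy()
    rel.columns = IMMUNE_CELL_TYPES
    abs_frac = absolute_immune_fraction(rel, tme["leukocyte_fraction"])
    m1 = abs_frac["Macrophages_M1"]

    out: dict = {}
    for name, lg in loads.items():
        cases = lg.reindex(tumor.index).dropna(subset=["group"])
        entry = {
            "onset": load_phenotype_report(cases, tumor["age_at_diagnosis"]),
            "tmb": load_phenotype_report(cases, tmb),
            "m1_fraction": load_phenotype_report(cases.reindex(tme.index).dropna(subset=["group"]), m1),
        }
        out[name] = entry
    out["_m1_survival"] = cox_survival(
        tme["survival_time"], tme["survival_event"], m1,
        strata=tme["cancer_type"] if "cancer_type" in tme else None,
    )
    return out


def _write_outputs(results: dict, outdir: Path) -> None:
    for rep in results.get("qc_reports", []):
        mode = "a" if (outdir / "qc_report.tsv").exists() else "w"
        rep.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False,
                              mode=mode, header=mode == "w")
    if "kinship" in results:
        results["kinship"].to_csv(outdir / "kinship.tsv", sep="\t", index=False)
    if "pc_scores" in results:
        results["pc_scores"].to_csv(outdir / "pc_scores.tsv", sep="\t",
                                    index_label="participant")
    if "classified" in results:
        results["classified"].to_csv(outdir / "classified_variants.tsv", sep="\t",
                                     index_label="variant_id")
    if "rdv_matrix" in results:
        results["rdv_matrix"].to_csv(outdir / "rdv_matrix.tsv", sep="\t")
    if "syn_background" in results:
        results["syn_background"].to_csv(outdir / "syn_background.tsv", sep="\t",
                                         index_label="participant")
    if "burden_targeted" in results:
        pd.DataFrame([r.to_dict() for r in results["burden_targeted"].values()]
                     ).to_csv(outdir / "burden_targeted.tsv", sep="\t", index=False)
    for key in ("burden_gene_scan", "burden_catalog"):
        if key in results:
            results[key].to_csv(outdir / f"{key}.tsv", sep="\t")
    if "load_groups" in results:
        for name, lg in results["load_groups"].items():
            lg.to_csv(outdir / f"load_groups_{name}.tsv", sep="\t",
                      index_label="participant")
    if "dose_association" in results:
        rows = []
        for name, contrasts in results["dose_association"].items():
            for label, res in contrasts.items():
                d = res.to_dict()
                d["gene_set"], d["contrast"] = name, label
                rows.append(d)
        if rows:
            pd.DataFrame(rows).to_csv(outdir / "dose_association.tsv", sep="\t",
                                      index=False)
    if "phenotype" in results:
        serial = {}
        for name, entry in results["phenotype"].items():
            if name == "_m1_survival":
                r = entry
                serial[name] = {"hazard_ratio": r.hazard_ratio, "p_value": r.p_value,
                                "n": r.n, "n_events": r.n_events, "note": r.note}
            else:
                serial[name] = {
                    ph: {c: {"statistic": t.statistic, "p_value": t.p_value,
                             "group_sizes": list(t.group_sizes), "method": t.method}
                         for c, t in tests.items()}
                    for ph, tests in entry.items()
                }
        with open(outdir / "phenotype_associations.json", "w") as fh:
            json.dump(serial, fh, indent=2, default=float)
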