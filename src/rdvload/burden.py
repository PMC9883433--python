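"""Carrier-collapsing burden tests at gene and gene-set level.

A unit (gene or gene-set) is collapsed to one binary exposure per
participant — carries >= 1 qualifying RDV allele in the unit — and
tested with Firth-penalized logistic regression against case status,
adjusting for the synonymous background load and the first two ancestry
PCs (optionally gender).  Scans over a unit catalog append
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import BurdenSettings
from .firth import fit_firth, profile_ci_and_p, wald_ci_and_p


@dataclass
class BurdenResult:
    """One Table-2-style row: OR (p) [95% CI] plus carrier/variant tallies."""

    unit: str
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n_case_carriers: int
    n_control_carriers: int
    n_cases: int
    n_controls: int
    n_variants: int = 0
    n_genes: int = 0
    converged: bool = True
    open_ci: bool = False
    note: str = ""

    @property
    def testable(self) -> bool:
        return np.isfinite(self.odds_ratio)

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "p_value": self.p_value,
            "n_case_carriers": self.n_case_carriers,
            "n_control_carriers": self.n_control_carriers,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_variants": self.n_variants,
            "n_genes": self.n_genes,
            "converged": self.converged,
        }


def carrier_fraction_pct(n_carriers: int, n_total: int) -> float:
    """Carrier frequency as the percentage printed in burden reports."""
    if n_total <= 0:
        raise ValueError("cohort size must be positive")
    return round(100.0 * n_carriers / n_total, 2)


def carrier_cell(n_carriers: int, n_total: int) -> str:
    """Format '464 (7.28%)' style report cells."""
    return f"{n_carriers} ({carrier_fraction_pct(n_carriers, n_total):.2f}%)"


def design_matrix(
    y: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + exposure + covariate columns; rejects missing values."""
    cols = [np.ones(len(y)), np.asarray(exposure, dtype=float)]
    names = ["intercept", "exposure"]
    if covariates is not None and covariates.shape[1] > 0:
        if covariates.isna().any().any():
            bad = list(covariates.columns[covariates.isna().any()])
            raise ValueError(f"covariates contain missing values: {bad}")
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(str(c))
    return np.column_stack(cols), names


def burden_test(
    y: np.ndarray,
    carrier: np.ndarray,
    covariates: pd.DataFrame | None = None,
    unit: str = "unit",
    settings: BurdenSettings = BurdenSettings(),
    n_variants: int = 0,
    n_genes: int = 0,
) -> BurdenResult:
    """Firth burden test of one collapsed unit.

    With zero carriers overall the unit is untestable: OR is NaN and the
    result carries a note (scans skip it)."""
    y = np.asarray(y, dtype=int)
    carrier = np.asarray(carrier, dtype=int)
    ncc = int(carrier[y == 1].sum())
    nkc = int(carrier[y == 0].sum())
    base = dict(
        unit=unit,
        n_case_carriers=ncc,
        n_control_carriers=nkc,
        n_cases=int((y == 1).sum()),
        n_controls=int((y == 0).sum()),
        n_variants=n_variants,
        n_genes=n_genes,
    )
    if ncc + nkc == 0:
        return BurdenResult(
            odds_ratio=np.nan, ci95=(np.nan, np.nan), p_value=np.nan,
            converged=False, note="no carriers", **base,
        )
    X, names = design_matrix(y, carrier, covariates)
    fit = fit_firth(X, y, column_names=names)
    if settings.p_method == "wald":
        (lo, hi), p = wald_ci_and_p(fit, 1, settings.ci_level)
        open_ci = False
    else:
        (lo, hi), p, open_ci = profile_ci_and_p(X, y, fit, 1, settings.ci_level)
    return BurdenResult(
        odds_ratio=float(np.exp(fit.beta[1])),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p_value=p,
        converged=fit.converged,
        open_ci=open_ci,
        note="" if fit.converged else "did not converge",
        **base,
    )


def burden_test_counts(
    case_carriers: int,
    n_cases: int,
    control_carriers: int,
    n_controls: int,
    unit: str = "unit",
    settings: BurdenSettings = BurdenSettings(),
) -> BurdenResult:
    """Covariate-free burden test reconstructed from a 2x2 carrier table."""
    y = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    carrier = np.concatenate([
        np.ones(case_carriers, int), np.zeros(n_cases - case_carriers, int),
        np.ones(control_carriers, int), np.zeros(n_controls - control_carriers, int),
    ])
    return burden_test(y, carrier, None, unit=unit, settings=settings)


def unit_carriers(rdv_matrix: pd.DataFrame, genes) -> pd.Series:
    """Carrier-of-unit indicator from the participants x genes RDV matrix."""
    present = [g for g in genes if g in rdv_matrix.columns]
    if not present:
        return pd.Series(False, index=rdv_matrix.index)
    return rdv_matrix[present].sum(axis=1) > 0


def unit_tallies(
    rdv_matrix: pd.DataFrame, classified: pd.DataFrame, genes
) -> tuple[int, int]:
    """Distinct carried RDV sites and genes within the unit (any participant)."""
    present = [g for g in genes if g in rdv_matrix.columns]
    if not present:
        return 0, 0
    carried_genes = [g for g in present if (rdv_matrix[g] > 0).any()]
    rdv = classified[classified["is_rdv"] & classified["gene"].isin(carried_genes)]
    return int(len(rdv)), len(carried_genes)


def burden_test_geneset(
    rdv_matrix: pd.DataFrame,
    case_by_sample: pd.Series,
    genes,
    covariates: pd.DataFrame | None = None,
    unit: str = "unit",
    classified: pd.DataFrame | None = None,
    settings: BurdenSettings = BurdenSettings(),
) -> BurdenResult:
    ids = rdv_matrix.index
    y = case_by_sample.reindex(ids)
    if y.isna().any():
        raise ValueError("case label missing for some participants")
    carrier = unit_carriers(rdv_matrix, genes).to_numpy()
    nv, ng = unit_tallies(rdv_matrix, classified, genes) if classified is not None else (0, 0)
    cov = covariates.reindex(ids) if covariates is not None else None
    return burden_test(
        y.to_numpy(int), carrier, cov, unit=unit, settings=settings,
        n_variants=nv, n_genes=ng,
    )


def scan_units(
    rdv_matrix: pd.DataFrame,
    case_by_sample: pd.Series,
    units: dict[str, list[str]],
    covariates: pd.DataFrame | None = None,
    classified: pd.DataFrame | None = None,
    settings: BurdenSettings = BurdenSettings(),
) -> pd.DataFrame:
    """Burden-test every unit in a catalog; append BH q-values.

    Units with zero observed carriers are reported with NaN statistics
    and excluded from the multiple-testing correction.  Output is
    deterministically ordered by (p, unit id).
    """
    if not units:
        raise ValueError("empty unit catalog")
    rows = []
    for name in units:
        res = burden_test_geneset(
            rdv_matrix, case_by_sample, units[name], covariates,
            unit=name, classified=classified, settings=settings,
        )
        rows.append(res.to_dict())
    out = pd.DataFrame(rows).set_index("unit")
    tested = out["p_value"].notna()
    out["q_value"] = np.nan
    if tested.any():
        out.loc[tested, "q_value"] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return out.sort_index(kind="mergesort").sort_values("p_value", kind="mergesort")


@dataclass
class CancerTypeGroups:
    """Configurable case-subsetting by cancer type (cases vs full controls)."""

    groups: dict[str, list[str]] = field(default_factory=dict)

    def subset_mask(
        self, case_by_sample: pd.Series, cancer_type: pd.Series, group: str
    ) -> pd.Series:
        if group not in self.groups:
            raise KeyError(f"unknown cancer-type group {group!r}")
        wanted = set(self.groups[group])
        is_case = case_by_sample == 1
        keep_case = is_case & cancer_type.reindex(case_by_sample.index).isin(wanted)
        return keep_case | ~is_case
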