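"""Genotype-level and case/control-aware site-level QC cascade.

Order of application (missingness fractions depend on it): sample
missingness pre-filter, then per-call genotype masks, then site-level
statistic filters, then the case/control missingness screen.  All
filters are idempotent and tightening any threshold can only shrink the
kept set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MISSING, CohortGenotypes
from .config import QcThresholds

_TRANCHE_RE = re.compile(r"VQSRTranche\w*?(\d+(?:\.\d+)?)to\d+(?:\.\d+)?")

#: site-filter reason codes, in reporting order
SITE_RULES = ["qual", "qd", "mq", "rprs", "mqrs", "tranche"]


@dataclass
class QcReport:
    """Per-rule removal tallies for one QC stage."""

    stage: str
    counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": self.stage, "rule": list(self.counts), "n_removed": list(self.counts.values())}
        )


def filter_sample_missingness(
    cohort: CohortGenotypes, t: QcThresholds = QcThresholds()
) -> tuple[CohortGenotypes, QcReport]:
    """Drop participants with >= ``sample_miss_max`` missing genotypes."""
    miss = cohort.sample_missingness()
    keep = miss < t.sample_miss_max
    report = QcReport("sample_missingness", {"sample_missingness": int((~keep).sum())})
    return cohort.subset_samples(list(miss.index[keep])), report


def apply_genotype_filters(
    cohort: CohortGenotypes, t: QcThresholds = QcThresholds()
) -> tuple[CohortGenotypes, QcReport]:
    """Mask individual calls failing GQ/DP/alt-depth/allele-balance rules.

    Heterozygous calls additionally require alternate allele fraction in
    [ab_low, ab_high] (inclusive); homozygous calls are exempt.  Non-
    reference calls with absent quality fields are masked and counted,
    never raised.
    """
    gt, gq, dp, ad = cohort.gt, cohort.gq, cohort.dp, cohort.ad_alt
    called = gt != MISSING
    nonref = gt > 0

    fail_gq = called & (gq < t.gq_min)
    fail_dp = called & (dp < t.dp_min)
    fail_ad = nonref & (ad < t.ad_alt_min)
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(dp > 0, ad / np.maximum(dp, 1), np.nan)
    het = gt == 1
    fail_ab = het & ~((ab >= t.ab_low) & (ab <= t.ab_high))

    fail = fail_gq | fail_dp | fail_ad | fail_ab
    out = cohort.subset_variants(np.arange(cohort.n_variants))
    out.gt = gt.copy()
    out.gt[fail] = MISSING
    report = QcReport(
        "genotype",
        {
            "gq": int(fail_gq.sum()),
            "dp": int(fail_dp.sum()),
            "ad_alt": int(fail_ad.sum()),
            "allele_balance": int(fail_ab.sum()),
        },
    )
    return out, report


def tranche_lower_bound(filter_label: str) -> float | None:
    """Lower sensitivity bound of a GATK VQSR tranche FILTER label, if any."""
    m = _TRANCHE_RE.search(filter_label or "")
    return float(m.group(1)) if m else None


def apply_site_filters(
    variants: pd.DataFrame, t: QcThresholds = QcThresholds()
) -> tuple[np.ndarray, pd.DataFrame]:
    """Evaluate site-level statistic filters; returns (keep mask, reasons).

    A site fails if any *defined* statistic violates its threshold or its
    FILTER names a VQSR tranche with lower bound >= ``tranche_max``.
    Absent rank-sum statistics (NaN) do not fail a site.  The reasons
    frame has one boolean column per rule so every violated rule is
    enumerated.
    """
    qual = variants["qual"].to_numpy(dtype=float)
    qd = variants["qd"].to_numpy(dtype=float)
    mq = variants["mq"].to_numpy(dtype=float)
    rprs = variants["rprs"].to_numpy(dtype=float)
    mqrs = variants["mqrs"].to_numpy(dtype=float)

    def defined_fail(x, ok):
        return np.isfinite(x) & ~ok

    reasons = pd.DataFrame(
        {
            "qual": defined_fail(qual, qual >= t.qual_min),
            "qd": defined_fail(qd, qd >= t.qd_min),
            "mq": defined_fail(mq, mq >= t.mq_min),
            "rprs": defined_fail(rprs, rprs > t.rprs_min),
            "mqrs": defined_fail(mqrs, mqrs > t.mqrs_min),
            "tranche": np.array(
                [
                    (b := tranche_lower_bound(f)) is not None and b >= t.tranche_max
                    for f in variants["filter"]
                ]
            ),
        },
        index=variants.index,
    )
    keep = ~reasons.any(axis=1).to_numpy()
    return keep, reasons


def case_control_site_screen(
    cohort: CohortGenotypes,
    case_mask: np.ndarray,
    t: QcThresholds = QcThresholds(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep sites with balanced and near-complete data in both arms.

    A site survives iff |miss_case - miss_control| <= ``diff_miss_max``
    and completeness (1 - missing fraction) >= ``completeness_min`` in
    both arms.  Returns (keep mask, per-site report with both rules); a
    site failing completeness is reported under completeness even if the
    differential rule also fails it.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    if case_mask.sum() == 0 or (~case_mask).sum() == 0:
        raise ValueError("case/control screen undefined without both arms")
    miss_case = cohort.missing_fraction(case_mask)
    miss_ctrl = cohort.missing_fraction(~case_mask)
    fail_complete = (1.0 - miss_case < t.completeness_min) | (
        1.0 - miss_ctrl < t.completeness_min
    )
    fail_diff = np.abs(miss_case - miss_ctrl) > t.diff_miss_max
    report = pd.DataFrame(
        {
            "miss_case": miss_case,
            "miss_control": miss_ctrl,
            "fail_completeness": fail_complete,
            "fail_differential": fail_diff & ~fail_complete,
        },
        index=cohort.variants.index,
    )
    return ~(fail_complete | fail_diff), report


def run_variant_qc(
    cohort: CohortGenotypes,
    case_by_sample: dict[str, int] | pd.Series,
    t: QcThresholds = QcThresholds(),
) -> tuple[CohortGenotypes, list[QcReport]]:
    """Full cascade: sample missingness -> genotype masks -> site screens."""
    reports: list[QcReport] = []
    cohort, rep = filter_sample_missingness(cohort, t)
    reports.append(rep)
    cohort, rep = apply_genotype_filters(cohort, t)
    reports.append(rep)
    keep_site, reasons = apply_site_filters(cohort.variants, t)
    reports.append(
        QcReport("site", {r: int(reasons[r].sum()) for r in SITE_RULES})
    )
    cohort = cohort.subset_variants(keep_site)
    labels = pd.Series(case_by_sample)
    case_mask = labels.reindex(cohort.samples).to_numpy(dtype=float)
    if np.isnan(case_mask).any():
        raise ValueError("every participant must be labeled case (1) or control (0)")
    keep_cc, cc_report = case_control_site_screen(cohort, case_mask == 1, t)
    reports.append(
        QcReport(
            "case_control_screen",
            {
                "completeness": int(cc_report["fail_completeness"].sum()),
                "differential_missingness": int(cc_report["fail_differential"].sum()),
            },
        )
    )
    return cohort.subset_variants(keep_cc), reports
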