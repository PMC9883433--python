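"""Per-individual RDV load and its phenotype associations.

RDV load within a gene-set counts the *distinct genes* carrying >= 1
qualifying RDV, grouped as zero / one / multi (>= 2).  Dose-response on
case status uses the same Firth model as the burden tests with one-vs-
zero and multi-vs-zero indicator exposures.  Phenotype contrasts use
rank tests: Mann-Whitney U with midrank ties (exact enumeration at
small n, tie-corrected normal approximation otherwise) and tie-corrected
Kruskal-Wallis.  Tumor mutational burden is the somatic missense +
nonsense + frameshift + inframe count per 38 Mb of exome; relative
immune fractions times the leukocyte fraction give absolute tissue
fractions; M1-vs-survival uses a stratified Cox proportional-hazards
model (lifelines, Efron ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .burden import BurdenResult, burden_test
from .config import BurdenSettings

LOAD_GROUPS = ("zero", "one", "multi")

#: somatic consequence classes entering the TMB numerator
TMB_CONSEQUENCES = ("missense", "nonsense", "frameshift", "inframe")

DEFAULT_EXOME_MB = 38.0


@dataclass(frozen=True)
class RankTestResult:
    statistic: float       # U (Mann-Whitney) or H (Kruskal-Wallis)
    p_value: float
    group_sizes: tuple[int, ...]
    method: str


def assign_load_groups(rdv_matrix: pd.DataFrame, genes, gene_set_id: str = "set") -> pd.DataFrame:
    """Count distinct carrier genes within the set and map to zero/one/multi."""
    genes = list(genes)
    if not genes:
        raise ValueError(f"gene-set {gene_set_id!r} is empty")
    present = [g for g in genes if g in rdv_matrix.columns]
    n = (rdv_matrix[present] > 0).sum(axis=1) if present else pd.Series(0, index=rdv_matrix.index)
    group = pd.cut(n, bins=[-1, 0, 1, np.inf], labels=LOAD_GROUPS).astype(str)
    return pd.DataFrame(
        {"gene_set": gene_set_id, "n_rdv_genes": n.astype(int), "group": group},
        index=rdv_matrix.index,
    )


def load_dose_association(
    load: pd.DataFrame,
    case_by_sample: pd.Series,
    covariates: pd.DataFrame | None = None,
    settings: BurdenSettings = BurdenSettings(),
) -> dict[str, BurdenResult]:
    """One-vs-zero and multi-vs-zero Firth contrasts against case status.

    An empty exposed group is skipped (logged via the returned keys).
    Monotonicity of the two ORs is reported, never enforced.
    """
    out: dict[str, BurdenResult] = {}
    y_all = case_by_sample.reindex(load.index)
    for label in ("one", "multi"):
        mask = load["group"].isin(["zero", label])
        sub = load[mask]
        if (sub["group"] == label).sum() == 0:
            continue
        y = y_all[mask].to_numpy(int)
        exposure = (sub["group"] == label).to_numpy(int)
        cov = covariates.reindex(sub.index) if covariates is not None else None
        out[f"{label}_vs_zero"] = burden_test(
            y, exposure, cov, unit=f"{load['gene_set'].iloc[0]}:{label}_vs_zero",
            settings=settings,
        )
    return out


def _u_statistic(ranks: np.ndarray, idx_x: np.ndarray, n1: int) -> float:
    r1 = float(ranks[idx_x].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(
    x, y, exact_max: int = 8, use_continuity: bool = False
) -> RankTestResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact two-sided p by full enumeration of rank assignments when both
    samples have <= ``exact_max`` observations (extremeness measured by
    |U - n1 n2 / 2|); otherwise a normal approximation with tie-corrected
    variance.  All values tied across both samples gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = _u_statistic(ranks, np.arange(n1), n1)
    mu = n1 * n2 / 2.0

    if np.ptp(pooled) == 0:
        return RankTestResult(u, 1.0, (n1, n2), "degenerate")

    if n1 <= exact_max and n2 <= exact_max:
        obs = abs(u - mu)
        total = 0
        hits = 0
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            if abs(_u_statistic(ranks, np.array(idx), n1) - mu) >= obs - 1e-9:
                hits += 1
        return RankTestResult(u, hits / total, (n1, n2), "exact")

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankTestResult(u, 1.0, (n1, n2), "degenerate")
    num = u - mu
    if use_continuity:
        num -= 0.5 * np.sign(num)
    z = num / np.sqrt(var)
    return RankTestResult(u, min(1.0, 2.0 * float(norm.sf(abs(z)))), (n1, n2), "normal")


def _h_statistic(ranks: np.ndarray, sizes: list[int], tie_term: float) -> float:
    n = len(ranks)
    h = 0.0
    start = 0
    for s in sizes:
        h += ranks[start:start + s].sum() ** 2 / s
        start += s
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def kruskal_wallis(groups, exact: bool = False) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H; p from chi-square with k-1 df.

    ``exact=True`` replaces the chi-square p by full enumeration of group
    assignments (P(H >= H_obs)); intended for total n <= ~12.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if tie_term <= 0:
        return RankTestResult(0.0, 1.0, tuple(sizes), "degenerate")
    h = _h_statistic(ranks, sizes, tie_term)
    if not exact:
        p = float(chi2.sf(h, df=len(groups) - 1))
        return RankTestResult(h, min(1.0, p), tuple(sizes), "chi2")

    # enumerate which pooled positions belong to each group, in order
    def _assignments(remaining: tuple[int, ...], sizes_left: list[int]):
        if len(sizes_left) == 1:
            yield [list(remaining)]
            return
        s = sizes_left[0]
        for pick in combinations(remaining, s):
            rest = tuple(i for i in remaining if i not in set(pick))
            for tail in _assignments(rest, sizes_left[1:]):
                yield [list(pick)] + tail

    hits = total = 0
    for assign in _assignments(tuple(range(n)), sizes):
        perm_ranks = np.concatenate([ranks[idx] for idx in assign])
        total += 1
        if _h_statistic(perm_ranks, sizes, tie_term) >= h - 1e-9:
            hits += 1
    return RankTestResult(h, hits / total, tuple(sizes), "exact")


def compute_tmb(counts: pd.DataFrame, exome_mb: float = DEFAULT_EXOME_MB) -> pd.Series:
    """Somatic missense+nonsense+frameshift+inframe mutations per Mb exome.

    Synonymous (or any other) consequence columns are ignored by the
    definition's consequence list.  Negative counts raise.
    """
    missing = [c for c in TMB_CONSEQUENCES if c not in counts.columns]
    if missing:
        raise ValueError(f"somatic count table missing columns: {missing}")
    sub = counts[list(TMB_CONSEQUENCES)]
    if (sub.to_numpy() < 0).any():
        raise ValueError("negative somatic mutation count")
    tmb = sub.sum(axis=1) / float(exome_mb)
    tmb.name = "tmb"
    return tmb


def absolute_immune_fraction(
    relative: pd.DataFrame, leukocyte_fraction: pd.Series, atol: float = 1e-6
) -> pd.DataFrame:
    """Scale relative immune-cell fractions to absolute tissue fractions.

    Requires each row of relative fractions to sum to 1 (within ``atol``)
    and leukocyte fractions in [0, 1]; the output rows sum to the
    leukocyte fraction.
    """
    lf = leukocyte_fraction.reindex(relative.index)
    if ((lf < 0) | (lf > 1)).any() or lf.isna().any():
        raise ValueError("leukocyte fraction must lie in [0, 1]")
    sums = relative.sum(axis=1)
    if (np.abs(sums - 1.0) > atol).any():
        bad = relative.index[np.abs(sums - 1.0) > atol][:5].tolist()
        raise ValueError(f"relative fractions do not sum to 1 for {bad}")
    return relative.mul(lf, axis=0)


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    p_value: float
    n: int
    n_events: int
    note: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.hazard_ratio)


def cox_survival(
    time: pd.Series,
    event: pd.Series,
    covariate: pd.Series,
    strata: pd.Series | None = None,
) -> CoxResult:
    """Stratified Cox PH of survival on one covariate (e.g. absolute M1
    fraction); hazard ratio per unit covariate with Wald p.

    Strata without events are dropped; a covariate with no variation
    yields an undefined (flagged) result rather than an error.
    """
    df = pd.DataFrame({"time": time, "event": event, "x": covariate})
    if strata is not None:
        df["stratum"] = strata
    df = df.dropna()
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if strata is not None:
        keep = df.groupby("stratum")["event"].transform("sum") > 0
        df = df[keep]
    if df.empty or df["event"].sum() == 0:
        return CoxResult(np.nan, np.nan, len(df), 0, note="no events")
    if df["x"].nunique() <= 1:
        return CoxResult(np.nan, np.nan, len(df), int(df["event"].sum()),
                         note="covariate has no variation")
    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    cph.fit(
        df, duration_col="time", event_col="event",
        strata="stratum" if strata is not None else None,
    )
    return CoxResult(
        hazard_ratio=float(np.exp(cph.params_["x"])),
        p_value=float(cph.summary.loc["x", "p"]),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def load_phenotype_report(
    load: pd.DataFrame,
    phenotype: pd.Series,
    exact_max: int = 8,
) -> dict[str, RankTestResult]:
    """Standard contrast panel for one phenotype against RDV load:
    any-vs-zero, one-vs-zero, multi-vs-zero Mann-Whitney plus the
    three-group Kruskal-Wallis (groups with data only)."""
    ph = phenotype.reindex(load.index)
    vals = {g: ph[load["group"] == g].dropna().to_numpy() for g in LOAD_GROUPS}
    out: dict[str, RankTestResult] = {}
    zero = vals["zero"]
    if len(zero):
        any_rdv = np.concatenate([vals["one"], vals["multi"]])
        if len(any_rdv):
            out["any_vs_zero"] = mann_whitney(any_rdv, zero, exact_max)
        for g in ("one", "multi"):
            if len(vals[g]):
                out[f"{g}_vs_zero"] = mann_whitney(vals[g], zero, exact_max)
    nonempty = [vals[g] for g in LOAD_GROUPS if len(vals[g])]
    if len(nonempty) >= 2:
        out["kruskal_wallis"] = kruskal_wallis(nonempty)
    return out
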