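"""Sample-level QC: KING-robust kinship pruning and PCA ancestry gating.

Kinship uses the allele-frequency-free KING-robust estimator

    phi_hat = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j))

over SNPs co-called in both members: ~0.5 for duplicates/MZ twins,
~0.25 first degree, ~0.125 second degree; pairs above 0.0884 are
flagged as related up to second degree.  Ancestry control standardizes
a common-SNP panel (MAF >= 5%, LD-pruned, call rate >= 0.99) to
(g - 2p)/sqrt(2p(1-p)), decomposes by SVD together with labeled
reference samples, and "gates" a rectangle on (PC1, PC2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MISSING, CohortGenotypes
from .config import GateSettings, KinshipSettings, PcaSettings


@dataclass(frozen=True)
class KinshipEstimate:
    pair: tuple[str, str]
    phi: float | None
    n_snps: int

    @property
    def evaluable(self) -> bool:
        return self.phi is not None


@dataclass
class PcaModel:
    """Shared score space for study and reference samples."""

    scores: pd.DataFrame          # index sample id; PC1..PCk + origin/label
    loadings: np.ndarray          # (n_snps_kept, k)
    explained_variance_ratio: np.ndarray
    kept_variants: pd.Index


@dataclass(frozen=True)
class GateRegion:
    pc1: tuple[float, float]
    pc2: tuple[float, float]

    def __post_init__(self):
        if not (self.pc1[0] < self.pc1[1] and self.pc2[0] < self.pc2[1]):
            raise ValueError("gate bounds must satisfy lower < upper on each axis")

    def contains(self, pc1: np.ndarray, pc2: np.ndarray) -> np.ndarray:
        return (
            (pc1 >= self.pc1[0]) & (pc1 <= self.pc1[1])
            & (pc2 >= self.pc2[0]) & (pc2 <= self.pc2[1])
        )


def estimate_kinship(g_i: np.ndarray, g_j: np.ndarray,
                     pair: tuple[str, str] = ("i", "j")) -> KinshipEstimate:
    """KING-robust kinship for one pair of dosage vectors (-1 = missing)."""
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    ok = (g_i != MISSING) & (g_j != MISSING)
    gi, gj = g_i[ok], g_j[ok]
    het_i, het_j = gi == 1, gj == 1
    n_hh = int(np.sum(het_i & het_j))
    n_opp = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    denom = int(het_i.sum() + het_j.sum())
    if denom == 0:
        return KinshipEstimate(pair, None, int(ok.sum()))
    return KinshipEstimate(pair, (n_hh - 2.0 * n_opp) / denom, int(ok.sum()))


def kinship_table(cohort: CohortGenotypes,
                  settings: KinshipSettings = KinshipSettings()) -> pd.DataFrame:
    """All-pairs KING-robust kinship over the cohort's variant panel.

    Vectorized via indicator-matrix products; returns one row per pair
    with ``phi``, ``n_snps`` and a ``related`` flag (phi > threshold).
    Unevaluable pairs (no heterozygous co-called sites) get phi = NaN.
    """
    g = cohort.gt
    called = (g != MISSING).astype(np.float32)
    het = (g == 1).astype(np.float32)
    hom_ref = (g == 0).astype(np.float32)
    hom_alt = (g == 2).astype(np.float32)

    n_hh = het.T @ het
    n_opp = hom_ref.T @ hom_alt + hom_alt.T @ hom_ref
    het_i_cocalled = het.T @ called          # het count of i over sites called in j
    denom = het_i_cocalled + het_i_cocalled.T
    n_co = called.T @ called

    ii, jj = np.triu_indices(cohort.n_samples, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hh - 2.0 * n_opp) / np.maximum(denom, 1), np.nan)
    samples = np.array(cohort.samples)
    tab = pd.DataFrame(
        {
            "id1": samples[ii],
            "id2": samples[jj],
            "phi": phi[ii, jj],
            "n_snps": n_co[ii, jj].astype(int),
        }
    )
    tab["related"] = tab["phi"] > settings.phi_threshold
    return tab


def prune_relatives(
    kinship: pd.DataFrame,
    missingness: pd.Series,
    settings: KinshipSettings = KinshipSettings(),
) -> tuple[set[str], list[str]]:
    """Greedy removal over flagged pairs, dropping the member with higher
    missingness (ties broken toward the lexicographically larger id).

    Returns (removal set, log lines).  Postcondition — no retained pair
    exceeds the threshold — is asserted before returning.
    """
    flagged = kinship[kinship["phi"] > settings.phi_threshold]
    removed: set[str] = set()
    log: list[str] = []
    for row in flagged.sort_values(["id1", "id2"]).itertuples():
        if row.id1 in removed or row.id2 in removed:
            continue
        for s in (row.id1, row.id2):
            if s not in missingness.index:
                raise KeyError(f"missingness unknown for flagged participant {s}")
        m1, m2 = missingness[row.id1], missingness[row.id2]
        if m1 > m2:
            drop = row.id1
        elif m2 > m1:
            drop = row.id2
        else:
            drop = max(row.id1, row.id2)
            log.append(f"missingness tie for pair ({row.id1},{row.id2}); removed {drop}")
        removed.add(drop)
    for row in flagged.itertuples():
        assert row.id1 in removed or row.id2 in removed, "pruning left a related pair"
    return removed, log


def _pairwise_r2(dos: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed)."""
    x = dos.astype(float)
    for k in range(x.shape[1]):
        col = x[:, k]
        m = col == MISSING
        col[m] = col[~m].mean() if (~m).any() else 0.0
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    c = (x / sd).T @ (x / sd) / x.shape[0]
    return c**2


def ld_prune(cohort: CohortGenotypes,
             settings: PcaSettings = PcaSettings()) -> np.ndarray:
    """Greedy windowed LD pruning; keeps the first variant of each
    correlated clique (pairwise r^2 > ``ld_r2_max``)."""
    n = cohort.n_variants
    keep = np.ones(n, dtype=bool)
    w, step = settings.ld_window, settings.ld_step
    start = 0
    while start < n:
        idx = np.arange(start, min(start + w, n))
        live = idx[keep[idx]]
        if live.size > 1:
            r2 = _pairwise_r2(cohort.gt[live].T.copy())
            for a in range(len(live)):
                if not keep[live[a]]:
                    continue
                drop = np.where(r2[a, a + 1:] > settings.ld_r2_max)[0]
                keep[live[a + 1 + drop]] = False
        start += step
    return keep


def build_common_panel(cohort: CohortGenotypes,
                       settings: PcaSettings = PcaSettings()) -> CohortGenotypes:
    """Restrict to biallelic SNPs with MAF >= maf_min and call rate >= min,
    then LD-prune.  Indels (len(ref)!=1 or len(alt)!=1) are excluded."""
    v = cohort.variants
    snp = (v["ref"].str.len() == 1) & (v["alt"].str.len() == 1)
    maf = cohort.minor_allele_frequency()
    call_rate = 1.0 - cohort.missing_fraction()
    mask = snp.to_numpy() & (maf >= settings.maf_min) & (call_rate >= settings.call_rate_min)
    panel = cohort.subset_variants(mask)
    return panel.subset_variants(ld_prune(panel, settings))


def compute_ancestry_pcs(
    panel: CohortGenotypes,
    reference: CohortGenotypes | None = None,
    reference_labels: pd.Series | None = None,
    k: int = 10,
) -> PcaModel:
    """Joint PCA of study + reference samples on the common panel.

    Genotypes are mean-imputed, standardized per site by
    (g - 2p)/sqrt(2p(1-p)) with p estimated on the combined matrix, and
    decomposed by SVD.  Monomorphic sites are dropped with a log entry in
    the model.  Raises if ``k`` exceeds the matrix rank.
    """
    mats = [panel.gt]
    ids = list(panel.samples)
    origin = ["study"] * panel.n_samples
    if reference is not None:
        common = panel.variants.index.intersection(reference.variants.index)
        panel = panel.subset_variants(panel.variants.index.get_indexer(common))
        ref = reference.subset_variants(reference.variants.index.get_indexer(common))
        mats = [panel.gt, ref.gt]
        ids = list(panel.samples) + list(ref.samples)
        origin = ["study"] * panel.n_samples + ["reference"] * ref.n_samples

    g = np.hstack(mats).astype(float).T  # samples x snps
    miss = g == MISSING
    col_sum = np.where(miss, 0.0, g).sum(axis=0)
    col_n = (~miss).sum(axis=0)
    p_hat = np.where(col_n > 0, col_sum / (2.0 * np.maximum(col_n, 1)), np.nan)
    poly = np.isfinite(p_hat) & (p_hat > 0.0) & (p_hat < 1.0)
    g = g[:, poly]
    p_hat = p_hat[poly]
    mean = 2.0 * p_hat
    g = np.where(miss[:, poly], mean, g)
    z = (g - mean) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))

    rank = min(z.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    df = pd.DataFrame(scores, index=ids, columns=[f"PC{i+1}" for i in range(k)])
    df["origin"] = origin
    if reference_labels is not None:
        df["label"] = reference_labels.reindex(df.index)
    return PcaModel(
        scores=df,
        loadings=vt[:k].T,
        explained_variance_ratio=(s[:k] ** 2) / np.sum(s**2),
        kept_variants=panel.variants.index[poly],
    )


def derive_gate(model: PcaModel, label: str, sd_multiplier: float = 3.0) -> GateRegion:
    """Rectangle around the labeled reference cluster: centroid +/- c*SD."""
    if "label" not in model.scores:
        raise ValueError("model has no reference labels to derive a gate from")
    ref = model.scores[model.scores["label"] == label]
    if ref.empty:
        raise ValueError(f"no reference samples labeled {label!r}")
    b = []
    for pc in ("PC1", "PC2"):
        mu, sd = ref[pc].mean(), ref[pc].std(ddof=0)
        b.append((mu - sd_multiplier * sd, mu + sd_multiplier * sd))
    return GateRegion(pc1=tuple(b[0]), pc2=tuple(b[1]))


def gate_ancestry(
    model: PcaModel,
    region: GateRegion,
    case_by_sample: pd.Series | None = None,
) -> tuple[list[str], dict[str, int]]:
    """Retain study participants whose (PC1, PC2) fall inside the gate.

    Returns (retained ids, counts by arm).  Raises if the gate is empty
    or, when labels are supplied, if it excludes all cases or controls.
    """
    study = model.scores[model.scores["origin"] == "study"]
    inside = region.contains(study["PC1"].to_numpy(), study["PC2"].to_numpy())
    retained = list(study.index[inside])
    if not retained:
        raise ValueError("empty gate: no study participants inside the region")
    counts = {"n_retained": len(retained)}
    if case_by_sample is not None:
        y = case_by_sample.reindex(retained)
        counts["n_cases"] = int((y == 1).sum())
        counts["n_controls"] = int((y == 0).sum())
        if counts["n_cases"] == 0 or counts["n_controls"] == 0:
            raise ValueError("gate excludes an entire arm; burden tests undefined")
    return retained, counts


def resolve_gate(model: PcaModel, settings: GateSettings) -> GateRegion:
    if settings.pc1_bounds is not None and settings.pc2_bounds is not None:
        return GateRegion(pc1=tuple(settings.pc1_bounds), pc2=tuple(settings.pc2_bounds))
    if settings.reference_label is not None:
        return derive_gate(model, settings.reference_label, settings.sd_multiplier)
    raise ValueError("gate settings need explicit bounds or a reference label")
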