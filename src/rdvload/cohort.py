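"""In-memory cohort genotype container and VCF 4.2 round-trip.

Genotypes are stored as an ``(n_variants, n_samples)`` int8 matrix of
alternate-allele dosages (0/1/2, -1 for missing) with parallel per-call
quality arrays (GQ, DP, alt-allele depth) and a per-site statistics
table.  Multi-allelic records are expected to be decomposed upstream;
:func:`read_vcf` rejects them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: columns every site table carries
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "qd", "mq", "rprs", "mqrs", "filter"]

MISSING = -1


@dataclass
class CohortGenotypes:
    """Participants x variants genotype matrix with per-call quality fields.

    ``variants`` is indexed by variant id (``chrom:pos:ref:alt``) and
    carries the site-level statistics used by the QC cascade.
    """

    samples: list[str]
    variants: pd.DataFrame
    gt: np.ndarray       # (n_var, n_samp) int8 dosage, -1 missing
    gq: np.ndarray       # (n_var, n_samp) int16
    dp: np.ndarray       # (n_var, n_samp) int16
    ad_alt: np.ndarray   # (n_var, n_samp) int16

    def __post_init__(self) -> None:
        n_var, n_samp = self.gt.shape
        if len(self.samples) != n_samp:
            raise ValueError("sample count does not match genotype matrix")
        if len(self.variants) != n_var:
            raise ValueError("variant table does not match genotype matrix")
        if len(set(self.samples)) != n_samp:
            raise ValueError("participant ids are not unique")

    @property
    def n_variants(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def sample_index(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"participants absent from genotype matrix: {missing[:5]}")
        return np.array([pos[s] for s in ids], dtype=int)

    def subset_samples(self, ids) -> "CohortGenotypes":
        idx = self.sample_index(ids)
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            gt=self.gt[:, idx].copy(),
            gq=self.gq[:, idx].copy(),
            dp=self.dp[:, idx].copy(),
            ad_alt=self.ad_alt[:, idx].copy(),
        )

    def subset_variants(self, mask: np.ndarray) -> "CohortGenotypes":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            variants=self.variants.iloc[idx].copy(),
            gt=self.gt[idx].copy(),
            gq=self.gq[idx].copy(),
            dp=self.dp[idx].copy(),
            ad_alt=self.ad_alt[idx].copy(),
        )

    def missing_fraction(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-variant missing-call fraction, optionally within a sample subset."""
        g = self.gt if sample_mask is None else self.gt[:, sample_mask]
        if g.shape[1] == 0:
            raise ValueError("empty sample subset")
        return np.mean(g == MISSING, axis=1)

    def sample_missingness(self) -> pd.Series:
        return pd.Series(np.mean(self.gt == MISSING, axis=0), index=self.samples)

    def alt_allele_frequency(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency among non-missing calls (NaN if none)."""
        g = self.gt if sample_mask is None else self.gt[:, sample_mask]
        called = g != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def minor_allele_frequency(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        af = self.alt_allele_frequency(sample_mask)
        return np.minimum(af, 1.0 - af)


def _fmt_float(x: float) -> str:
    return "." if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.2f}"


def write_vcf(cohort: CohortGenotypes, path) -> None:
    """Write a deterministic multi-sample VCF 4.2 (FORMAT GT:GQ:DP:AD)."""
    v = cohort.variants
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=rdvload\n")
    for c in pd.unique(v["chrom"]):
        buf.write(f"##contig=<ID={c}>\n")
    buf.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
    for fl in sorted(set(v["filter"]) - {"PASS", "."}):
        buf.write(f'##FILTER=<ID={fl},Description="VQSR tranche">\n')
    buf.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
    buf.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
    buf.write('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">\n')
    buf.write('##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    buf.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(cohort.samples) + "\n")

    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for i, (vid, row) in enumerate(v.iterrows()):
        info = []
        for tag, col in (("QD", "qd"), ("MQ", "mq"),
                         ("ReadPosRankSum", "rprs"), ("MQRankSum", "mqrs")):
            val = row[col]
            if val is not None and not (isinstance(val, float) and np.isnan(val)):
                info.append(f"{tag}={val:.2f}")
        fields = [
            str(row["chrom"]), str(int(row["pos"])), str(vid), str(row["ref"]),
            str(row["alt"]), _fmt_float(row["qual"]), str(row["filter"]),
            ";".join(info) if info else ".", "GT:GQ:DP:AD",
        ]
        g, q, d, a = cohort.gt[i], cohort.gq[i], cohort.dp[i], cohort.ad_alt[i]
        calls = [
            "./.:.:.:.,." if g[j] == MISSING
            else f"{gt_str[g[j]]}:{q[j]}:{d[j]}:{d[j] - a[j]},{a[j]}"
            for j in range(len(g))
        ]
        buf.write("\t".join(fields) + "\t" + "\t".join(calls) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_vcf(path) -> CohortGenotypes:
    """Read a multi-sample VCF via cyvcf2 into a :class:`CohortGenotypes`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)
    rows, gts, gqs, dps, ads = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; decompose before loading"
            )
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        gts.append(g)

        def _fmt(tag, default=0):
            arr = var.format(tag)
            if arr is None:
                return np.full(n, default, dtype=np.int16)
            a = arr[:, 0].astype(float)
            a[~np.isfinite(a)] = default
            a[a < 0] = default
            return a.astype(np.int16)

        gqs.append(_fmt("GQ"))
        dps.append(_fmt("DP"))
        ad = var.format("AD")
        if ad is None:
            ads.append(np.zeros(n, dtype=np.int16))
        else:
            a = ad[:, 1].astype(float)
            a[~np.isfinite(a)] = 0
            a[a < 0] = 0
            ads.append(a.astype(np.int16))
        rows.append({
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": var.ALT[0],
            "qual": var.QUAL if var.QUAL is not None else np.nan,
            "qd": _info_float(var, "QD"),
            "mq": _info_float(var, "MQ"),
            "rprs": _info_float(var, "ReadPosRankSum"),
            "mqrs": _info_float(var, "MQRankSum"),
            "filter": var.FILTER if var.FILTER else "PASS",
        })
    variants = pd.DataFrame(rows, columns=SITE_COLUMNS)
    variants.index = (
        variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
        + ":" + variants["ref"] + ":" + variants["alt"]
    )
    empty = (0, n)
    return CohortGenotypes(
        samples=samples,
        variants=variants,
        gt=np.vstack(gts) if gts else np.empty(empty, np.int8),
        gq=np.vstack(gqs) if gqs else np.empty(empty, np.int16),
        dp=np.vstack(dps) if dps else np.empty(empty, np.int16),
        ad_alt=np.vstack(ads) if ads else np.empty(empty, np.int16),
    )


def _info_float(var, tag: str) -> float:
    val = var.INFO.get(tag)
    return float(val) if val is not None else np.nan
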