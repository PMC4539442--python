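"""Genotype file IO and marker / sample quality control.

Filters follow standard GWAS practice: drop SNPs out of Hardy-Weinberg
equilibrium (exact-test p < 1e-6), with call rate < 95% or MAF < 1%; drop
samples with call rate < 95%, heterozygosity > 30%, or a pairwise
identity-by-state proportion > 0.8 (duplicates / close relatives, keeping
the member with the better call rate).  Missing genotypes are filled by
per-SNP mean dosage and population structure is summarized by principal
component scores of the standardized dosage matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import GenotypeMatrix, QCReport


# ---------------------------------------------------------------------------
# readers / writers

def read_genotypes(path: str, dialect: str = "dosage_tsv") -> GenotypeMatrix:
    """Read a genotype matrix; dialect in {ped_map, raw, dosage_tsv}.

    ``path`` is the file for raw/dosage_tsv and the prefix (without
    extension) for ped_map.  Whatever the on-disk allele order, dosages are
    returned counting the minor allele.
    """
    if dialect == "ped_map":
        return _read_ped_map(path)
    if dialect == "raw":
        return _read_raw(path)
    if dialect == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _default_meta(snp_ids, allele1=None, allele2=None) -> pd.DataFrame:
    p = len(snp_ids)
    return pd.DataFrame(
        {
            "id": list(snp_ids),
            "chrom": 1,
            "pos": np.arange(1, p + 1),
            "allele1": allele1 if allele1 is not None else ["A"] * p,
            "allele2": allele2 if allele2 is not None else ["G"] * p,
        }
    )


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "sample_id":
        raise ValueError("dosage TSV must start with a sample_id column")
    ids = df["sample_id"].astype(str).tolist()
    dos = df.iloc[:, 1:].to_numpy(dtype=float)
    G = GenotypeMatrix(ids, _default_meta(df.columns[1:]), dos)
    return _flip_to_minor(G)


def _read_raw(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise ValueError(".raw header does not start with the six PLINK columns")
        snp_cols = header[6:]
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + len(snp_cols):
                raise ValueError(
                    f"line {lineno}: expected {6 + len(snp_cols)} fields, got {len(f)}"
                )
            ids.append(f[1])
            rows.append([np.nan if v == "NA" else float(v) for v in f[6:]])
    snp_ids, counted = [], []
    for col in snp_cols:
        sid, _, allele = col.rpartition("_")
        snp_ids.append(sid if sid else col)
        counted.append(allele if sid else "A")
    G = GenotypeMatrix(
        ids, _default_meta(snp_ids, allele1=counted), np.asarray(rows, dtype=float)
    )
    return _flip_to_minor(G)


def _read_ped_map(prefix: str) -> GenotypeMatrix:
    mp = pd.read_csv(
        f"{prefix}.map",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos"],
        dtype={"id": str},
    )
    p = len(mp)
    ids, allele_rows = [], []
    with open(f"{prefix}.ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + 2 * p:
                raise ValueError(
                    f"line {lineno}: expected {6 + 2 * p} fields for {p} SNPs, got {len(f)}"
                )
            ids.append(f[1])
            allele_rows.append(f[6:])
    n = len(ids)
    a = np.array(allele_rows, dtype=object).reshape(n, p, 2)
    dos = np.full((n, p), np.nan)
    allele1, allele2 = [], []
    for j in range(p):
        pair = a[:, j, :]
        valid = pair[(pair != "0").all(axis=1)]
        alleles, counts = np.unique(valid, return_counts=True)
        if len(alleles) == 0:
            allele1.append("A")
            allele2.append("G")
            continue
        if len(alleles) > 2:
            raise ValueError(f"SNP {mp['id'][j]} has more than two alleles")
        order = np.lexsort((alleles, counts))  # minor first; count ties broken by name
        minor = alleles[order[0]]
        major = alleles[order[-1]] if len(alleles) > 1 else minor
        allele1.append(minor)
        allele2.append(major)
        obs = (pair != "0").all(axis=1)
        dos[obs, j] = (pair[obs] == minor).sum(axis=1)
    meta = _default_meta(mp["id"], allele1, allele2)
    meta["chrom"] = mp["chrom"].to_numpy()
    meta["pos"] = mp["pos"].to_numpy()
    return GenotypeMatrix(ids, meta, dos)


def _flip_to_minor(G: GenotypeMatrix) -> GenotypeMatrix:
    """Recode columns whose counted-allele frequency exceeds 0.5."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(G.dosages, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        G = G.copy()
        G.dosages[:, flip] = 2.0 - G.dosages[:, flip]
        a1 = G.snp_meta["allele1"].copy()
        G.snp_meta.loc[flip, "allele1"] = G.snp_meta.loc[flip, "allele2"]
        G.snp_meta.loc[flip, "allele2"] = a1[flip]
    return G


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE test p-value (Levene-Haldane, not mid-p).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_a = 2 * n_aa + n_Aa  # rarer-allele count (either orientation works)
    n_A = 2 * n_AA + n_Aa
    if n_a > n_A:
        n_a, n_A = n_A, n_a
    # possible heterozygote counts share the parity of n_a
    hets = np.arange(n_a % 2, n_a + 1, 2)
    # log P(n_Aa = h | allele counts) up to a constant:
    #   P ~ n! / (nAA! nAa! naa!) * 2^nAa  with nAA=(n_A-h)/2 (orientation-symmetric)
    naa = (n_a - hets) // 2
    nAA = (n_A - hets) // 2
    logp = hets * np.log(2.0) - (
        gammaln(nAA + 1) + gammaln(hets + 1) + gammaln(naa + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_Aa]
    if len(obs) != 1:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(prob[prob <= obs[0] * (1 + 1e-12)].sum())


def _hwe_pvalues(G: GenotypeMatrix) -> np.ndarray:
    dos = G.dosages
    p = G.n_snps
    out = np.ones(p)
    for j in range(p):
        col = dos[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            out[j] = 1.0
            continue
        n_aa = int((col == 2).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        out[j] = hwe_exact_test(n_AA, n_Aa, n_aa)
    return out


# ---------------------------------------------------------------------------
# QC filters

def snp_qc(
    G: GenotypeMatrix,
    hwe_thr: float = 1e-6,
    call_thr: float = 0.95,
    maf_thr: float = 0.01,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with HWE p < hwe_thr, call rate < call_thr or MAF < maf_thr.

    All statistics use nonmissing calls only; each removed SNP is reported
    with its first failing criterion in the order (hwe, call_rate, maf).
    """
    if G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    pvals = _hwe_pvalues(G)
    call = G.snp_call_rate()
    maf = G.maf()
    report = QCReport(
        thresholds={"hwe": hwe_thr, "call_rate": call_thr, "maf": maf_thr},
        n_snps_before=G.n_snps,
        n_samples_before=G.n_samples,
    )
    keep = []
    for j, sid in enumerate(G.snp_ids):
        if pvals[j] < hwe_thr:
            report.removed_snps.append((sid, "hwe"))
        elif call[j] < call_thr:
            report.removed_snps.append((sid, "call_rate"))
        elif maf[j] < maf_thr:
            report.removed_snps.append((sid, "maf"))
        else:
            keep.append(j)
    out = G.subset(snps=keep)
    report.n_snps_after = out.n_snps
    report.n_samples_after = out.n_samples
    return out, report


def ibs_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Mean pairwise identity-by-state proportion over shared nonmissing SNPs.

    Per SNP the IBS proportion between two dosages is (2 - |d_i - d_j|) / 2.
    """
    dos = G.dosages
    obs = ~np.isnan(dos)
    obs_f = obs.astype(float)
    shared = obs_f @ obs_f.T
    # sum over shared SNPs of |di - dj| via expansion on the 0/1/2 codes
    diff = np.zeros_like(shared)
    for a in (0.0, 1.0, 2.0):
        for b in (0.0, 1.0, 2.0):
            if a == b:
                continue
            ia = (obs & (np.abs(dos - a) < 1e-9)).astype(float)
            ib = (obs & (np.abs(dos - b) < 1e-9)).astype(float)
            diff += abs(a - b) * (ia @ ib.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = (2.0 * shared - diff) / (2.0 * shared)
    ibs[shared == 0] = 0.0
    return ibs


def sample_qc(
    G: GenotypeMatrix,
    call_thr: float = 0.95,
    het_thr: float = 0.30,
    ibs_thr: float = 0.8,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples with low call rate, high heterozygosity, or a relative.

    For every pair with mean IBS > ibs_thr the member with the lower call
    rate is removed (tie: the later sample id in row order).
    """
    if G.n_samples < 2:
        raise ValueError("sample QC needs at least 2 samples")
    report = QCReport(
        thresholds={"call_rate": call_thr, "het": het_thr, "ibs": ibs_thr},
        n_snps_before=G.n_snps,
        n_samples_before=G.n_samples,
    )
    call = G.sample_call_rate()
    obs = ~np.isnan(G.dosages)
    with np.errstate(invalid="ignore"):
        het = np.where(
            obs.sum(axis=1) > 0,
            (np.abs(G.dosages - 1.0) < 1e-9).sum(axis=1) / np.maximum(obs.sum(axis=1), 1),
            0.0,
        )
    removed = set()
    for i, sid in enumerate(G.sample_ids):
        if call[i] < call_thr:
            report.removed_samples.append((sid, "call_rate"))
            removed.add(i)
        elif het[i] > het_thr:
            report.removed_samples.append((sid, "heterozygosity"))
            removed.add(i)
    survivors = [i for i in range(G.n_samples) if i not in removed]
    if len(survivors) >= 2:
        sub = G.subset(samples=survivors)
        ibs = ibs_matrix(sub)
        for ai in range(len(survivors)):
            for bi in range(ai + 1, len(survivors)):
                i, j = survivors[ai], survivors[bi]
                if i in removed or j in removed:
                    continue
                if ibs[ai, bi] > ibs_thr:
                    if call[i] < call[j]:
                        drop = i
                    elif call[j] < call[i]:
                        drop = j
                    else:
                        drop = max(i, j)  # tie -> later sample
                    report.removed_samples.append((G.sample_ids[drop], "relatedness"))
                    removed.add(drop)
    keep = [i for i in range(G.n_samples) if i not in removed]
    out = G.subset(samples=keep)
    report.n_snps_after = out.n_snps
    report.n_samples_after = out.n_samples
    return out, report


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the per-SNP mean dosage over nonmissing calls."""
    dos = G.dosages
    miss = np.isnan(dos)
    if not miss.any():
        return G.copy()
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = [G.snp_ids[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"SNPs with no nonmissing calls cannot be imputed: {bad}")
    col_mean = np.nanmean(dos, axis=0)
    out = G.copy()
    out.dosages = np.where(miss, col_mean[None, :], dos)
    return out


def pc_scores(G: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """Top-k principal component scores of the standardized dosage matrix.

    Columns are mutually orthogonal; the sign of each component is fixed so
    that its largest-magnitude score is positive, which makes the scores
    invariant (not merely sign-equivalent) to SNP ordering.
    """
    if np.isnan(G.dosages).any():
        raise ValueError("impute missing genotypes before PCA")
    if k > min(G.n_samples, G.n_snps):
        raise ValueError(f"k={k} exceeds min(n, p)")
    X = G.dosages
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("monomorphic SNPs present; run snp_qc first")
    Z = (X - X.mean(axis=0)) / sd
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    rank = int((S > S[0] * 1e-10).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = U[:, :k] * S[:k]
    for c in range(k):
        idx = np.argmax(np.abs(scores[:, c]))
        if scores[idx, c] < 0:
            scores[:, c] = -scores[:, c]
    return scores


def write_qc_report(report: QCReport, path: str) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)
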