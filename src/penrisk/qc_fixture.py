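"""A small synthetic genotype panel with one planted violation per QC rule.

Entirely constructed (not sampled from any cohort): 20 SNPs x 24 samples
with deterministically placed genotypes such that exactly

* ``snp_hwe``     fails the Hardy-Weinberg exact test at p < 1e-6 (a
  balanced no-heterozygote configuration; 24 is the smallest even sample
  count at which the exact test can reach that threshold),
* ``snp_lowmaf``  fails MAF >= 0.01 (monomorphic),
* ``snp_lowcall`` fails the 95% genotype call rate (2 of 24 calls missing),
* ``bad_call``    (sample) falls below 95% call rate after SNP QC,
* ``bad_het``     (sample) exceeds 30% heterozygous calls,
* ``dup_b``       (sample) is an exact duplicate of ``dup_a`` (pairwise
  IBS = 1 > 0.8; the tie in call rate removes the later sample),

and nothing else trips any filter.  Used to demonstrate and test filter
threshold fidelity.
"""

from __future__ import annotations

import numpy as np

from .types import GenotypeMatrix
from . import io_qc  # noqa: F401  (documentation cross-reference)

N_SAMPLES = 24
N_CLEAN_SNPS = 17

SAMPLE_NAMES = (
    ["bad_call", "bad_het", "dup_a", "dup_b"] + [f"ok{i}" for i in range(N_SAMPLES - 4)]
)

EXPECTED_SNP_REMOVALS = {"snp_hwe": "hwe", "snp_lowmaf": "maf", "snp_lowcall": "call_rate"}
EXPECTED_SAMPLE_REMOVALS = {
    "bad_call": "call_rate",
    "bad_het": "heterozygosity",
    "dup_b": "relatedness",
}


def planted_qc_fixture() -> GenotypeMatrix:
    """Build the 20-SNP x 24-sample panel described in the module docstring."""
    import pandas as pd

    rng = np.random.default_rng(20240101)
    n = N_SAMPLES
    pool = np.arange(4, n)  # samples free of planted violations
    cols: list[np.ndarray] = []
    ids: list[str] = []

    # --- planted bad SNPs -------------------------------------------------
    hwe_col = np.r_[np.zeros(12), np.full(12, 2.0)]
    cols.append(hwe_col)
    ids.append("snp_hwe")

    cols.append(np.zeros(n))
    ids.append("snp_lowmaf")

    lowcall = np.zeros(n)
    het_pick = rng.choice(pool, 6, replace=False)
    lowcall[het_pick] = 1.0
    lowcall[pool[-1]] = 2.0
    lowcall[[4, 5]] = np.nan  # 22/24 = 91.7% < 95%
    cols.append(lowcall)
    ids.append("snp_lowcall")

    # --- clean SNPs with planted sample-level violations ------------------
    # each clean column: 6 heterozygotes, 8 homozygote-minor, 10 zeros.
    # The mild heterozygote deficit keeps every sample's heterozygosity
    # under 30% while the high minor-allele load keeps background pairwise
    # IBS well below the 0.8 relatedness cut even with only 17 markers
    # (exact-test HWE p for a 10/6/8 column is ~0.017, far above 1e-6).
    dup_cols = {0, 2, 4, 6, 8}          # dup_a/dup_b heterozygous here (5 hets)
    bad_het_cols = {1, 3, 5, 7, 9, 11}  # bad_het heterozygous here (6 > 30%)
    pool_het = {int(s): 0 for s in pool}
    pool_two = {0: 0, **{int(s): 0 for s in pool}}
    for c in range(N_CLEAN_SNPS):
        col = np.zeros(n)
        hets: list[int] = []
        if c in dup_cols:
            hets += [2, 3]
        if c in bad_het_cols:
            hets.append(1)
        # fill remaining het slots from the least-used pool samples,
        # shuffled for tie-breaking so no two pool rows coincide
        order = sorted(pool_het, key=lambda s: (pool_het[s], rng.random()))
        for s in order:
            if len(hets) >= 6:
                break
            if pool_het[s] >= 5:
                continue
            hets.append(s)
            pool_het[s] += 1
        col[hets] = 1.0
        # homozygote-minor slots among bad_call + unused pool samples
        cand = [s for s in pool_two if col[s] == 0.0]
        cand.sort(key=lambda s: (pool_two[s], rng.random()))
        for s in cand[:8]:
            col[s] = 2.0
            pool_two[s] += 1
        cols.append(col)
        ids.append(f"snp_clean{c}")

    dos = np.column_stack(cols)
    # duplicate pair: identical across all SNPs
    dos[3] = dos[2]
    # bad_call: one missing clean call -> 16/17 = 94.1% < 95% after SNP QC
    dos[0, 3 + N_CLEAN_SNPS - 1] = np.nan

    meta = pd.DataFrame(
        {
            "id": ids,
            "chrom": 1,
            "pos": np.arange(1, len(ids) + 1) * 100,
            "allele1": "A",
            "allele2": "G",
        }
    )
    return GenotypeMatrix(list(SAMPLE_NAMES), meta, dos)
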