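"""Run the SNP and sample QC filters on a panel with planted violations.

The fixture plants exactly one violation of each rule: a Hardy-Weinberg
failure (exact-test p < 1e-6), a monomorphic SNP (MAF < 1%), a SNP with
call rate < 95%, a sample with call rate < 95%, a sample with > 30%
heterozygous calls, and a duplicated sample (pairwise IBS > 0.8).  The
report should list those six removals and nothing else.
"""

from penrisk.io_qc import impute_missing, pc_scores, sample_qc, snp_qc
from penrisk.qc_fixture import planted_qc_fixture

G = planted_qc_fixture()
print(f"input: {G.n_samples} samples x {G.n_snps} SNPs")

G, snp_report = snp_qc(G, hwe_thr=1e-6, call_thr=0.95, maf_thr=0.01)
for snp_id, reason in snp_report.removed_snps:
    print(f"  removed SNP    {snp_id:12s} reason: {reason}")

G, sample_report = sample_qc(G, call_thr=0.95, het_thr=0.30, ibs_thr=0.8)
for sid, reason in sample_report.removed_samples:
    print(f"  removed sample {sid:12s} reason: {reason}")

G = impute_missing(G)
scores = pc_scores(G, k=2)
print(f"retained: {G.n_samples} samples x {G.n_snps} SNPs, no missing calls")
print(f"top-2 PC scores span: PC1 sd={scores[:,0].std():.2f}, PC2 sd={scores[:,1].std():.2f}")
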