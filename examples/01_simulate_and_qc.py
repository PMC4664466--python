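"""Generate a study-scale synthetic cohort and apply the SNP QC filters.

The generator emulates a 384-SNP candidate-gene panel typed in 226 cases
and 575 controls, with 25 low-call-rate SNPs and 14 Hardy-Weinberg
violators planted so the exclusion stage has real work to do.
"""

from mdrpipe import filter_snps, simulate, study_config

gm, pheno, truth = simulate(study_config(seed=1))
print(f"simulated {gm.n_samples} samples x {gm.n_snps} SNPs "
      f"({pheno.n_cases} cases / {pheno.n_controls} controls)")

kept, records = filter_snps(gm, status=pheno.status)
by_reason = {}
for r in records:
    if r.excluded:
        by_reason[r.reason] = by_reason.get(r.reason, 0) + 1

print(f"QC kept {kept.n_snps} SNPs; excluded {sum(by_reason.values())} "
      f"({by_reason.get('call_rate', 0)} for call rate < 90%, "
      f"{by_reason.get('hwe', 0)} for HWE p <= 0.001 in controls)")
print("planted low-call SNPs :", len(truth["low_call_rate_snps"]))
print("planted HWE violators :", len(truth["hwe_violator_snps"]))
# The kept count is the size of the panel entering association analysis;
# with the planted failure structure it lands at (or within one SNP of) 345.
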