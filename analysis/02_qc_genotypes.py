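"""Quality-control the genotyped cohorts: mask to the study's genotyped
sets (G1 hybrids, the G2 parents, pure-species uncles, and the seedling
sample of G2), inject realistic missingness, filter SNPs/samples, impute
by expected B-allele dosage and verify recorded parentage.
"""

import json

from common import CONFIG, RESULTS, load_program

from rrsgs import verify_parentage
from rrsgs.pipeline import define_cohorts, qc_genotypes

program = load_program()
cohorts = define_cohorts(program, CONFIG)
genotypes = qc_genotypes(program, cohorts, CONFIG)

genotypes.write_csv(RESULTS / "genotypes_qc.csv")
with open(RESULTS / "cohorts.json", "w") as fh:
    json.dump({k: list(v) for k, v in cohorts.items()}, fh, indent=2)

report = verify_parentage(genotypes, program.pedigree_true, max_conflict_rate=0.01)

print(f"genotyped cohorts: H={len(cohorts['H'])}, P={len(cohorts['P'])}, "
      f"U={len(cohorts['U'])}, G2 candidates={len(cohorts['candidates_genotyped'])}")
print(f"after QC: {genotypes.n_individuals} samples x {genotypes.n_snps} SNPs "
      f"(call-rate >= {CONFIG.min_snp_call_rate}, MAF >= {CONFIG.min_maf}, imputed)")
print(f"parentage check: {len(report.table)} genotyped parent-offspring pairs, "
      f"{int(report.table['flagged'].sum())} flagged, {len(report.skipped)} skipped "
      "(ungenotyped parent)")
report.table.to_csv(RESULTS / "parentage_check.csv", index=False)
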