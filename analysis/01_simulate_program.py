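"""Simulate the synthetic RRS breeding program (G0 founders -> G1 pure
species + hybrids -> G2 hybrid candidates) and its field measurements.

Writes pedigrees, genotypes, ground-truth genetic values and the two-age
phenotype table.
"""

from common import CONFIG, RESULTS, load_program

from rrsgs import simulate_phenotypes

program = load_program()
phenos = simulate_phenotypes(program, seed=CONFIG.stage_seed("phenotypes"))

outdir = RESULTS / "simulated"
program.write(outdir)
phenos.to_csv(RESULTS / "phenotypes.csv", index=False)

truth = program.truth
print(f"simulated {len(program.pedigree)} individuals "
      f"({(truth.generation == 'G0').sum()} G0, "
      f"{(truth.generation == 'G1').sum()} G1, "
      f"{(truth.generation == 'G2').sum()} G2) "
      f"with {program.genotypes.n_snps} SNPs")
print(f"{len(phenos)} volume measurements at nominal ages "
      f"{sorted(phenos.nominal_age.unique())} across {phenos.trial.nunique()} trials")
print(f"-> {outdir} and {RESULTS / 'phenotypes.csv'}")
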