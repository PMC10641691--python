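"""Shared configuration for the numbered analysis scripts.

The analysis runs on one desk-scale synthetic breeding program (the
generator is deterministic, so later scripts re-derive the program from
the seed instead of deserializing it) and writes every table under
results/analysis/.
"""

from pathlib import Path

from rrsgs import PipelineConfig, SimulationConfig, simulate_breeding_program

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

CONFIG = PipelineConfig(
    simulation=SimulationConfig(
        n_founders_per_species=30,
        n_snps=2000,
        n_psp_families_per_species=30,
        offspring_per_family=25,
        n_hybrid_families_g1=8,
        n_hybrid_families_g2=14,
        offspring_per_family_g2=30,
        n_parents_g2_per_species=9,
        seed=20240,
    ),
    models=("gblup", "gblup-gd", "hblup"),
    training_combos=("H", "P", "U", "H+P", "H+U", "P+U", "H+P+U"),
    genotyped_fraction_g2=0.50,
    n_uncles_per_species=40,
    uncles_unrelated=True,
    seed=20240,
)


def load_program():
    """Re-derive the analysis program deterministically from the config."""
    return simulate_breeding_program(CONFIG.simulation)
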