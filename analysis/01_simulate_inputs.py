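"""Generate the synthetic study inputs every later step consumes.

Emits, under results/inputs/: an aligned 16S-like FASTA (7 genera, 12
species, 20 strains plus an outgroup), an MGF of MS/MS feature spectra (5
planted families of 6 analogs plus 10 noise features) with its
feature-quantification table and sample-to-genus map, an OD620 plate CSV,
and the truth tables that later steps score themselves against.
"""

from pathlib import Path

from cyanoprospect.synthetic_data import (
    PlateSimConfig,
    SimulationConfig,
    simulate_bundle,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]

# a Table-2-like screen: one strongly active extract, one borderline-active,
# the rest moderate against the marine pathogen
PLANTED_INHIBITION = {
    ("PMC_A", "E_coli"): 100.0,
    ("PMC_A", "P_atlantica"): 35.0,
    ("PMC_B", "E_coli"): 5.0,
    ("PMC_B", "P_atlantica"): 54.0,
    ("PMC_C", "E_coli"): 10.0,
    ("PMC_C", "P_atlantica"): 48.0,
}


def main() -> None:
    cfg = SimulationConfig(
        seed=SEED,
        plates=PlateSimConfig(true_inhibition=PLANTED_INHIBITION),
    )
    outdir = ROOT / "results" / "inputs"
    paths = simulate_bundle(cfg, outdir)
    print(f"synthetic study inputs written to {outdir} (seed {SEED}):")
    for name, path in paths.items():
        print(f"  {name:13s} {path.name}")


if __name__ == "__main__":
    main()
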