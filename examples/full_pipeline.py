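"""Full simulate -> fit -> assign pipeline on a small synthetic dataset.

Runs both arms end to end: elastic scans to force constants, and an HDX-MS
dataset (overlapping digested peptides of the N-terminal third of the apoA-I
fixture, bimodal 2:1 dimer/monomer mixture with back exchange) through
deconvolution, kinetic fitting, pooling and residue-level assignment.  All
outputs land in ./pipeline_demo/.
"""

import json
import warnings
from pathlib import Path

from lipodyn.io import RunConfig
from lipodyn.pipeline import run_pipeline
from lipodyn.simulate import apoa1_sequence

demo = Path("pipeline_demo")
demo.mkdir(exist_ok=True)
fasta = demo / "apoa1_nterm.fasta"
fasta.write_text(">apoA-I_1-80\n" + apoa1_sequence()[:80] + "\n")

config = RunConfig(
    out_dir=str(demo),
    seed=17,
    sequence_fasta=str(fasta),
    n_peptides=12,
    dimer_pf=100.0,   # helical-dimer-like protection
    monomer_pf=2.0,   # near-random-coil hairpin
    dimer_weight=2 / 3,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # conflict warnings summarized below
    out = run_pipeline(config)

print(f"outputs in {out}/:")
for f in sorted(out.iterdir()):
    print(f"  {f.name}")

report = json.loads((out / "fit_report.json").read_text())
print("\npeptide          bimodal  ratio   populations (Pf, class)")
for entry in report:
    pops = {
        label: [(round(ph["pf"], 1), ph["class"]) for ph in pop["phases"]]
        for label, pop in entry["populations"].items()
    }
    print(f"{entry['peptide']:<16} {str(entry['is_bimodal']):<8} "
          f"{entry['relative_abundance']:.2f}   {pops}")
# bimodal peptides show a slow population near the generated dimer protection
# (Pf ~ 100, orange/green) and a fast one near the monomer value (Pf ~ 2, red),
# at an abundance ratio near 0.5.
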