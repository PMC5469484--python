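"""Run the whole pipeline and walk the candidate-target funnel.

Executes every stage on a simulated dataset — anchors, matrices,
clustering per mark and condition, cluster matching, TF peak assignment,
summit E-box scanning and expression integration — then prints the nested
funnel from the stable cluster-1 core down to the candidate directly
repressed TF targets, and compares the final set with the planted truth.
"""

import tempfile

from profileclust import PipelineConfig, PipelineInputs, run_pipeline
from profileclust.synthetic_data import simulate_dataset

with tempfile.TemporaryDirectory() as tmp:
    ds = simulate_dataset(tmp, seed=17)
    result = run_pipeline(PipelineInputs.from_simulation(ds.outdir), PipelineConfig(seed=17))

    f = result.funnel
    print("genes with stable cluster-1 profiles in both marks and conditions:",
          f["stable_core"])
    print("  of these, gaining a TF peak upon differentiation:", f["gain"])
    print("    of these, differentially expressed (FC >= 2):  ", f["gain_de"])
    print("      of these, down-regulated:                    ", f["gain_de_down"])
    print("        of these, preferred E-box (CAGCTG) at the summit:",
          f["gain_de_down_preferred"])
    print("final candidate repressed targets:", ", ".join(f["final_genes"]))
    planted = set(ds.truth["repressed_targets"])
    final = set(f["final_genes"])
    print(f"planted truth recovered: {final == planted} "
          f"({len(final & planted)}/{len(planted)} targets)")
    for cond, table in result.binding_tables.items():
        row = table[table.cluster == 1].iloc[0]
        print(f"{cond}: {row.percent_bound:.0f}% of common cluster-1 genes TF-bound "
              f"(two-sided Fisher p = {row.p_value:.2g} vs all other clusters)")
    print("the funnel is monotone by construction; each line filters the one above.")
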