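"""Full per-pair analysis of a toy dimer with designed binding modes.

Generates a two-chain model whose interface contains one ordered block
and one coil-to-order block, writes every input file to disk (mmCIF,
PAE JSON, DSSP records), re-reads them through the pipeline, and prints
the confidence summary and per-region mode flags.
"""

import tempfile

from ppimodes import InterfaceBlock, ToyDimerSpec, make_toy_dimer
from ppimodes.pipeline import run_pair_from_files
from ppimodes.config import PipelineConfig

spec = ToyDimerSpec(
    len_a=160, len_b=160,
    interface_blocks=[
        InterfaceBlock((20, 45), (20, 45), "ordered"),
        InterfaceBlock((70, 96), (70, 96), "coil_to_order"),
    ],
    seed=7)
dimer = make_toy_dimer(spec)

with tempfile.TemporaryDirectory() as tmp:
    paths = dimer.write_fixture(tmp)
    record = run_pair_from_files(
        {"pair_id": "demo", "protein_a": "protA", "protein_b": "protB",
         "iptm": 0.85, **paths},
        PipelineConfig())

c = record.confidence
print(f"pDockQ               {c.pdockq:.3f}")
print(f"interface contacts   {c.n_if_contacts} (Cb-Cb <= 8 A)")
print(f"mean interface pLDDT {c.mean_if_plddt:.1f}")
print(f"min inter-chain PAE  {c.min_interchain_pae:.1f} A")
print(f"confidence tier      {c.tier}")
print()
for ann in record.regions_a:
    span = f"{ann.region.span.start}-{ann.region.span.end}"
    p = "" if ann.fisher_p is None else f"  Fisher p = {ann.fisher_p:.2e}"
    print(f"chain A interface {span}: {sorted(ann.flags)}{p}")
print("PPI-level modes:", sorted(record.modes.flags))

# The 70-96 interface is coil in the monomer and strand in the complex;
# the one-sided Fisher test on its helix+strand counts flags the
# disorder-to-order transition, while the 20-45 interface stays ordered.
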