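"""Gold-standard label construction from an interactome table.

Generates a synthetic world, writes its interactome in the standard TSV
dialect, reads it back, and builds the kinase-substrate (KS) and
substrate-substrate (SS) label matrices used for evaluation.
"""

import io

from phosphonet import gold_networks as gn
from phosphonet import synthetic_phospho as sp

world = sp.generate_world(n_kinases=4, n_substrates_per_kinase=6, n_background=8, seed=1)

buf = io.StringIO()
world.interactome_frame().to_csv(buf, sep="\t", index=False)
buf.seek(0)
print("interactome head:")
print("\n".join(buf.getvalue().splitlines()[:4]), "\n")

records = gn.read_interactome(world.interactome_frame())
print(f"{len(records)} kinase->substrate records\n")

ks = gn.build_ks_labels(records, world.sites, world.kinase_classes())
print(f"KS labels: {ks.labels.shape[0]} kinase-site rows x {ks.labels.shape[1]} site columns")
print(f"  positives {ks.n_positive}, negatives {ks.n_negative} "
      "(residue-class mismatches and self pairs are NA)\n")

ss = gn.build_ss_labels(records, world.sites)
print(f"SS labels: {ss.labels.shape[0]} S/T sites, symmetric")
print(f"  positive pairs (shared kinase): {ss.n_positive // 2}")
print("  each kinase's m substrates contribute C(m,2) positive pairs.")
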