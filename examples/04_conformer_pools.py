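"""Conformer pools: a tethered domain and a melted hinge.

Starting from a compact six-domain template, generates (a) a pool where
the N-terminal domain swings on its 15-residue linker and (b) a pool where
an interior hinge is melted so the whole regulatory block swings.  The Rg
distributions show how each kind of flexibility broadens the accessible
conformational space.
"""

import numpy as np

from confensa import (AssemblySpec, build_pool, make_toy_multidomain,
                      radius_of_gyration)

template, dmap = make_toy_multidomain(packing="closed", seed=3)
n_res = int(template.residue_numbers.max())
print(f"template: {n_res} residues, Rg = {radius_of_gyration(template):.1f} A")
print(f"domains: { {k: v for k, v in dmap.domains.items()} }")

lo, hi = dmap.flexible[0]           # the N-terminal tether
tether = AssemblySpec(rigid_bodies={"NTD": [(1, lo - 1)],
                                    "core": [(hi + 1, n_res)]},
                      flexible_segments=[(lo, hi)])
pool = build_pool(template, tether, n_members=300, seed=1,
                  template_id="tethered-NTD")
print(f"tethered-NTD pool: Rg {pool.rg_values.mean():.1f} "
      f"+- {pool.rg_values.std():.1f} A "
      f"(range {pool.rg_values.min():.1f}-{pool.rg_values.max():.1f})")

h_lo, h_hi = dmap.flexible[1]       # the hinge
hinge = AssemblySpec(rigid_bodies={"regulatory": [(1, h_lo - 1)],
                                   "catalytic": [(h_hi + 1, n_res)]},
                     flexible_segments=[(h_lo, h_hi)])
pool_h = build_pool(template, hinge, n_members=300, seed=2,
                    template_id="melted-hinge")
print(f"melted-hinge pool: Rg {pool_h.rg_values.mean():.1f} "
      f"+- {pool_h.rg_values.std():.1f} A "
      f"(range {pool_h.rg_values.min():.1f}-{pool_h.rg_values.max():.1f})")
print("The hinge melt reaches far more extended shapes than the local")
print("domain tether — the structural signature that ensemble selection")
print("uses to tell the two kinds of states apart.")
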