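"""Side-chain switch experiment: set the inactive state's switch residue
to its active-state rotamer and compare the two activation profiles.

In the toy, one tryptophan flips from a membrane-parallel ("flattened")
orientation to a membrane-normal ("vertical") one upon activation —
the same kind of discrete rotamer switch that tunes activation
barriers in chemokine receptors.  Transferring the active rotamer onto
the inactive endpoint and re-running the pipeline shows how much of
the conformational work that side chain accounts for.
"""

from cgpathway import (
    EnergyParams,
    MorphConfig,
    MutationSpec,
    make_toy_two_state,
    set_sidechain_from_reference,
)
from cgpathway.perturb import run_pipeline

toy = make_toy_two_state(n_res=60, hinge_angle=15.0, seed=1)
chain, resnum, icode = toy.switch_residue
site = MutationSpec(chain, resnum, icode,
                    mode="ROTAMER_FROM_REFERENCE", reference_label="active")

params, cfg = EnergyParams(), MorphConfig(seed=0)
_, prof_wt, rep_wt = run_pipeline(toy.inactive, toy.active, params, cfg)

switched = set_sidechain_from_reference(toy.inactive, site, toy.active)
_, prof_sw, rep_sw = run_pipeline(switched, toy.active, params, cfg)

print(f"switch residue            : {toy.switch_residue} (TRP)")
print(f"wild-type barriers        : {rep_wt.barriers}")
print(f"switched-start barriers   : {rep_sw.barriers}")
print(f"endpoint G difference     : "
      f"{prof_sw.G[-1] - prof_wt.G[-1]:+.3f} kcal/mol")

# Matched-rank barrier differences (switched − WT) quantify how much
# pre-forming the active rotamer flattens the activation landscape.
if rep_wt.barriers:
    for (wt_label, wt_b), (_, sw_b) in zip(
        rep_wt.barriers.items(), rep_sw.barriers.items()
    ):
        print(f"{wt_label}: {sw_b - wt_b:+.3f} kcal/mol (switched - WT)")
else:
    # the toy's landscape is barrier-free on this surrogate energy; the
    # switch still registers as a start-state (and endpoint-G) shift
    print("no transition states above the prominence threshold; the "
          "rotamer's effect shows up as the endpoint G difference above")
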