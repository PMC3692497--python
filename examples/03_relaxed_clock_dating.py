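"""Date the chondrichthyan splits on a simulated 12-species dataset.

Rebuilds the study layout (four tetrapods, three teleosts, three
chondrichthyans, two outgroups; 19 fossil constraints at 11 nodes),
simulates a 2000-site alignment on the truth timetree, and runs the
independent-rates relaxed-clock MCMC in approximate-likelihood mode.
"""

from chondroclock import (
    ChainSettings,
    DatingModel,
    fit_branch_length_approximation,
    make_vertebrate_scenario,
    run_mcmc,
    summarize_trace,
)

timetree, calibrations, alignment, scenario = make_vertebrate_scenario(
    "I", n_sites=2000, seed=3
)
approx = fit_branch_length_approximation(timetree, alignment, scenario.model)
dm = DatingModel(timetree, calibrations, model=scenario.model)
trace = run_mcmc(
    alignment, dm, branch_approx=approx,
    settings=ChainSettings(burn_in=5000, sample_every=2, n_samples=20_000, seed=11),
)
summary = summarize_trace(trace)
truth = {n.name: n.age for n in timetree.postorder() if not n.is_tip}

print("node  truth   posterior mean   95% CI")
for _, row in summary.nodes.iterrows():
    print(
        f"{row['node']:>4}  {truth[row['node']]:5.0f}   "
        f"{row['mean_Ma']:8.0f} Ma     [{row['ci_low_Ma']:.0f}, {row['ci_high_Ma']:.0f}]"
    )
print(
    "\nn10 is the chimaera-elasmobranch split and n11 the shark-ray split;"
    "\nboth are constrained only by hard lower bounds, so their posteriors"
    "\nare driven by the sequence data and the surrounding soft calibrations."
)
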