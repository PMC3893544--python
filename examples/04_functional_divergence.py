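"""Estimate type-I functional divergence between two duplicate clades.

Simulates a two-cluster protein alignment in which half the sites have
independent evolutionary rates in the two clusters (theta = 0.5), counts
per-site substitutions by Fitch parsimony on each cluster tree, and fits
the Poisson-gamma mixture to recover theta1 with an LRT and per-site
posteriors.
"""

from hgtkit import divergence as dv, synth
from hgtkit.io import read_newick


def ladder(labels, tbl=0.1, ibl=0.04):
    n = f"({labels[0]}:{tbl},{labels[1]}:{tbl})"
    for l in labels[2:]:
        n = f"({n}:{ibl},{l}:{tbl})"
    return read_newick(n + ";")


t1 = ladder([f"a{i}" for i in range(24)])
t2 = ladder([f"b{i}" for i in range(24)])
msa, truth = synth.simulate_divergence_alignment(t1, t2, theta_true=0.5,
                                                 alpha=0.5, n_sites=1000, seed=0)
counts = dv.count_substitutions(msa, t1, t2)
res = dv.estimate_theta1(counts)
print(f"theta1 = {res.theta1:.4f} +- {res.se_theta1:.4f} "
      f"(truth 0.5; planted fraction {truth.mean():.3f})")
print(f"LRT = {res.lrt:.2f}, p = {res.p_value:.3g} (chi-square, 1 df)")
sites = dv.divergent_sites(res, cutoff=0.7)
print(f"{len(sites)} sites with posterior > 0.7; top 5: "
      f"{[(c, round(p, 3)) for c, p in sites[:5]]}")
# theta1 near 0.5 with a large LRT means the rate constraints of a
# substantial fraction of sites shifted between the two clades after
# duplication - the type-I divergence signature.
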