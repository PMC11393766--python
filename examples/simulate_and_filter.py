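"""Simulate a synthetic ddRAD dataset under the six-taxon island model and
apply the standard site filters.

Prints how many of the simulated loci are variable, how missingness thins
the genotype calls, and how many sites survive the genotyping-rate /
minor-allele-count / heterozygosity filters.
"""

from demosfs import catalog, coalsim
from demosfs.sfs import FilterConfig, filter_sites

model = catalog.model_e1()
print(f"model {model.name}: {len(model.populations)} demes, "
      f"{sum(e.kind == 'divergence' for e in model.events)} divergence events")

g = coalsim.simulate_genotypes(model, n_sites=5000, seed=42)
n_var = sum(s.is_variable for s in g.sites)
print(f"simulated {g.n_sites} loci x {g.n_individuals} diploids; "
      f"{n_var} variable ({n_var / g.n_sites:.1%})")

g_miss = coalsim.apply_missingness(g, rate=0.15, seed=7)
miss = (g_miss.genotypes == coalsim.MISSING).mean()
print(f"after knockout: {miss:.1%} of genotype calls missing")

cfg = FilterConfig(r=0.8, p=6, min_mac=1, max_obs_het=0.5)
kept = filter_sites(g_miss, cfg)
print(f"filters (-r {cfg.r} -p {cfg.p} --min-mac {cfg.min_mac} "
      f"--max-obs-het {cfg.max_obs_het}): {kept.n_sites} sites kept")
print("a kept site is genotyped in >=80% of each deme, polymorphic, and not")
print("heterozygote-excessive — the SNP set demographic inference runs on.")
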