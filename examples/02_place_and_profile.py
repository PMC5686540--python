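"""Filter, place and profile metagenomic protein reads.

Simulates a community in which the focal genus makes up 7.8% of the
bacteria, pushes reads through the BLASTP-style and profile-HMM-style
filters, places survivors on the reference tree, and reports genus-level
relative abundances plus the sub-OTU clade breakdown.
"""

from microdiv import pipeline, profiler, simdata

cfg = simdata.UniverseConfig(n_phyla=2, genera_per_phylum=3, genomes_per_genus=3,
                             n_markers=5, marker_len=120, focal_clades=6, seed=42)
universe = simdata.simulate_universe(cfg)
build = pipeline.build_reference(universe, seed=42)

focal = universe.focal_ids
background = [g for g in universe.genome_ids if g not in set(focal)]
composition = {g: 0.078 / len(focal) for g in focal}
composition.update({g: 0.922 / len(background) for g in background})

reads, truth = simdata.simulate_reads(universe, composition, n_reads=2000,
                                      read_len=60, decoy_frac=0.05, seed=1)
result = pipeline.place_sample(build, reads, "S1", seed=42)
print(f"{result.n_reads} reads -> {result.n_stage1} pass stage 1 (E<=1e-5) "
      f"-> {result.n_stage2} pass stage 2 (E<=1e-10)")

ba = pipeline.branch_abundance(build, [result])
profile = profiler.classify_mass(ba, "genus")
print("\ngenus-level relative abundance (sums to 1 incl. unclassified):")
print(profile.data["S1"].round(4).to_string())
print(f"\nsimulated focal abundance was 7.8%; recovered "
      f"{100 * profile.data.loc[simdata.FOCAL_GENUS, 'S1']:.2f}%")

clades, failed = profiler.bin_clades(ba, simdata.FOCAL_GENUS)
print("\nwithin-genus clade composition of the focal OTU:")
print(clades.data["S1"].round(4).to_string())
print(f"fraction of genus reads without clade consensus: {failed['S1']:.4f}")
# The clade rows show microdiversity the 16S OTU alone cannot resolve:
# all six lineages sit inside one 97% OTU yet are separable by placement.
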