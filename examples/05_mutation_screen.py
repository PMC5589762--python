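"""Point-mutation ΔΔG screen on the planted benchmark.

Each substitution is evaluated by rotamer-repacking four arms (mutant and
wild type, in the complex and in the histone dimer alone) with paired
seeds; ΔΔG = (ΔG_complex,mut − ΔG_dimer,mut) − (ΔG_complex,wt − ΔG_dimer,wt).
Positive ΔΔG is destabilising.  The benchmark plants one site that must
clash with the chaperone when enlarged and one distal null site.
"""

from czbkit import (
    AnnealSchedule,
    Mutation,
    RepackParams,
    ddg_of_mutation,
    make_ddg_benchmark,
    wt_noise_floor,
)

centroids, (clash, distal) = make_ddg_benchmark(seed=0)
print(f"benchmark: {len(centroids)} centroid copies")
print(f"  planted clash site:  {clash.chain_id}{clash.res_seq} "
      f"({clash.res_name} -> {clash.to_res}, expected ΔΔG > 0)")
print(f"  distal control site: {distal.chain_id}{distal.res_seq} "
      f"({distal.res_name} -> {distal.to_res}, expected ΔΔG ≈ 0)")

params = RepackParams(schedule=AnnealSchedule(sweeps=80))
rec = ddg_of_mutation(
    centroids,
    Mutation(clash.chain_id, clash.res_seq, clash.res_name, clash.to_res),
    n_runs=5, seed=1, params=params,
)
print(f"clash ΔΔG = {rec.ddg_mean:.2f} ± {rec.ddg_sem:.2f} "
      f"(surrogate units; {rec.values.size} runs pooled)")

rec_d = ddg_of_mutation(
    centroids,
    Mutation(distal.chain_id, distal.res_seq, distal.res_name, distal.to_res),
    n_runs=5, seed=1, params=params,
)
noise = wt_noise_floor(
    centroids, (clash.chain_id, clash.res_seq),
    n_runs=5, seed=2, params=params, paired=False,
)
print(f"distal ΔΔG = {rec_d.ddg_mean:.3f} "
      f"(WT-replicate noise floor SD {noise.std():.3f})")
print("positive ΔΔG at the clash site and a null distal control confirm "
      "the screen ranks interface-disrupting substitutions first")
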