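"""The whole study in one run: scan, regions, GWAS, overlap.

Simulates the default two-population design (sweep at chr1:2.5 Mb, causal
SNP at the swept locus), runs QC -> CLR + F_ST -> CSR/CASR calling, then
the LOCO mixed-model GWAS, and joins significant SNPs against the candidate
artificial-selection regions.  Expect one CASR covering the sweep and the
causal SNP listed in the overlap table.
"""

from sweepscan import RunConfig, SimConfig, run_gwas, run_scan

cfg = RunConfig(sim=SimConfig(), seed=1)
scan = run_scan(cfg, "scratch/example_pipeline")
gwas = run_gwas(cfg, "scratch/example_pipeline", casrs=scan["casrs"])

truth = scan["truth"]
print(f"true sweep             : {truth['sweep_chrom']}:{truth['sweep_position_bp']}")
print(f"true causal SNP        : {truth['causal_chrom'][0]}:{truth['causal_pos'][0]}")
print("CASRs                  :", [(r.chrom, r.start, r.end) for r in scan["casrs"]])
print(f"M_eff / threshold      : {gwas['m_eff']} / {gwas['threshold']:.3g}")
print("significant SNPs       :")
print(gwas["hits"][["chrom", "pos", "beta", "se", "wald_p"]].to_string(index=False))
print("CASR-hit overlap table :")
print(gwas["overlap"].to_string(index=False))
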