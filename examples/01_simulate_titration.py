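"""Simulate a cell-mixture titration with known tumor fractions.

Two virtual breast-cancer-like cell lines (length-weighted mean copy number
2.65 and 4.2) are mixed with diploid cells at tumor fractions 0-1 in three
replicates, and low-pass WGS read counts are drawn per 1 Mb bin.
"""

from ctmtf.genome import build_genome_bins
from ctmtf.simulate import default_cell_lines, generate_titration_set

genome = build_genome_bins()
print(f"genome: {genome.n_bins} bins of {genome.window:,} bp "
      f"({genome.genome_length / 1e9:.2f} Gb, chr1-22+X)")

for line in default_cell_lines(genome):
    profile = line.profile
    gains = sum(s.call == "gain" for s in profile.segments)
    losses = sum(s.call == "loss" for s in profile.segments)
    print(f"{line.name}: mean copy {profile.mean_copy(genome):.3f} "
          f"(target {line.target_mean_copy}), {gains} gains / {losses} losses")

samples, truth = generate_titration_set(master_seed=1, genome=genome)
print(f"\n{len(samples)} titration samples "
      f"(2 lines x 10 tumor fractions x 3 replicates)")
print(truth.head(6).to_string(index=False))
print("\nEach row records the known mixing truth for one sample; the read")
print("counts sum exactly to total_reads (multinomial over bins weighted by")
print("bin length x mixture copy number).")
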