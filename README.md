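# mito-recomb

Repeat and recombination analysis for circular organelle genomes.

Seed plant mitochondrial genomes are structurally fluid: dispersed repeats
mediate intramolecular recombination that splits the circle into subgenomic
molecules (direct repeats) or inverts the intervening segment (inverted
repeats), and alternative genome configurations can persist *in vivo* at
very low stoichiometry. Assaying that activity by PCR is treacherous,
because PCR itself recombines templates across short regions of shared
sequence. `mito-recomb` packages the computational side of this analysis
for people studying organelle genome structure:

* **Repeat discovery** (`repeat_finder`) — seed-and-extend self-alignment
  of a circular genome (word size W, match/mismatch scores M/N, gap
  penalties Q/R), with Karlin–Altschul filtering
  `E = K·m·n·e^(−λS)` and an E ≤ 1 repeat cutoff.
* **Repeat statistics** (`repeat_stats`) — non-redundant coverage
  (positions in ≥1 repeat counted once, classified short `<1 kb` / large
  `≥1 kb` / short-within-large), unique begin–end coordinate counts, and
  the combinatorial bounds `k ≤ #coordinates ≤ k(k−1)` for a k-copy family.
* **Recombination geometry** (`recombination`) — for a direct repeat at
  starts s₁ < s₂ on a circle of length L, the two predicted subcircles of
  sizes `s₂−s₁` and `L−(s₂−s₁)`; for an inverted repeat, the inversion of
  the intervening segment; junction sequences, junction-specific PCR
  layouts, chimeric-read detection, and reference:recombinant read ratios.
* **PCR-recombination control** (`pcr_recomb`) — discovery of "surrogate
  repeats" (near-identical regions shared between two *different*
  genomes, uniquely flanked), prediction of the bi-species chimeric
  products only in-vitro recombination can create, and a seeded
  template-switching simulator reproducing the dependence of chimera
  formation on template concentration.
* **Partition accounting** (`partition_accounting`) — mutually exclusive
  classification of every genomic position (conserved syntenic,
  chloroplast-like, nuclear-like, mitochondrial-like, uncharacterized)
  whose counts sum exactly to L.
* **Synthetic data** (`synthetic_data`) — circular genomes with planted
  repeat pairs (length, identity, orientation), recombinant molecule
  pools at chosen abundance ratios, labelled shotgun read pools, and
  bi-species fixtures, all with machine-readable ground truth.

## Worked example

```python
from mito_recomb import (
    find_repeats, coverage_profile, predict_products,
    detect_chimeric_reads, quantify_configurations,
)
from mito_recomb.synthetic_data import (
    RepeatSpec, generate_genome, generate_recombinant_molecules, generate_reads,
)

specs = [
    RepeatSpec(length=175, identity=100.0, orientation="direct"),
    RepeatSpec(length=80, identity=93.0, orientation="inverted"),
]
genome, truth = generate_genome(L=20_000, specs=specs, seed=42)

for h in find_repeats(genome):
    print(f"{h.orientation:8s} {h.copy1}  {h.copy2}  len={h.aln_length} "
          f"id={h.identity:.1f}%  E={h.evalue:.2g}")

profile = coverage_profile(find_repeats(genome), genome.length)
print(f"non-redundant repeat coverage: {profile.percent_covered:.2f}%")

direct = truth.repeats[0].as_hit(genome.length)
cfg = predict_products(genome, direct, flank=200)
print("subgenomic circle sizes:", cfg.product_sizes, "sum:", sum(cfg.product_sizes))

pool = generate_recombinant_molecules(genome, truth, "rep1", ratio=(50, 1))
reads = generate_reads(pool, depth=1500, read_len=350, seed=7)
evidence = detect_chimeric_reads(reads, genome, [direct], min_anchor=20)
r = quantify_configurations(evidence, reads, genome, [direct])["rep1"]
print(f"reads: {len(reads)}  junction-spanning chimeras: {len(evidence)}")
print(f"reference:recombinant = {r.reference_reads}:{r.recombinant_reads} "
      f"(ratio {r.ratio:.0f}, planted 50)")
```

prints

```
inverted 828..907(+)  19825..19904(-)  len=80 id=92.5%  E=1.1e-25
direct   14681..14855(+)  17837..18011(+)  len=175 id=100.0%  E=1.1e-96
non-redundant repeat coverage: 2.55%
subgenomic circle sizes: [3156, 16844] sum: 20000
reads: 85819  junction-spanning chimeras: 28
reference:recombinant = 1146:28 (ratio 41, planted 50)
```

Both planted repeats come back with their exact coordinates, orientation
and realised identity (the 93 % request rounds to 6 substitutions in 80 nt,
i.e. 92.5 %). The two predicted subcircles conserve the genome length, and
at 1500× simulated coverage the planted 50:1 configuration ratio is
recovered within Poisson counting error (ratio estimate 41 from 28
junction-spanning reads).

A command-line interface mirrors the library
(`mito-recomb find-repeats|repeat-stats|predict|detect-chimeras|partition|surrogate-assay|simulate-pcr|synth`);
run any subcommand with `--help`.

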