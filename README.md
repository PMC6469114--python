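# hgtscan

Detection of endosymbiont-to-host horizontal gene transfer (HGT) in genome
assemblies, with the full evidence chain used to tell a genuine chromosomal
insertion from a chimeric mis-assembly.

## The problem

When an insect is sequenced together with an intracellular endosymbiont such
as *Wolbachia*, the assembly mixes both genomes. Most scaffolds separate
cleanly on a taxon-annotated GC-coverage (TAGC/blob) plane, but a scaffold
that carries *both* host- and symbiont-matching sequence admits two
explanations:

- a **horizontal transfer**: a symbiont fragment integrated into a host
  chromosome. It is replicated with the host, so read depth is continuous
  across its boundaries and matches the host depth regime;
- a **chimera**: an assembler artifact joining a host and a symbiont
  molecule. Each side keeps its source depth, so the depth track steps at
  the join.

With host depth $d_h$ and symbiont depth $d_s$ well separated (e.g. ~47×
vs ~120×), the junction statistic

$$r = \log_2\frac{\bar{d}_{\text{left}} + \varepsilon}{\bar{d}_{\text{right}} + \varepsilon}$$

over windows flanking each host/symbiont boundary separates the two:
$|r| \le \log_2 \tau$ (default $\tau = 1.5$) is consistent with insertion,
a step of $\log_2(d_s/d_h) \approx 1.35$ is not. Calls additionally require
corroboration by an independently produced assembly containing a contig
that spans the junction, and are annotated with transposase proximity,
overlapping genes, and transcription (FPKM).

The package is for researchers curating draft genomes of hosts with
intracellular symbionts: it reimplements, as a tested reusable pipeline,
the scaffold triage, insertion detection, chimera discrimination,
multi-strain evidence scoring, and assembly statistics such a curation
needs — exercised end-to-end on synthetic data with known truth.

## What is in the box

| module | role |
|---|---|
| `hgtscan.io` | FASTA/BLAST-tabular/GFF3/BED/TSV readers-writers; one internal 0-based half-open coordinate convention |
| `hgtscan.simulate` | host+symbiont genomes, planted insertions, depth-step chimeras, strain mixtures, shredded alternative assemblies, exact depth tracks, truth tables |
| `hgtscan.tagc` | GC, depth, taxon-coverage and the scaffold classifier (host / symbiont / hgt_candidate / unassigned) |
| `hgtscan.detect` | k-mer anchor-chaining aligner, candidate segmentation, junction depth test, cross-assembly corroboration, final calls |
| `hgtscan.strains` | duplicated / polymorphic single-copy genes, marker duplication, multi-strain flag, gene-set recovery |
| `hgtscan.stats` | N50/L50-family contiguity statistics, length-threshold accounting, fixed-point library totals |
| `hgtscan.cli` | `hgtscan simulate / classify / detect-hgt / strain-evidence / stats / pipeline` |

## Worked example

Simulate a study (1 Mb host at GC 0.36, 47.37×; 300 kb symbiont at GC
0.3513, 120×; three planted insertions of 0.5–20 kb; one chimera; one
shredded alternative assembly) and run the full analysis:

```python
from hgtscan import SimulationConfig, analyze, simulate_study

bundle = simulate_study(SimulationConfig(seed=1))
result = analyze(
    bundle.scaffolds, bundle.tracks, bundle.host_ref, bundle.symbiont_ref,
    bundle.alt_assemblies, bundle.features, bundle.fpkm,
)
for c in result.calls:
    print(c.scaffold_id, c.interval.start, c.interval.end, c.length,
          c.verdict, c.corroborations, c.transposase_distance, len(c.genes))
```

prints

```
chimera_1 30001 50000 19999 chimera_suspect 0 None 0
host_1 162746 166274 3528 hgt 1 465 0
host_2 240896 251612 10716 hgt 1 933 2
host_3 97642 115661 18019 hgt 1 1240 3
```

Reading this: the three planted insertions are recovered as `hgt` calls —
every junction depth ratio is inside the band (e.g. host_2's junctions show
log2 ratios 0.128 and −0.014), each call is corroborated by 1 alternative
assembly, and each sits within ~1 kb of an annotated transposase. The
constructed chimera is flagged `chimera_suspect`: its junction shows a
depth step (log2 ratio −1.57, i.e. ~47× against ~120×) and no alternative
contig spans the join. Against the truth table, the recovered boundaries
are exact to ≤ 1 bp on this seed. The classifier labels the 11 scaffolds
6 symbiont / 4 hgt_candidate / 1 host (the insertion-free host scaffold).

The same run from the shell:

```bash
hgtscan simulate --seed 1 --out bundle/
hgtscan pipeline --assembly bundle/assembly.fasta --depth bundle/depth.tsv \
    --host-ref bundle/host_ref.fasta --symbiont-ref bundle/symbiont_ref.fasta \
    --gff bundle/features.gff3 --fpkm bundle/fpkm.tsv \
    --alt bundle/alt_assembly_0.fasta --out results/ --plot
```

writes `classifications.tsv`, `calls.bed`, `calls.tsv`, `stats.json`,
`params.json` and the TAGC scatter `tagc.png`.

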