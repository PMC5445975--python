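# deldesign

Design engine for seamless CRISPR/Cas9 deletions in small genomes (built for
fission-yeast-style workflows). Given a genome FASTA and a target region —
by gene name (GFF3 or a simple TSV table) or by chromosome coordinates —
it produces:

1. **Ranked genome-unique sgRNAs.** The whole genome is scanned on both
   strands for 5'-NGG-3' PAM sites with a complete 20-nt spacer; a
   suffix-count database records, for each PAM-proximal suffix length
   k = 8, 10, …, 20, how many genomic spacers share it. Only spacers that
   are unique at full length (count 1 at k = 20) are offered, ranked by
   ascending similarity counts from k = 20 down to k = 8, with the 12-nt
   seed-uniqueness flag, the predicted blunt-cut site (3 bp upstream of the
   PAM), and the 10-nt PAM-proximal editable window annotated.
2. **sgRNA plasmid-cloning primers**, for inverse PCR of an expression
   plasmid, by two methods: a ligation method (spacer on the forward
   primer's 5' end) and a ligation-free method (spacer on both primers, in
   opposite orientation, so bacteria recircularize by homology). An
   in-silico assembly checker verifies that the reconstructed circle equals
   leader + spacer + scaffold.
3. **HR-template primers.** The 160-nt homologous-recombination donor is
   the 80-nt flanks of the deletion joined together; two 100-nt primers
   (forward = template 5' end, reverse = reverse complement of the 3' end,
   40-nt physical overlap) synthesise it by overlap extension. A 20-nt
   overlap is treated as the enforced minimum; the actual overlap is
   reported.
4. **Deletion-checking primers.** The 250-nt flanks of the junction are
   joined and primers picked by a Tm-driven score (length 18–25 opt 20,
   Tm 57–63 opt 60 °C, GC 20–80 %, pair ΔTm ≤ 3 °C), reported with
   nearest-neighbor melting temperatures (SantaLucia 1998 unified tables,
   50 mM monovalent, 50 nM oligo) and predicted product sizes for the
   deleted and wild-type alleles (wild-type − deleted = deleted length).

The design pipeline is fully deterministic: identical invocations produce
byte-identical JSON.

## CLI

```sh
# full design, coordinates
deldesign design --genome genome.fa --chrom II --start 1500340 --end 1501528

# full design, gene name via GFF3 (or --genes-tsv id<TAB>chrom:start-end)
deldesign design --genome genome.fa --gff annotation.gff3 --gene cdc2

# prebuild / reuse the genome spacer index
deldesign index build --genome genome.fa --out genome.idx.jsonl
deldesign design --genome genome.fa --index genome.idx.jsonl --chrom I --start 100 --end 400

# candidate table only / checking primers only
deldesign sgrna --genome genome.fa --chrom I --start 100 --end 400
deldesign primers check --genome genome.fa --chrom I --start 100 --end 400
```

Useful flags on `design`: `--hr-flank`, `--hr-primer-len`, `--check-flank`,
`--top-n`, `--containment/--relaxed` (whether the spacer may overhang the
region), `--cloning-method {ligation,ligation_free,both}`,
`--plasmid FILE --insertion-point P --anneal-len N` (FASTA or GenBank;
without these a documented toy placeholder plasmid is used — supply the
real expression plasmid, e.g. Addgene #74215, for lab use),
`--format {json,tsv}`, `--config file.yaml` (YAML or `key=value` lines
mirroring the flags). Exit codes: 2 usage, 3 missing file, 4 malformed
input, 5 unknown gene, 6 infeasible primers.

Note: output DNA is uppercase; the order-sheet writer
(`deldesign.io_cli.order_sheet`) emits lowercase sequences.

## Library

```python
from deldesign import (GenomeSequence, index_genome, parse_region,
                       run_design)

genome = GenomeSequence.from_fasta("genome.fa")
region = parse_region("I", 1150, 1450, genome)
report = run_design(genome, region)
print(report.to_json())
```

`deldesign.fixtures` provides a seeded synthetic-genome generator with
exact truth tables (background is rejection-sampled so planted 20-mers
never recur by accident) and independent brute-force oracles used by the
test suite.

## Scope notes

Wet-lab protocol details (PCR programs, ligation recipes, transformation)
are out of scope; this package covers the computational design only. The
similarity profile is a suffix-share count, not a mismatch-tolerant
off-target score.
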