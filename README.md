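# tlpcensus

A genome-wide census toolkit for **thaumatin-like proteins** (TLPs, the
PR-5 family of pathogenesis-related proteins). Given protein sequences,
precomputed alignments, gene models and repeat annotations, it reproduces
the standard analysis chain used in TLP family surveys:

1. **Domain delimitation** — the thaumatin domain is located between the
   boundary motifs `N-x-C-x(3)-V/I-W` (N-terminal) and `Y-x-I/V-x-F-C-x`
   (C-terminal); gene models without a complete domain (both motifs,
   plausible length, enough cysteines) are excluded with per-criterion
   reasons.
2. **Architecture classification** — typical TLP (~215-aa domain,
   16 cysteines), small-TLP (~150 aa, 10 cysteines), TLP-kinase and
   small-TLP-kinase (~650-aa fusions with a C-terminal protein-kinase
   domain, detected via the glycine-loop / H-x-D / D-x-G anchor triad,
   plus Kyte–Doolittle transmembrane detection), and conservation scoring
   of the acidic-cleft **REDDD** residues with charge-preserving
   equivalences ({R,K}, {D,E}).
3. **Physicochemical descriptors** — average molecular weight and
   isoelectric point (Henderson–Hasselbalch bisection on the EMBOSS pKa
   table).
4. **Phylogeny** — p-distance with pairwise deletion, Poisson correction
   *d* = −ln(1 − *p*), Saitou–Nei Neighbour-Joining, seeded column
   bootstrap (default 1,000 replicates) with integer-percent supports in
   Newick output, and anchor-based clade assignment.
5. **Genomics** — tandem family-cluster detection on GFF3 gene models and
   transposable-element coverage/enrichment of cluster spans computed on
   interval unions.

A first-class synthetic-data module (`tlpcensus.synthetic_data`) generates
all of these inputs with recorded ground truth — TLP scaffolds per
architecture, alignments evolved under a 20-state uniform-jump substitution
process matched to the Poisson distance estimator, and tandem-array loci
with exact planted TE coverage — so the entire pipeline is testable without
any downloads.

## Worked example

Generate a synthetic census (38 typical TLPs + 4 TLP-kinases, mirroring a
poplar-sized family) together with a tandem-array locus, then run the full
pipeline:

```sh
tlpcensus simulate proteins --seed 11 --n-typical 38 --n-kinase 4 --out data
tlpcensus simulate locus --seed 11 --out data
awk -F'ID=' '/\tgene\t/ && /TLPfam/ {split($2,a,";"); print a[1]}' data/locus.gff3 > data/family_ids.txt
tlpcensus run --fasta data/proteins.fasta --gff data/locus.gff3 \
    --family data/family_ids.txt --repeats data/repeats.tsv --out report
```

The run logs `census: typical=38, tlp_kinase=4` and writes four tables.
`report/census.tsv` starts:

```
id	organism_code	label	domain_start	domain_end	domain_len	n_cys	coverage	mw_kda	pi	clade	cluster_id
Poptr-TLP0000	Poptr	typical	5	220	215	16	0.9556	25.557	8.46
Poptr-TLP0001	Poptr	typical	5	220	215	16	0.9556	25.782	8.05
```

Each row gives the motif-delimited domain coordinates (here a 215-residue
domain covering 95.6 % of the protein, with its 16 cysteines), the
architecture label, and the predicted mass (≈ 25 kDa, squarely in the
typical TLP range) and isoelectric point. `report/clusters.tsv` reports one
exclusive 11-gene tandem array spanning 350,000 bp, and
`report/coverage.tsv` its TE coverage:

```
chrom	start	end	te_class	covered_bp	fraction	enrichment
chr1	100000	450000	LTR_Gypsy	129500	0.3700
chr1	100000	450000	total	182000	0.5200
```

i.e. transposable elements cover 52 % of the cluster span, 37 % of it from
LTR/Gypsy elements — exactly the fractions planted by the generator.
`tlpcensus phylo --aln msa.fasta --boot 1000 --seed 42 --out tree.nwk`
builds the bootstrap NJ tree for any alignment.

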