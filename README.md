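# islandscan

Regulator-anchored discovery of phage-defence islands, plus EMSA binding
quantification — implemented as a tested, reusable pipeline exercised on
synthetic genomes with known ground truth.

Given annotated genomes (FASTA + GFF3, or GenBank), a query regulator
protein, and a panel of defence-system marker proteins, `islandscan`:

1. finds regulator and marker homologues by local protein alignment
   (affine-gap Gotoh scoring, BLOSUM62, Karlin–Altschul E-values;
   default threshold E < 1e-5, sensitivity mode 1e-3) or ingests
   precomputed 12-column tabular homology results;
2. anchors on each regulator homologue and scans a strand-aware 50-kb
   window downstream and upstream for marker hits (edge-gap distances,
   windows never cross replicon boundaries);
3. collapses marker hits into defence-system instances (20-kb cluster
   gap), classifies each locus (`downstream_only` / `upstream_only` /
   `both` / `none`), and summarizes class distribution, class
   co-occurrence sets, taxonomy, and chromosome/plasmid location;
4. scans up to 200 bp upstream of each regulator for mismatch-tolerant
   inverted repeats (default: 20-bp minimum arm, spacer ≤ 7 bp, ≤ 2
   mismatches; both per-arm and total length semantics supported);
5. quantifies EMSA titrations: fractional saturation Y = 1 − I_T/I_C and
   dissociation constants by nonlinear least squares (hyperbolic or Hill).

A deterministic synthetic-data module (`islandscan.synth`) generates
annotated multi-replicon genomes with planted regulator homologues at
controlled identity, planted marker genes at controlled distances and
strands, planted upstream inverted repeats of controlled geometry, and
noisy binding curves — each with a machine-readable truth table.

## CLI

```bash
# generate a synthetic corpus with truth tables
islandscan simulate --spec corpus.yaml --out corpus/ --seed 1

# run the full neighbourhood scan
islandscan scan --genomes corpus/genomes --query corpus/query.faa \
    --panel-fasta corpus/panel.faa --panel-tsv corpus/panel.tsv \
    --lineage corpus/lineage.tsv --out results/

# standalone inverted-repeat scan
islandscan ir --fasta upstream.fa --out irs.tsv --min-arm 20

# fit dissociation constants from an EMSA intensity table
islandscan emsa-fit --input curves.tsv --out fits.tsv

# reprint headline numbers from a finished run
islandscan report --summary results/summary.json
```

`scan` writes `loci.tsv`, `instances.tsv`, `associations.tsv`,
`cooccurrence.tsv`, `class_distribution.tsv`, `taxonomy.tsv`,
`inverted_repeats.tsv`, `summary.json` and a `manifest.json` carrying the
effective configuration and its hash; identical configs give byte-identical
outputs. Exit codes: 0 success, 2 input error, 3 validation error.

A flat `key = value` config file can replace the flags
(`islandscan scan --config run.cfg`); flags override file values.

## Layout

- `src/islandscan/genome.py` — domain types, FASTA/GFF3/GenBank I/O,
  coordinate utilities (0-based half-open internally)
- `src/islandscan/homology.py` — local alignment, E-values, search,
  tabular ingest
- `src/islandscan/neighbourhood.py` — anchoring, window scan, system
  grouping, association verdicts, summaries
- `src/islandscan/irscan.py` — maximal mismatch-tolerant inverted-repeat
  discovery and operator-box comparison
- `src/islandscan/emsa.py` — fractional saturation, Kd fitting,
  saturation tables
- `src/islandscan/synth.py` — seeded generators and truth tables
- `src/islandscan/pipeline.py`, `src/islandscan/cli.py` — configuration,
  end-to-end driver, CLI
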