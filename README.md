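# livmet

Analysis toolkit for liver-metastasis immunotherapy studies that combine
imaging-based spatial transcriptomics (MERFISH/MERSCOPE), single-cell TCR
repertoires, tumor neoantigen discovery, and gene-signature survival
analysis. The package implements the bespoke computational pieces such
studies rely on, each exercisable end-to-end on seeded synthetic data:

* **Transcript co-localization** — for an ordered gene pair (A, B), the
  fraction of transcripts participating in a "close" interaction:

      score(A, B) = 2 · |{a ∈ A : ∃ b ∈ B, d(a, b) < r, cell(a) ≠ cell(b)}| / (n_A + n_B)

  with radius r = 30 µm (strictly below), same-cell pairs excluded, and each
  source transcript counted at most once — which makes the gene×gene matrix
  asymmetric. Differential matrices (case − control, positive = closer in
  case) compare conditions, with diverging heatmaps for gene subsets.
* **TCR clonotypes** — expansion classes on CDR3β amino-acid keys
  (unique = 1 cell, small = 2–5, large = 6–30, hyperexpanded > 30) and
  clonotype sharing between tissues (e.g. healthy liver vs metastasis).
* **Neoantigen ranking** — somatic missense variants kept when called in
  ≥3 of 4 datasets (WES/RNA × in vivo/in vitro, germline excluded), merged
  with two epitope predictors' score tables and expression (TPM), filtered
  on affinity/TPM/agretopicity/foreignness, ranked, topped (default 33),
  and assembled into a chimeric polyepitope construct whose peptide order
  minimizes predicted junction immunogenicity (maximin over
  junction-spanning 8–11-mers).
* **Quantifications** — lentiviral vector copies per genome
  (2 · c_HIV / c_normalizer from ddPCR), caliper tumor volume (x²·y/2), and
  the IIT (IFN/IL12-induced T cell) signature: per-sample summed log2
  expression with a 50th-percentile high/low split ready for Kaplan–Meier /
  Cox fitting in standard survival packages.

## Worked example

```python
import livmet

# plant co-localization between two genes in a 3 mm synthetic section
cfg = livmet.SpatialSimConfig(
    seed=0, field_size=3000.0, n_genes=12, transcripts_per_gene=200,
    coloc_pairs=(livmet.ColocPair("gene_000", "gene_001",
                                  sigma=2.0, coupled_fraction=0.8),),
)
case = livmet.coloc_matrix(livmet.gen_transcripts(cfg))
control_cfg = livmet.SpatialSimConfig(
    seed=1, field_size=3000.0, n_genes=12, transcripts_per_gene=200)
control = livmet.coloc_matrix(livmet.gen_transcripts(control_cfg),
                              panel=case.panel)
diff = livmet.differential_matrix(case, control)
print(f"planted pair: {diff.score('gene_000', 'gene_001'):+.3f}")
print(f"typical null pair: {diff.score('gene_002', 'gene_003'):+.3f}")
```

prints

```
planted pair: +0.150
typical null pair: +0.005
```

The planted pair's differential score is more than an order of magnitude
above the null background: the coupled placement survives the same-cell exclusion and
shows up as "closer in case", exactly the readout used to compare treated
vs control tissue sections.

The same functionality is exposed on the command line (`livmet simulate`,
`livmet coloc`, `livmet clonotype`, `livmet neoantigen`, `livmet score`);
see `livmet --help`.

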