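# nbgcloner

Positional-cloning toolkit for a diabetes quantitative trait locus (QTL)
mapped in an (NZO×C3H)N2 mouse backcross. It implements, as a tested and
reusable library, the analysis chain that narrows a blood-glucose QTL on
chromosome 15 (the *Nbg15* locus, ~50–80 Mbp) down to a handful of
candidate genes:

1. **QTL scan** — marker-regression LOD scores over the backcross,
   genome-wide significance by phenotype permutation, and a 1.5-LOD support
   interval snapped to the nearest genotyped markers.
2. **Cohort diabetes metrics** — diabetic classification (random blood
   glucose ≥ 300 mg/dL for ≥ 3 consecutive weeks), prevalence, case
   fatality rate among diabetics within the 20-week study, severe
   hyperglycemia (> 500 mg/dL at week 15), and islet-area binning.
3. **Haplotype blocks** — classification of windows tiling the locus into
   identical-by-descent (IBD) vs polymorphic (non-IBD) between the parental
   strains by discordant-SNP density (default: > 50 SNPs per 150-kb window;
   a 250-kb/≥ 100 dialect is also provided), merged into blocks.
4. **Variant prioritization** — genes retained when they carry a
   HIGH-impact variant or a MODERATE-impact variant with SIFT < 0.5,
   intersected with the polymorphic blocks, plus conservation flagging of
   the mutated residue from a protein multiple alignment.
5. **Expression scoring** — islet-specificity z-scores of log2 expression
   ratios (islet vs liver, quadriceps, gonadal white fat, brown fat) per
   strain (NZO, C3H, B6), combined by the minimum so only genes enriched in
   every strain and against every tissue score high; plus qPCR ΔCt
   relative expression, 2^−(Ct_target − Ct_Actb).
6. **Pipeline** — one config drives scan → blocks → impact filter → block
   intersection → expression filter → ranked candidate report.

Because the original animal data are not public, the package ships a
first-class **synthetic-data generator** that emulates every input with a
planted causal structure (additive QTL effect, polymorphic blocks, one
deleterious islet-enriched gene), so the entire chain is testable end to
end: the planted gene must come out ranked first, and a null study must
yield an empty report.

## The scan statistic

For an N2 backcross every marker has two genotype classes (homozygous N/N
coded 0, heterozygous N/C coded 1), so marker regression is exact:

    LOD = (n/2) · log10(RSS₀ / RSS₁) = −(n/2) · log10(1 − r²)

with RSS₀ the residual sum of squares about the grand phenotype mean, RSS₁
about the genotype-group means, and r the genotype–phenotype correlation.
The genome-wide threshold is the ceil((1−α)·N)-th smallest of N permutation
maximum LOD scores (default N = 100, α = 0.05).

## Worked example

```
$ nbgcloner simulate --out-dir demo --seed 3
study written to demo
planted causal marker: rs0028, gene: GENE0018

$ nbgcloner scan --genotypes demo/genotypes.csv --phenotype demo/phenotypes.csv \
    --map demo/map.tsv --out-prefix demo/scan --seed 3
peak rs0028 LOD=107.67 threshold=1.47 significant=True

$ nbgcloner blocks --catalog demo/snp_catalog.vcf \
    --region chr15:50000000-80000000 --out-prefix demo/b
2 polymorphic block(s) from 5045 discordant SNPs
```

The scan finds the planted marker rs0028 with LOD 107.7, far above the
permutation threshold of 1.47 (the simulated effect is deliberately strong:
protective heterozygotes escape the progressive hyperglycemic drift
entirely). The block caller recovers the two planted polymorphic regions
(proximal ~61.5–64 Mbp, distal ~77.5–80 Mbp). Running the whole chain:

```
$ nbgcloner run-all --config demo/cfg.yaml --out-dir demo/run
funnel: {'total_genes': 20, 'impact_pass': 4, 'block_pass': 1, 'expression_pass': 1, 'final': 1}
top candidate: Syng18 (GENE0018)
```

Of 20 genes in the locus, 4 carry deleterious-looking variants, 1 of those
lies in a polymorphic block, and that one is also islet-specific — the
planted causal gene, flagged with all evidence columns in
`demo/run/candidates.tsv`.

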