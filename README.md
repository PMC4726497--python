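# cnotscreen

Post-transcriptional target discovery for **CNOT7**, the catalytic
deadenylase subunit of the CCR4-NOT complex.

CNOT7 shortens mRNA poly(A) tails and thereby sets transcript stability.
It has no sequence specificity of its own: adaptor proteins (TOB1,
CNOT1) bridge it to sequence-specific RNA-binding proteins whose
recognition elements sit in 3'UTRs. `cnotscreen` implements the
computational side of finding the transcripts such a deadenylase program
targets:

1. **3'UTR motif scanning** — map degenerate RBP elements (CPE, PUM,
   NRE, CPSF, permissive/stringent ARE) given as IUPAC strings;
   overlapping sites counted, sense strand only.
2. **Anticorrelated-transcript calling** — from a
   control / *Cnot7*-knockdown / *CNOT7*-overexpression expression
   design, call genes that move *inversely* to Cnot7 (up on knockdown,
   down on overexpression) with per-gene Welch t-tests.
3. **RIP enrichment** — call transcripts enriched in a FLAG-CNOT7
   immunoprecipitate relative to both input RNA and a control IP
   (depth-normalized fold change ≥ θ against both), and intersect with
   the anticorrelated set.
4. **Motif enrichment by genome resampling** — draw same-size random
   gene sets from the annotated genome 1000 times and compare the
   observed count of motif-bearing target genes against that null
   (smoothed empirical p, plus a one-tailed t-style approximation).
5. **Tripartite screen** — genome-wide search for transcripts carrying
   CPE **and** CPSF **and** NRE sites, filtered for expressed and
   anticorrelated genes, with exact Venn accounting.
6. **Signature survival analysis** — weight candidate targets by
   −corr(gene, CNOT7), score patients by a normalized weighted sum of
   z-scores, split at the median and compare distant-metastasis-free
   survival with the Mantel-Cox (log-rank) test.

A synthetic-data module generates every input with planted, recorded
ground truth, so the whole pipeline is testable end to end without
external data.

## The statistics in brief

For target set $T$ (size $n$) and motif $m$, the enrichment null is
built by resampling: draw $n$ genes without replacement from the
annotated background, record the number carrying $m$, repeat $B$ times
(default $B=1000$). With observed carrier count $k_{obs}$,

$$p_{\mathrm{emp}} = \frac{1 + \#\{k^{(b)} \ge k_{obs}\}}{B + 1},
\qquad
p_t = \Pr\left(t_{B-1} \ge \frac{k_{obs} - \bar k}{s_k}\right).$$

A transcript is *anticorrelated* when the knockdown-vs-overexpression
Welch test has $p < \alpha$ (default 0.01) **and** $t_{KD} > 0$,
$t_{OE} < 0$ (contrasts oriented perturbation − control). Patient
scores are $s_p = \sum_g w_g z_{gp} / \sum_g |w_g|$ with
$w_g = -r_{g,\mathrm{CNOT7}}$; groups split at the median score (ties
low) are compared by the standard log-rank statistic
$(O-E)^2/V$.

## Worked example

```bash
cnotscreen all --seed 11 --out-dir demo --n-genes 2000 --quiet
python -m json.tool demo/run_report.json
```

produces (abridged):

```json
"target_chain": {
    "n_genes": 2001,
    "n_dysregulated": 109,
    "n_anticorrelated": 102,
    "n_rip_intersected": 93,
    "n_tripartite_in_intersection": 7,
    "tripartite_percent": "8%"
},
"genome_screen": {
    "n_genome": 2000, "n_tripartite": 124,
    "n_expressed_tripartite": 92, "n_final": 7
},
"survival": {
    "chi_square": 7.09, "p_value": 0.0077,
    "groups": {"high": {"n": 300, "median_survival": 53.7},
               "low":  {"n": 300, "median_survival": 38.4}}
}
```

Reading it: of 2000 synthetic genes (plus the `Cnot7` driver row), 102
were called anticorrelated with Cnot7 (100 were planted); 93 of those
were also RIP-enriched; 7 carry the full CPE/CPSF/NRE tripartite motif.
Genome-wide, 124 genes are tripartite, 92 of them expressed, 7 also
anticorrelated; those genes, weighted by inverse correlation with the
driver and applied to a simulated 600-patient cohort, separate survival
at the median split (log-rank p = 0.0077), with the high-score group
living longer — the protective direction planted in the simulation.

Every stage is also available as its own subcommand (`simulate`,
`scan`, `de`, `rip`, `enrich`, `screen`, `signature`, `survival`)
reading and writing plain TSV/FASTA/JSON in the shared output
directory.

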