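# ampliconcna

Detection of large copy number aberrations (CNAs) from ultra-deep targeted
**amplicon sequencing** data.

Amplicon panels are cheap and routine in oncology for calling actionable
point mutations, but the PCR amplification step destroys most of the raw
copy-number signal: per-amplicon read counts are dominated by
amplicon-specific PCR efficiency, GC-content and fragment-length biases,
and run-to-run technology effects. `ampliconcna` recovers gene-level gains
and losses from such data using only a small panel of diploid control
samples processed with the same target-selection kit — no SNP array, no
array CGH, no matched normal.

It is intended for bioinformaticians processing targeted cancer panels
(tens to thousands of amplicons, several amplicons per gene) with at least
two diploid controls available.

## Method

Per-amplicon raw read counts (RRC; duplicates deliberately kept — at this
depth nearly all reads are PCR duplicates) are pushed through a
multi-factor normalization:

1. **Library size** — NRC_Lib = RRC / (N/R) for N total reads over R
   amplicons, so a copy-neutral, bias-free amplicon sits near 1.
2. **GC content, then amplicon length** — local quadratic regression
   (LOESS, degree 2) of log NRC on each covariate, removed
   multiplicatively.
3. **Gender** — chrX dosage M_i ≈ mean chrX NRC classifies controls via a
   1- vs 2-component Gaussian mixture (BIC); male chrX counts are doubled.
4. **Technology baseline** — PCA of the controls' log NRC_Len (amplicons ×
   controls). PC1 is essentially the shared amplicon-efficiency profile
   (r ≥ 0.99 with the mean profile); the first k = min(3, n−1) PCs form
   the baseline, and each sample's log NRC_Len is regressed on them (OLS);
   the residuals are the log copy-ratio profile.
5. **Noise model** — per-amplicon σ_i = f(PC1) fitted by LOESS to squared,
   per-control-rescaled residuals: high-coverage amplicons are quieter.

Tumor profiles are then segmented with a **weighted circular binary
segmentation** (weights 1/σ_i², permutation acceptance at α = 0.01); the
copy-neutral **zero level** is the highest-density component of a Gaussian
mixture over resampled segment means; ratios are centered on it and the
per-sample scale σ_sample is estimated on neutral amplicons. Each
candidate CNA must survive, on X_i = log(NRC_final,i)/σ_i^sample:

- the **fixed variance test**: P = 2(1 − Φ(|X̄|√n)), and
- the **one-sample t-test**, both at P < 0.01, and
- the **purity band**: its weighted geometric mean ratio must fall outside
  (0.875, 1.125). Since ExpectedNRC = (1−c) + c(1 ± l/P) for an l-copy
  event in a fraction c of cells at ploidy P, this suppresses one-copy
  events carried by fewer than 25% / 50% of cells in diploid / tetraploid
  tumors — below that, noise and signal are indistinguishable.

Breakpoints falling inside genes are re-tested gene-aware (t-test against
the adjoining segment means) and moved to gene boundaries when
unjustified. Per-amplicon outlier P-values (Benjamini–Hochberg adjusted)
are reported but single-amplicon events are never promoted to CNA calls.

Calls are *relative* to the zero level: a gain shared by every gene on a
tiny panel is invisible by construction.

## Worked example

A fully synthetic run (the `simulate` subcommand plants known CNAs and
writes panel BED + counts TSV + truth table):

```sh
cat > sim.json <<'EOF'
{"n_genes": 40, "amplicons_per_gene": 8, "n_controls": 15,
 "cna_spec": [{"genes": ["GENE003", "GENE004"], "direction": "gain", "l": 1, "c": 1.0},
              {"genes": ["GENE025"], "direction": "loss", "l": 1, "c": 1.0}],
 "seed": 7}
EOF
ampliconcna simulate --config sim.json --outdir simdata
ampliconcna baseline --counts simdata/counts.tsv \
    --samples C01,C02,C03,C04,C05,C06,C07,C08,C09,C10,C11,C12,C13,C14,C15 \
    --out base.tsv --seed 7
ampliconcna call --baseline base.tsv --counts simdata/counts.tsv \
    --sample T01 --outdir calls --seed 7
```

which prints

```
wrote 320 amplicons x 16 samples to simdata
baseline written to base.tsv (k=3, explained variance [0.957, 0.0041, 0.0041])
T01: 3 gene-level CNA call(s); results in calls
```

(PC1 explains 96% of the control variance — the shared efficiency
profile.) The non-neutral rows of `calls/T01.genes.tsv`:

```
gene     status  ratio   copies  n_amplicons  filter
GENE003  gain    1.516   3       8            PASS
GENE004  gain    1.470   3       8            PASS
GENE025  loss    0.504   1       8            PASS
```

Exactly the three planted events: one-copy gains at ratio ≈ 1.5 (3 copies
under the diploid assumption) and a one-copy loss at ratio ≈ 0.5
(1 copy). The segments table carries both test P-values and the filter
verdict per segment; the amplicons table carries per-amplicon outlier
q-values. Alignment input (SAM/BAM) is accepted wherever a counts TSV is,
via `--panel`/`--controls`/`--tumor`.

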