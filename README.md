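# hopfec

Directed effective-connectivity (EC) estimation for networks of coupled
Stuart–Landau (Hopf) oscillators.

Each network node sits near a supercritical Hopf bifurcation; the package
simulates the coupled stochastic system, measures functional connectivity
(FC, zero-lag Pearson correlation of the band-limited signals) and lagged
functional connectivity (FC at lag tau, whose asymmetry carries
direction), and recovers a directed, non-negative coupling matrix by
iterative error correction:

```
C[i,j] <- C[i,j] + eps * [(FC_emp - FC_sim) + (FCtau_emp - FCtau_sim)][i,j]
```

with entries clamped to `[0, 0.2]`. All matrices are read *from column to
row*: `C[i, j]` is the link from source region `j` to target region `i`.

Because no real imaging data ships with the package, a synthetic-cohort
module generates ground-truth networks (sparse, asymmetric, with strong
homotopic cross-hemisphere links) and multi-subject, multi-session
band-limited "resting-state" cohorts, which power the parameter-recovery
validation end to end.

## Layout

| module | contents |
| --- | --- |
| `hopfec.simulate` | Euler–Maruyama integration of the coupled oscillators (numba-accelerated when available) |
| `hopfec.metrics` | band-pass filtering, intrinsic-frequency estimation, FC / lagged FC, session averaging |
| `hopfec.inference` | EC initialization, the error-correcting update, fit metric, and the fit loop |
| `hopfec.cohort` | ground-truth networks, structural masks, synthetic cohorts |
| `hopfec.roi` | direction differences, display thresholding, ROI-profile ANOVA, ipsi/contra ratios |
| `hopfec.io`, `hopfec.cli`, `hopfec.pipeline` | TSV + JSON-sidecar I/O, the `hopfec` CLI, end-to-end runs |

## CLI

```bash
hopfec synth --regions 20 --density 0.15 --subjects 20 --sessions 4 \
             --volumes 900 --seed 42 --outdir cohort/
hopfec simulate --ec EC.tsv --params params.toml --volumes 900 --seed 7 --out ts.tsv
hopfec fit --fc fc.tsv --fctau fctau.tsv --init zeros --seed 11 \
           --out ec.tsv --log fit.log
hopfec analyze --ec ec.tsv --parcellation parc.tsv --outdir report/
hopfec pipeline --config run.toml --outdir run/ --seed 17
```

Matrices and timeseries are labeled TSV files with a `<file>.json` sidecar
carrying kind, lag, sampling interval and provenance. `hopfec pipeline`
writes a `manifest.json` from which the run is exactly reproducible.

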