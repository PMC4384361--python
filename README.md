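# pausewave

Multi-scale Haar wavelet analysis of single-molecule polymerase kinetics,
and pause profiling around non-B-DNA sequence motifs.

Real-time single-molecule sequencers report, for every incorporated base,
the interpulse duration (IPD): the waiting time in seconds before the
polymerase added that base. Long IPDs mean the polymerase paused — which
can happen when the template forms a non-B-DNA structure such as a
G-quadruplex ((GGC)ₙ and G₃N₁₋₇-type repeats) or a Z-DNA-prone (CG)ₙ
tract. `pausewave` gives researchers working with such kinetics two
analyses:

1. **Multi-scale correlation** — how much of the kinetic variation tracks
   nucleotide composition, and at which genomic length scales. Each track
   (A/C/G/T occupancy indicators, IPD, insert-error counts) is decomposed
   with the orthonormal decimated Haar transform,

   ```
   s_k^(2) = (x_{2k-1} + x_{2k}) / √2        d_k^(2) = (x_{2k-1} - x_{2k}) / √2
   ```

   applied recursively, so smooth coefficients measure local density at
   scales 2, 4, …, and detail coefficients the change in that density.
   Pearson correlations between coefficient vectors are reported per track
   pair, per scale, separately for smooth and detail, together with each
   track's per-scale detail power `P_j = Σᵢ(dᵢ^(j))² / Σ_jΣᵢ(dᵢ^(j))²`.
   Orthonormality (E(d)=0, E(d²)=1 for white noise at every scale) is
   what keeps coarse scales from losing variance the way plain sliding
   averages do.

2. **Pause profiling** — pattern sites defined by a regular expression
   (e.g. the G-quadruplex motif `(GGG(.){1,7}GGG(.){1,7}GGG(.){1,7}GGG)`)
   are located on both strands of the reference; each site aggregates the
   reads that synthesize *its* strand over a 128-nt window in synthesis
   order. Per window position the profiler reports count, mean, 90% and
   95% quantiles of the raw IPD and of the 2-nt and 4-nt **causal** wavelet
   smooths `s_i^(w) = (x_{i-w+1} + … + x_i)/√w`, computed within each read
   only — a pause is attributed to the base at which it occurs and its
   already-synthesized context, never to bases the polymerase has not
   reached.

A seeded simulator generates references and aligned kinetic reads
(log-normal baseline IPD with small base-identity effects, additive
exponential pause events at motif offsets on the correct strand, Poisson
insert errors), so the entire pipeline is testable without sequencer
data.

## Worked example

Simulate 500 reads over a 12-kb reference carrying three (GGC)₃GG
repeats, with a pause process at the repeat's first cytosine (offset 2):
10% of reads crossing it gain an Exponential(4 s) IPD addition. Then scan
for the repeat and profile the kinetics:

```bash
pausewave simulate --seed 42 --out-dir sim --reference-length 12000 --n-reads 500 \
    --motif GGCGGCGGCGG@3000 --motif GGCGGCGGCGG@6500 --motif GGCGGCGGCGG@10000 \
    --pause 2:0.1:4.0
# simulated 500 reads over 12000 nt -> sim/
pausewave scan --fasta sim/reference.fasta --kinetics sim/kinetics.tsv \
    --pattern "GGCGGCGGCGG" --out-dir scan
# 3 sites, 121 reads contributed -> scan/
```

`scan/profile.tsv` holds the aggregated profile. The pattern starts at
window position 58 (centered anchor), so the injected pause sits at
position 60 — exactly where the raw-IPD quantiles spike:

```
position  count   mean    q90    q95
      58    109  0.181  0.323  0.454
      59    109  0.188  0.344  0.398
      60    109  0.455  0.706  2.383     <- injected pause offset
      61    109  0.214  0.413  0.605
      62    109  0.192  0.338  0.485
```

The mean at the pause position triples and the 95% quantile reaches
2.4 s against a ~0.15 s baseline — the signature of rare, heavy-tailed
pausing, while `sites.bed` records the three loci. The multi-scale
correlation analysis on the same data,

```bash
pausewave correlate --kinetics sim/kinetics.tsv --out-dir corr --max-scale 2048
# 500/500 reads kept, track length 524288, scales up to 2048 -> corr/
```

writes one row per track pair per scale; e.g. the G-vs-IPD correlations
stay near zero at all scales (r_smooth 0.028 at scale 2, −0.009 at scale
2048) because in this simulation base identity shifts the baseline by
only a few percent — composition alone explains little of the kinetic
variation, and pausing is a local motif effect instead.

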