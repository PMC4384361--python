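# Methods

## The transform

`pausewave` analyses per-base signal tracks from aligned single-molecule
reads: interpulse duration (IPD, seconds), insert-error counts, and 0/1
nucleotide occupancy indicators. Two Haar transforms are used.

**Decimated transform.** For a signal of length N = 2^J, the filters
h = (1/√2, 1/√2) and g = (1/√2, −1/√2) are applied recursively:
smooths at scale 2w come from pairs of smooths at scale w, halving the
coefficient count at each scale. Scales are labelled by the region width
a coefficient summarizes (2, 4, …, N), not by the dyadic level. The
basis is orthonormal: energy is conserved (Parseval), and white noise
has detail coefficients with mean 0 and second moment 1 at *every*
scale, so coarse scales retain testable variance where a plain sliding
average would wash it out. Inputs must already be a power of two:
trimming is the caller's decision because silently truncating one track
would desynchronize it from the others.

**Causal smooth.** For attributing scaled kinetics to individual
nucleotides, the non-decimated (stationary) smooth is computed on the
*reversed* signal, equivalently as a trailing-window sum
s_i^(w) = (x_{i−w+1} + … + x_i)/√w. This attributes a pause to the base
at which it occurs and its already-synthesized context — the physically
sensible direction, since obstacles ahead of the polymerase slow it as
it approaches. Leading positions without a full trailing window are
undefined (NaN), never padded: periodic or reflective padding would
fabricate kinetics across read starts. Only smooth coefficients are
produced at this layer; the windowed analysis does not use non-decimated
details.

**Power.** The per-scale detail power fraction
P_j = Σᵢ(dᵢ^(j))² / Σ_jΣᵢ(dᵢ^(j))² quantifies where a track's variation
lives. A constant track has no detail energy and raises a
degenerate-energy error rather than returning NaNs. Inside the
correlation table the denominator is restricted to the scales the table
actually reports (≤ max_scale), so the tabulated fractions sum to 1
over the rows present; `power_by_scale` on a full decomposition uses
all scales.

## The correlation analysis

Reads strictly longer than 1000 nt (boundary discontinuities stay rare)
are concatenated in input order and trimmed from the tail to the largest
power of two ≤ min(total, 2²³). Six tracks are decomposed once each and
Pearson's r is computed per unordered track pair per scale, separately
for smooth and detail coefficient vectors, up to max_scale (default
2048, additionally capped at half the track length so every r has ≥ 2
coefficient pairs). Coefficients spanning read boundaries are included
by default — with >1000-nt reads they are a negligible fraction — and a
`mask_boundaries` flag excludes them for sensitivity analysis.
Zero-variance coefficient vectors yield an undefined r, reported as
missing, never coerced to 0; this arises naturally (e.g. periodic
sequence makes an indicator's coarse smooths constant). IPDs are
correlated in raw seconds; a clearly-labelled `log_ipd` (log1p) switch
is provided as an extension only.

## The pause profiler

Pattern sites are leftmost non-overlapping regex matches, scanned
independently on the forward sequence and on the reverse complement
(mapped back to forward coordinates, strand "−"); an `overlapped` flag
resumes scanning one position after each match start for dense tandem
repeats. A site aggregates only reads that synthesize its own strand,
over a window (default 128 nt) laid out in synthesis order with the
pattern start at floor((W − match length)/2) by default (configurable
anchor). This strand discipline is what separates, e.g., (GGC)ₙ from
(CCG)ₙ kinetics at the same loci: a pattern and its reverse complement
share no (site, read) contributions.

Each read contributes raw IPD at covered positions plus its 2-nt and
4-nt causal smooths computed within the read (never across reads; no
imputation at partially covered windows). All (site, read) observations
are pooled per window position; count, mean, and upper quantiles
(default 0.90/0.95) are reported per position per track. Quantiles use
linear interpolation of order statistics, rank h = (n−1)p + 1 (numpy's
default), fixed so results are reproducible across implementations. The
plotted/tabulated central statistic is the mean, labelled as such.
Positions with fewer than `min_count` observations are flagged, not
dropped. A pattern with no sites or no covering reads yields a profile
of zero counts, not an error; a window shorter than a match is an
error.

## The simulator

The generator emulates whole-genome-amplified (modification-free)
single-molecule kinetics with the structure the analyses assume:

- **Reference**: i.i.d. bases from configurable composition (default
  uniform), with motif sequences overwritten at stated positions.
- **Reads** (default 500 per run): starts uniform, strand
  Bernoulli(0.5), lengths uniform on [1001, 2000] nt so the default
  length filter retains them; bases are the strand-appropriate
  reference slice in synthesis order.
- **Baseline IPD**: log-normal with σ = 0.6 and per-base log-medians
  0.146/0.150/0.154/0.148 s (A/C/G/T). The median sits near 0.15 s and
  IPDs above 1 s are rare (~3 log-sd away), the regime in which a
  multi-second pause is conspicuous. The ±3% per-base spread makes
  composition a real but small kinetic factor: large enough to exist,
  small enough that a pattern's composition alone is not detectable as
  pausing at the coverage the tests use — matching the observation that
  composition explains only a small part of kinetic variation.
- **Pauses**: at stated motif-relative offsets, reads synthesizing the
  motif's strand gain an additive Exponential(τ) IPD with probability
  p_pause (additive because structure-resolution time adds to normal
  incorporation time; exponential for a heavy-ish tail at desk scale).
  Every injected pause is recorded in a ground-truth table.
- **Inserts**: Poisson(λ = 0.01) per position.

One PCG64 stream (numpy `default_rng`, named in run metadata) drives
the whole run in documented order — reference bases, then per read:
length, start, strand, baseline IPDs, pause draws (sites in coordinate
order, specs in listed order), inserts — so identical configs give
byte-identical TSV output.

What the simulator does **not** emulate: mismatch/deletion errors,
context-dependent kinetic signatures beyond single-base identity,
modified bases, or genuine polymerase dynamics. Tests passing on this
generator therefore demonstrate that the machinery recovers pausing of
the assumed form at realistic coverage; they do not validate kinetic
claims about real genomes, where sequence-context effects are far
richer.

## Statistical behaviour of the q90 pause signature

With an additive Exponential(τ) pause at probability exactly p = 0.1,
the population 90th percentile at the pause offset solves
0.9·S_base(t) + 0.1·e^(−(t−m)/τ) = 0.1 — it sits at the *lower edge* of
the pause component (≈0.6 s for τ = 4 s on this baseline), about 2–3×
the background q90 (≈0.32 s). The q90 towers over background only when
p_pause clearly exceeds the quantile's tail mass (e.g. p = 0.3–0.5), or
at higher quantiles. Localization is nevertheless sharp: the argmax of
the per-position q90 lands on the injected offset at ~60× coverage. The
test suite asserts the localization property and a moderate (>1.5×)
elevation; null-model indistinguishability of the pattern region from
background is tested with per-position two-sided Mann–Whitney tests at
family-wise α = 0.01 (Bonferroni over pattern positions), since
uncorrected per-position testing falsely rejects for a meaningful
fraction of seeds under an exact null.

## Numerical choices and problem sizes

Double precision throughout. Closeness tolerances: reconstruction
1e-10 relative, Parseval 1e-9 relative, causal/decimated consistency
1e-9, power normalization 1e-12. Haar is the only filter (the analyses
need its locality and simplicity; no filter plug-in API). TSV floats
are written with 6 significant digits, and round-trips are exact at
that precision. Test simulations use 8–12 kb references with 3 motif
sites and 500–600 reads (≈60–100× coverage), sizes at which the
stochastic properties under test have comfortable Monte-Carlo margins;
the correlation default max_scale is 2048 with the track cap at 2²³
nucleotides. The orthonormality check in the acceptance script uses
2¹⁶ standard-normal values and summarizes scales with ≥ 256 detail
coefficients.

## Known limitations

- The kinetics TSV is the only read format; native sequencer containers
  (cmp.h5, kinetics-tagged BAM) are out of scope, as is alignment.
- The profiler assumes pre-aligned, per-position IPDs; inserts are
  counted after their aligned position by convention (the simulator
  follows the same convention).
- Reads spanning several nearby sites contribute once per site.
- No significance testing is attached to the correlation table, and the
  profiler offers no statistical detection of structures — it is an
  exploration tool for pause signatures.
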